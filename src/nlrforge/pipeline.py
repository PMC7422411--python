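"""End-to-end orchestration: census -> clusters -> ids -> homology -> splice.

``run_all`` executes the stages in dependency order from a single config
mapping (typically loaded from YAML), writes the stage reports under the
output directory, and records a run manifest with input checksums, the
seed, and per-stage row counts.  Stages are individually skippable; a
failed stage preserves the outputs produced so far and is marked failed
in the manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Iterable, Mapping, Optional

import pandas as pd
import yaml

from . import __version__
from . import io as nio
from .align import align_pair, progressive_align
from .classify import (
    DEFAULT_CORE_ACCESSIONS,
    census,
    classify_architecture,
    find_nbarc_proteins,
    motifs_complete,
    scan_motifs,
)
from .clusters import (
    clusters_to_bed,
    detect_clusters,
    similarity_bins,
    write_clusters_tsv,
)
from .homology import (
    assign_progenitor_category,
    build_kmer_index,
    flag_nlr_homologs,
    nlr_homolog_fraction,
    progenitor_category_table,
    search_homologs,
)
from .integrated import extract_ids, positional_profile
from .splice import compare_transcript_domains, join_expression, report_to_frame
from .trees import bootstrap_support, cluster_nesting, neighbor_joining, p_distance_matrix

logger = logging.getLogger(__name__)

STAGES = ("census", "cluster", "ids", "homology", "splice")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _protein_to_gene(genes) -> dict[str, str]:
    mapping = {}
    for g in genes:
        for tid in g.transcript_ids:
            mapping[tid] = g.gene_id
    return mapping


def run_all(
    config: Mapping | str | Path,
    outdir: str | Path,
    skip: Iterable[str] = (),
    seed: int = 0,
) -> Path:
    """Run all stages; returns the output directory.

    ``config`` maps input names to paths: ``proteome`` (FASTA), ``gff3``,
    ``domains`` (TSV); optionally ``expression`` (TSV), ``id_map``,
    ``targets`` (mapping species code -> {proteome, domains}), and
    numeric stage parameters (``max_gap_bp``, ``max_intervening``,
    ``min_identity``, ``min_coverage``, ``truncation_fraction``,
    ``bootstrap_reps``, ``tree_max_taxa``).
    """
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    skip = set(skip)

    required = ["proteome", "gff3", "domains"]
    for key in required:
        if key not in config or not Path(config[key]).exists():
            raise FileNotFoundError(f"required input {key!r} missing or unreadable")

    manifest = {
        "version": __version__,
        "seed": seed,
        "config": {k: str(v) for k, v in config.items() if not isinstance(v, dict)},
        "input_checksums": {k: _sha256(Path(config[k])) for k in required},
        "stages": {},
    }

    proteome = nio.read_fasta(config["proteome"])
    genes, transcripts = nio.read_gff3(config["gff3"])
    domain_table = nio.read_domain_table(config["domains"], proteome=proteome)
    id_map = nio.read_id_map(config["id_map"]) if config.get("id_map") else {}
    if id_map:
        domain_table = type(domain_table)(
            nio.DomainHit(id_map.get(h.protein_id, h.protein_id), h.accession,
                          h.name, h.start, h.end, h.source, h.score)
            for h in domain_table
        )
    prot_by_id = {p.protein_id: p for p in proteome}
    p2g = _protein_to_gene(genes)

    state: dict = {}
    for stage in STAGES:
        if stage in skip:
            manifest["stages"][stage] = {"status": "skipped"}
            continue
        try:
            counts = _STAGE_FUNCS[stage](
                config, outdir, seed, proteome, prot_by_id, genes, transcripts,
                domain_table, p2g, state,
            )
            manifest["stages"][stage] = {"status": "ok", **counts}
        except Exception as exc:  # stage failure preserves partial outputs
            logger.exception("stage %s failed", stage)
            manifest["stages"][stage] = {"status": "failed", "error": str(exc)}
            break
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return outdir


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _stage_census(config, outdir, seed, proteome, prot_by_id, genes, transcripts,
                  domain_table, p2g, state):
    nbarc_proteins = find_nbarc_proteins(domain_table)
    hits_by_protein: dict[str, list] = {}
    for h in domain_table:
        hits_by_protein.setdefault(h.protein_id, []).append(h)
    architectures = []
    for pid in sorted(nbarc_proteins):
        hits = hits_by_protein[pid]
        complete = False
        if pid in prot_by_id:
            nb = next(h for h in hits if h.accession in DEFAULT_CORE_ACCESSIONS["NBARC"])
            complete = motifs_complete(scan_motifs(prot_by_id[pid], nb))
        architectures.append(
            classify_architecture(pid, hits, motif_complete=complete)
        )
    result = census(architectures, genes=genes, protein_to_gene=p2g)
    result.to_frame().to_csv(outdir / "census.tsv", sep="\t", index=False)
    pd.DataFrame([a.__dict__ for a in architectures]).to_csv(
        outdir / "architectures.tsv", sep="\t", index=False
    )
    state["architectures"] = architectures
    state["nbarc_proteins"] = nbarc_proteins
    state["hits_by_protein"] = hits_by_protein
    state["nbarc_genes"] = {p2g.get(p, p) for p in nbarc_proteins}
    return {"n_nbarc_proteins": len(nbarc_proteins), "n_nbarc_genes": result.n_genes}


def _stage_cluster(config, outdir, seed, proteome, prot_by_id, genes, transcripts,
                   domain_table, p2g, state):
    nbarc_genes = state.get("nbarc_genes") or {
        p2g.get(p, p) for p in find_nbarc_proteins(domain_table)
    }
    clusters = detect_clusters(
        nbarc_genes, genes,
        max_gap_bp=int(config.get("max_gap_bp", 200_000)),
        max_intervening=int(config.get("max_intervening", 7)),
    )
    write_clusters_tsv(clusters, outdir / "clusters.tsv")
    nio.write_bed(clusters_to_bed(clusters), outdir / "clusters.bed")

    # within-cluster pairwise identity and the similarity-bin edge list
    gene_seq = {}
    for g in genes:
        if g.transcript_ids and g.transcript_ids[0] in prot_by_id:
            gene_seq[g.gene_id] = prot_by_id[g.transcript_ids[0]].sequence
    results = []
    for c in clusters:
        members = [m for m in c.member_gene_ids if m in gene_seq]
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                results.append(
                    align_pair(gene_seq[members[i]], gene_seq[members[j]],
                               id_a=members[i], id_b=members[j])
                )
    bins = similarity_bins(results)
    bins.to_csv(outdir / "cluster_similarity.tsv", sep="\t", index=False)

    # per-chromosome nesting test on an NJ tree of clustered genes
    n_reps = int(config.get("bootstrap_reps", 0))
    max_taxa = int(config.get("tree_max_taxa", 40))
    nesting_rows = []
    by_chrom: dict[str, list] = {}
    for c in clusters:
        by_chrom.setdefault(c.chromosome, []).append(c)
    for chrom in sorted(by_chrom):
        taxa = [m for c in by_chrom[chrom] for m in c.member_gene_ids if m in gene_seq]
        if len(taxa) < 4 or len(taxa) > max_taxa or len(by_chrom[chrom]) < 2:
            continue
        seqs = {t: gene_seq[t] for t in taxa}
        msa = progressive_align(seqs)
        if n_reps > 0:
            tree = bootstrap_support(msa, n_reps=n_reps, seed=seed)
        else:
            tree = neighbor_joining(p_distance_matrix([msa[t] for t in taxa]), taxa)
        with open(outdir / f"tree_{chrom}.nwk", "w") as fh:
            fh.write(tree.to_newick() + "\n")
        for c in by_chrom[chrom]:
            members = [m for m in c.member_gene_ids if m in seqs]
            if len(members) >= 2:
                nesting_rows.append(
                    {"cluster_id": c.cluster_id, "chromosome": chrom,
                     "nested": cluster_nesting(tree, members)}
                )
    pd.DataFrame(nesting_rows).to_csv(outdir / "cluster_nesting.tsv", sep="\t", index=False)
    state["clusters"] = clusters
    return {"n_clusters": len(clusters),
            "n_clustered_genes": sum(c.n_members for c in clusters)}


def _stage_ids(config, outdir, seed, proteome, prot_by_id, genes, transcripts,
               domain_table, p2g, state):
    nbarc_proteins = state.get("nbarc_proteins") or find_nbarc_proteins(domain_table)
    hits_by_protein = state.get("hits_by_protein")
    if hits_by_protein is None:
        hits_by_protein = {}
        for h in domain_table:
            hits_by_protein.setdefault(h.protein_id, []).append(h)
    all_ids = []
    for pid in sorted(nbarc_proteins):
        length = prot_by_id[pid].length if pid in prot_by_id else None
        all_ids.extend(
            extract_ids(pid, hits_by_protein.get(pid, []), protein_length=length)
        )
    rows = [
        {"protein_id": d.protein_id, "accession": d.domain.accession,
         "name": d.domain.name, "start": d.domain.start + 1, "end": d.domain.end,
         "rel_start": d.rel_start, "rel_end": d.rel_end, "rel_mid": d.rel_mid,
         "category": d.category, "n_copies": d.n_copies_in_protein}
        for d in all_ids
    ]
    pd.DataFrame(rows).to_csv(outdir / "integrated_domains.tsv", sep="\t", index=False)
    positional_profile(all_ids).to_csv(outdir / "id_profile.tsv", sep="\t", index=False)
    state["integrated_domains"] = all_ids
    return {"n_ids": len(all_ids),
            "n_id_proteins": len({d.protein_id for d in all_ids})}


def _stage_homology(config, outdir, seed, proteome, prot_by_id, genes, transcripts,
                    domain_table, p2g, state):
    targets: dict = config.get("targets") or {}
    if not targets:
        return {"n_hits": 0, "note": "no target proteomes configured"}
    all_ids = state.get("integrated_domains") or []
    loaded = {}
    for species, spec_ in targets.items():
        tp = nio.read_fasta(spec_["proteome"])
        table = nio.read_domain_table(spec_["domains"]) if spec_.get("domains") else []
        loaded[species] = (tp, build_kmer_index(tp), table)
    min_identity = float(config.get("min_identity", 70.0))
    min_coverage = float(config.get("min_coverage", 0.8))
    hits = []
    for d in all_ids:
        qseq = prot_by_id[d.protein_id].sequence[d.domain.start: d.domain.end] \
            if d.protein_id in prot_by_id else None
        if not qseq:
            continue
        for species in sorted(loaded):
            tp, index, _table = loaded[species]
            hits.extend(
                search_homologs(
                    qseq, tp, min_identity=min_identity, min_coverage=min_coverage,
                    species=species, query_protein_id=d.protein_id,
                    query_id_accession=d.domain.accession, kmer_index=index,
                )
            )
    hits = flag_nlr_homologs(hits, {sp: loaded[sp][2] for sp in loaded})
    pd.DataFrame([h.__dict__ for h in hits]).to_csv(
        outdir / "homology_hits.tsv", sep="\t", index=False
    )
    nlr_homolog_fraction(hits).to_csv(outdir / "homology_species.tsv", sep="\t", index=False)

    assignments = []
    if {"TU", "AT"} & set(loaded):
        gene_best: dict[str, dict[str, float]] = {}
        for h in hits:
            if h.subject_species in ("TU", "AT"):
                gid = p2g.get(h.query_protein_id, h.query_protein_id)
                d = gene_best.setdefault(gid, {"TU": 0.0, "AT": 0.0})
                d[h.subject_species] = max(d[h.subject_species], h.pct_identity)
        gene_by_id = {g.gene_id: g for g in genes}
        id_genes = sorted({p2g.get(d.protein_id, d.protein_id) for d in all_ids})
        for gid in id_genes:
            if gid not in gene_by_id:
                continue
            best = gene_best.get(gid, {"TU": 0.0, "AT": 0.0})
            assignments.append(
                assign_progenitor_category(gene_by_id[gid], best["TU"], best["AT"])
            )
        pd.DataFrame([a.__dict__ for a in assignments]).to_csv(
            outdir / "progenitor_assignments.tsv", sep="\t", index=False
        )
        progenitor_category_table(assignments).to_csv(
            outdir / "progenitor_categories.tsv", sep="\t", index=False
        )
    state["homology_hits"] = hits
    state["progenitor_assignments"] = assignments
    return {"n_hits": len(hits), "n_assignments": len(assignments)}


def _stage_splice(config, outdir, seed, proteome, prot_by_id, genes, transcripts,
                  domain_table, p2g, state):
    hits_by_protein = state.get("hits_by_protein")
    if hits_by_protein is None:
        hits_by_protein = {}
        for h in domain_table:
            hits_by_protein.setdefault(h.protein_id, []).append(h)
    tx_by_id = {t.transcript_id: t for t in transcripts}
    plen = {p.protein_id: p.length for p in proteome}
    nbarc_genes = state.get("nbarc_genes") or {
        p2g.get(p, p) for p in find_nbarc_proteins(domain_table)
    }
    expression = None
    if config.get("expression"):
        expression = pd.read_csv(config["expression"], sep="\t")
    reports = []
    for g in genes:
        if g.gene_id not in nbarc_genes or len(g.transcript_ids) < 2:
            continue
        rep = compare_transcript_domains(
            g,
            {t: hits_by_protein.get(t, []) for t in g.transcript_ids},
            transcripts=tx_by_id,
            protein_lengths=plen,
            truncation_fraction=float(config.get("truncation_fraction", 0.8)),
        )
        if expression is not None:
            rep = join_expression(rep, expression)
        reports.append(rep)
    df = report_to_frame(reports)
    df.to_csv(outdir / "splice_reports.tsv", sep="\t", index=False)
    summary = [
        {"gene_id": r.gene_id, "excluding_variant": r.has_id_excluding_variant()}
        for r in reports
    ]
    nio.write_json(summary, outdir / "splice_summary.json")
    state["splice_reports"] = reports
    return {"n_genes_compared": len(reports),
            "n_genes_with_excluding_variant": sum(s["excluding_variant"] for s in summary)}


_STAGE_FUNCS = {
    "census": _stage_census,
    "cluster": _stage_cluster,
    "ids": _stage_ids,
    "homology": _stage_homology,
    "splice": _stage_splice,
}
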