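"""ID homology across comparator proteomes and progenitor assignment.

A wheat ID subsequence is searched against a target proteome with a
k-mer prefilter (any subject sharing at least one exact k-mer is a
candidate) followed by local affine-gap alignment.  Hits must clear both
a percent-identity and a query-coverage threshold.  For hexaploid wheat,
each ID-bearing gene is then placed in a progenitor category by
comparing its best hits in the two sequenced progenitors (*T. urartu*
for the A subgenome, *Ae. tauschii* for D; the B progenitor is not
sequenced).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .align import align_pair, make_aligner
from .classify import NBARC_ACCESSION
from .io import DomainHit, GeneModel, ProteinRecord

logger = logging.getLogger(__name__)

SPECIES_CODES = ("AT", "AmT", "ArT", "BD", "HV", "MA", "OS", "SI", "TU", "ZM", "TA")

PROGENITOR_OF_SUBGENOME = {"A": "TU", "D": "AT"}

IDENTITY_BINS = (">90", "70-90", "<70")


@dataclass
class HomologyHit:
    query_protein_id: str
    query_id_accession: str
    subject_species: str
    subject_protein_id: str
    pct_identity: float
    coverage: float
    subject_has_nbarc: bool = False


@dataclass(frozen=True)
class SubgenomeAssignment:
    gene_id: str
    subgenome: str
    best_progenitor: str
    category: str
    identity_bin: str


def build_kmer_index(proteome: Sequence[ProteinRecord], k: int = 5) -> dict[str, set[str]]:
    index: dict[str, set[str]] = {}
    for rec in proteome:
        seq = rec.sequence
        for i in range(len(seq) - k + 1):
            index.setdefault(seq[i : i + k], set()).add(rec.protein_id)
    return index


def search_homologs(
    query_seq: str,
    target_proteome: Sequence[ProteinRecord],
    min_identity: float = 70.0,
    min_coverage: float = 0.8,
    k: int = 5,
    species: str = "",
    query_protein_id: str = "",
    query_id_accession: str = "",
    kmer_index: Optional[Mapping[str, set[str]]] = None,
    gap_open: float = 10.0,
    gap_extend: float = 1.0,
) -> list[HomologyHit]:
    """Seed-and-extend homology search for one query (ID subsequence).

    Candidates sharing >= 1 exact k-mer with the query are aligned locally
    (Smith–Waterman, BLOSUM62).  Identity is computed over aligned columns
    and coverage as the fraction of query residues aligned.  Hits passing
    both thresholds are returned sorted by identity (desc), ties by
    subject ID (asc).
    """
    if not target_proteome:
        logger.warning("empty target proteome for species %r", species)
        return []
    by_id = {r.protein_id: r for r in target_proteome}
    if kmer_index is None:
        kmer_index = build_kmer_index(target_proteome, k)
    candidates: set[str] = set()
    for i in range(len(query_seq) - k + 1):
        candidates |= kmer_index.get(query_seq[i : i + k], set())
    aligner = make_aligner("local", "BLOSUM62", gap_open, gap_extend)
    hits: list[HomologyHit] = []
    for sid in sorted(candidates):
        aln = aligner.align(query_seq, by_id[sid].sequence)
        if len(aln) == 0:
            continue
        best = aln[0]
        row_q, row_s = str(best[0]), str(best[1])
        cols = len(row_q)
        ident = sum(1 for x, y in zip(row_q, row_s) if x == y and x != "-")
        pct = 100.0 * ident / cols if cols else 0.0
        q_aligned = sum(1 for x in row_q if x != "-")
        cov = q_aligned / len(query_seq)
        if pct >= min_identity and cov >= min_coverage:
            hits.append(
                HomologyHit(
                    query_protein_id=query_protein_id,
                    query_id_accession=query_id_accession,
                    subject_species=species,
                    subject_protein_id=sid,
                    pct_identity=pct,
                    coverage=cov,
                )
            )
    hits.sort(key=lambda h: (-h.pct_identity, h.subject_protein_id))
    return hits


def flag_nlr_homologs(
    hits: Iterable[HomologyHit],
    subject_domain_tables: Mapping[str, Iterable[DomainHit]],
) -> list[HomologyHit]:
    """Set ``subject_has_nbarc`` from the per-species domain tables."""
    nbarc_by_species: dict[str, set[str]] = {}
    for species, table in subject_domain_tables.items():
        nbarc_by_species[species] = {
            h.protein_id for h in table if h.accession == NBARC_ACCESSION
        }
    out = []
    for h in hits:
        known = nbarc_by_species.get(h.subject_species)
        if known is None:
            logger.warning(
                "no domain table for species %s; NLR flag of %s left false",
                h.subject_species, h.subject_protein_id,
            )
            h.subject_has_nbarc = False
        else:
            h.subject_has_nbarc = h.subject_protein_id in known
        out.append(h)
    return out


def nlr_homolog_fraction(hits: Sequence[HomologyHit]) -> pd.DataFrame:
    """Per-species fraction of homologous subjects that are themselves NLRs."""
    rows = []
    by_species: dict[str, list[HomologyHit]] = {}
    for h in hits:
        by_species.setdefault(h.subject_species, []).append(h)
    for species in sorted(by_species):
        subjects = {h.subject_protein_id: h.subject_has_nbarc for h in by_species[species]}
        n = len(subjects)
        rows.append(
            {
                "species": species,
                "n_homolog_subjects": n,
                "nlr_fraction": sum(subjects.values()) / n if n else 0.0,
            }
        )
    return pd.DataFrame(rows)


def _identity_bin(identity: float) -> str:
    if identity > 90.0:
        return ">90"
    if identity >= 70.0:
        return "70-90"
    return "<70"


def assign_progenitor_category(
    gene: GeneModel,
    tu_best_identity: float,
    at_best_identity: float,
) -> SubgenomeAssignment:
    """Progenitor–subgenome category for one ID-bearing gene.

    A/D-subgenome genes are "Match" when the better progenitor hit comes
    from the expected progenitor (A<->TU, D<->AT; the expected progenitor
    wins ties), otherwise the mismatching label "A" (an A gene closest to
    *Ae. tauschii*) or "D" (a D gene closest to *T. urartu*).  B-subgenome
    genes are always "B" (no sequenced progenitor); unknown subgenomes
    are "U".
    """
    sub = gene.subgenome
    if sub == "B":
        best = max(tu_best_identity, at_best_identity)
        return SubgenomeAssignment(gene.gene_id, "B", "none", "B", _identity_bin(best))
    if sub not in ("A", "D"):
        best = max(tu_best_identity, at_best_identity)
        return SubgenomeAssignment(gene.gene_id, "unknown", "none", "U", _identity_bin(best))
    expected = PROGENITOR_OF_SUBGENOME[sub]
    if tu_best_identity == at_best_identity == 0.0:
        return SubgenomeAssignment(gene.gene_id, sub, "none", _no_hit_category(sub), "<70")
    if expected == "TU":
        best_prog = "TU" if tu_best_identity >= at_best_identity else "AT"
    else:
        best_prog = "AT" if at_best_identity >= tu_best_identity else "TU"
    best = max(tu_best_identity, at_best_identity)
    if best_prog == expected:
        category = "Match"
    else:
        # the observed (mismatching) pattern is labeled by the gene's subgenome
        category = sub
    return SubgenomeAssignment(gene.gene_id, sub, best_prog, category, _identity_bin(best))


def _no_hit_category(sub: str) -> str:
    # no hits in either progenitor: category follows the subgenome with the
    # lowest identity bin ("Match" cannot be claimed without evidence)
    return sub


def progenitor_category_table(assignments: Sequence[SubgenomeAssignment]) -> pd.DataFrame:
    df = pd.DataFrame([a.__dict__ for a in assignments])
    if df.empty:
        return pd.DataFrame(columns=["category", "identity_bin", "n"])
    return (
        df.groupby(["category", "identity_bin"], as_index=False)
        .agg(n=("gene_id", "size"))
        .sort_values(["category", "identity_bin"], kind="stable")
        .reset_index(drop=True)
    )
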