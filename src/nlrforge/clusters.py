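"""Physical clustering of NB-ARC genes.

Two consecutive NB-ARC genes on a chromosome are linked when the gap
between them (end of the upstream gene to start of the downstream gene)
is at most ``max_gap_bp`` and at most ``max_intervening`` non-NB-ARC
genes lie strictly between them.  Clusters are the maximal chains of
linked genes; singletons are not emitted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pandas as pd

from .align import PairwiseAlignmentResult
from .io import GeneModel, to_external, to_internal

logger = logging.getLogger(__name__)

SIMILARITY_BINS = ("<50%", "<75%", "<100%", "100%")


@dataclass
class GeneCluster:
    cluster_id: str
    chromosome: str
    member_gene_ids: list[str]
    start: int
    end: int

    @property
    def n_members(self) -> int:
        return len(self.member_gene_ids)

    @property
    def span(self) -> int:
        return self.end - self.start


def detect_clusters(
    nbarc_gene_ids: Iterable[str],
    all_genes: Sequence[GeneModel],
    max_gap_bp: int = 200_000,
    max_intervening: int = 7,
    all_pairs: bool = False,
) -> list[GeneCluster]:
    """Maximal chains of linked NB-ARC genes per chromosome.

    ``all_genes`` supplies the intervening-gene counts; NB-ARC genes never
    count as intervening.  With ``all_pairs`` the link test is applied to
    every NB-ARC pair within a chromosome (transitively closed), not only
    consecutive ones — a sensitivity-analysis mode.
    """
    nbarc = set(nbarc_gene_ids)
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in all_genes:
        if not g.chromosome:
            logger.warning("gene %s has no chromosome name; skipped", g.gene_id)
            continue
        by_chrom.setdefault(g.chromosome, []).append(g)

    clusters: list[GeneCluster] = []
    for chrom in sorted(by_chrom):
        genes = sorted(by_chrom[chrom], key=lambda g: (g.start, g.end, g.gene_id))
        nb = [g for g in genes if g.gene_id in nbarc]
        if len(nb) < 2:
            continue
        order = {g.gene_id: i for i, g in enumerate(genes)}

        def linked(a: GeneModel, b: GeneModel) -> bool:
            gap = b.start - a.end
            intervening = sum(
                1
                for k in range(order[a.gene_id] + 1, order[b.gene_id])
                if genes[k].gene_id not in nbarc
            )
            return gap <= max_gap_bp and intervening <= max_intervening

        # chain construction == connected components of the link graph on
        # consecutive NB-ARC genes
        pairs = (
            [(i, j) for i in range(len(nb)) for j in range(i + 1, len(nb))]
            if all_pairs
            else [(i, i + 1) for i in range(len(nb) - 1)]
        )
        parent = list(range(len(nb)))

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for i, j in pairs:
            if linked(nb[i], nb[j]):
                parent[find(i)] = find(j)
        comps: dict[int, list[GeneModel]] = {}
        for i, g in enumerate(nb):
            comps.setdefault(find(i), []).append(g)
        for members in comps.values():
            if len(members) < 2:
                continue
            members.sort(key=lambda g: (g.start, g.gene_id))
            clusters.append(
                GeneCluster(
                    cluster_id="",
                    chromosome=chrom,
                    member_gene_ids=[g.gene_id for g in members],
                    start=min(g.start for g in members),
                    end=max(g.end for g in members),
                )
            )
    clusters.sort(key=lambda c: (c.chromosome, c.start))
    for i, c in enumerate(clusters, 1):
        c.cluster_id = f"cluster_{i:04d}"
    return clusters


def similarity_bins(results: Iterable[PairwiseAlignmentResult]) -> pd.DataFrame:
    """Assign each pairwise identity to one of four bins.

    Bins follow the within-cluster similarity display convention:
    [0, 50) -> "<50%", [50, 75) -> "<75%", [75, 100) -> "<100%",
    exactly 100 -> "100%".
    """
    rows = []
    for r in results:
        if r.pct_identity >= 100.0:
            b = "100%"
        elif r.pct_identity >= 75.0:
            b = "<100%"
        elif r.pct_identity >= 50.0:
            b = "<75%"
        else:
            b = "<50%"
        rows.append((r.id_a, r.id_b, r.pct_identity, b))
    return pd.DataFrame(rows, columns=["id_a", "id_b", "pct_identity", "bin"])


# ---------------------------------------------------------------------------
# TSV / BED round-trip
# ---------------------------------------------------------------------------

def write_clusters_tsv(clusters: Sequence[GeneCluster], path) -> None:
    with open(path, "w") as fh:
        fh.write("cluster_id\tchromosome\tstart\tend\tn_members\tmembers\n")
        for c in clusters:
            s, e = to_external(c.start, c.end)
            fh.write(
                f"{c.cluster_id}\t{c.chromosome}\t{s}\t{e}\t{c.n_members}\t"
                + ",".join(c.member_gene_ids)
                + "\n"
            )


def read_clusters_tsv(path) -> list[GeneCluster]:
    out = []
    with open(path) as fh:
        header = fh.readline()
        assert header.startswith("cluster_id")
        for line in fh:
            cid, chrom, s, e, _n, members = line.rstrip("\n").split("\t")
            start, end = to_internal(int(s), int(e))
            out.append(GeneCluster(cid, chrom, members.split(","), start, end))
    return out


def clusters_to_bed(clusters: Sequence[GeneCluster]) -> list[tuple[str, int, int, str]]:
    return [(c.chromosome, c.start, c.end, c.cluster_id) for c in clusters]
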