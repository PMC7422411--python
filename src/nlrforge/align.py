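"""Pairwise alignment and a small guide-tree progressive aligner.

Percent identity between clustered paralogs is computed from an optimal
affine-gap pairwise alignment (global by default, local on request).
The gap cost convention is ``gap_open + (L - 1) * gap_extend`` for a gap
of length L.  The identity denominator is the number of aligned columns
including gap columns; a ``shorter`` denominator (length of the shorter
sequence) is available for local-style comparisons.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

logger = logging.getLogger(__name__)

_NONSTANDARD = re.compile(r"[^ACDEFGHIKLMNPQRSTVWYX*]")


@dataclass(frozen=True)
class PairwiseAlignmentResult:
    id_a: str
    id_b: str
    score: float
    aligned_cols: int
    identities: int
    pct_identity: float


def _sanitize(seq: str, label: str) -> str:
    if _NONSTANDARD.search(seq):
        logger.warning("non-amino-acid symbols in %s treated as X", label)
        seq = _NONSTANDARD.sub("X", seq)
    return seq


def make_aligner(
    mode: str = "global",
    matrix: str | object = "BLOSUM62",
    gap_open: float = 10.0,
    gap_extend: float = 1.0,
) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    if isinstance(matrix, str):
        matrix = substitution_matrices.load(matrix)
    aligner.substitution_matrix = matrix
    aligner.open_gap_score = -float(gap_open)
    aligner.extend_gap_score = -float(gap_extend)
    return aligner


def simple_matrix(alphabet: str, match: float = 1.0, mismatch: float = 0.0):
    """A match/mismatch substitution matrix over an arbitrary alphabet."""
    n = len(alphabet)
    arr = np.full((n, n), mismatch)
    np.fill_diagonal(arr, match)
    return substitution_matrices.Array(alphabet=alphabet, dims=2, data=arr)


def align_pair(
    seq_a: str,
    seq_b: str,
    mode: str = "global",
    matrix: str | object = "BLOSUM62",
    gap_open: float = 10.0,
    gap_extend: float = 1.0,
    id_a: str = "a",
    id_b: str = "b",
    denominator: str = "columns",
) -> PairwiseAlignmentResult:
    """Optimal affine-gap alignment with percent identity.

    ``denominator`` is "columns" (aligned columns including gaps, the
    default) or "shorter" (length of the shorter input).
    """
    if not seq_a or not seq_b:
        raise ValueError("cannot align an empty sequence")
    seq_a = _sanitize(seq_a.upper(), id_a)
    seq_b = _sanitize(seq_b.upper(), id_b)
    # co-optimal alignments can differ between (a,b) and (b,a); aligning in a
    # canonical sequence order makes the reported identity symmetric
    if seq_b < seq_a:
        swapped = align_pair(seq_b, seq_a, mode, matrix, gap_open, gap_extend,
                             id_b, id_a, denominator)
        return PairwiseAlignmentResult(
            id_a, id_b, swapped.score, swapped.aligned_cols,
            swapped.identities, swapped.pct_identity,
        )
    aligner = make_aligner(mode, matrix, gap_open, gap_extend)
    alignments = aligner.align(seq_a, seq_b)
    aln = alignments[0]
    row_a, row_b = str(aln[0]), str(aln[1])
    cols = len(row_a)
    ident = sum(1 for x, y in zip(row_a, row_b) if x == y and x != "-")
    denom = min(len(seq_a), len(seq_b)) if denominator == "shorter" else cols
    pct = 100.0 * ident / denom if denom else 0.0
    return PairwiseAlignmentResult(id_a, id_b, float(aln.score), cols, ident, pct)


def identity_distance_matrix(
    sequences: Mapping[str, str], **align_kwargs
) -> tuple[np.ndarray, list[str]]:
    """Pairwise distance 1 - identity/100 for all sequence pairs."""
    labels = list(sequences)
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            r = align_pair(
                sequences[labels[i]], sequences[labels[j]],
                id_a=labels[i], id_b=labels[j], **align_kwargs,
            )
            d[i, j] = d[j, i] = 1.0 - r.pct_identity / 100.0
    return d, labels


# ---------------------------------------------------------------------------
# progressive multiple alignment
# ---------------------------------------------------------------------------

def _consensus(rows: Sequence[str]) -> str:
    """Per-column majority residue (gaps excluded; all-gap columns -> X)."""
    out = []
    for col in zip(*rows):
        residues = [c for c in col if c != "-"]
        if not residues:
            out.append("X")
        else:
            counts: dict[str, int] = {}
            for c in residues:
                counts[c] = counts.get(c, 0) + 1
            out.append(max(sorted(counts), key=lambda c: counts[c]))
    return "".join(out)


def _merge_groups(rows_a: list[str], rows_b: list[str], aligner) -> tuple[list[str], list[str]]:
    """Align two sub-alignments via their consensus strings and propagate gaps."""
    ca, cb = _consensus(rows_a), _consensus(rows_b)
    aln = aligner.align(ca, cb)[0]
    ga, gb = str(aln[0]), str(aln[1])

    def expand(rows: list[str], gapped_consensus: str) -> list[str]:
        out = []
        for row in rows:
            it = iter(row)
            out.append("".join("-" if c == "-" else next(it) for c in gapped_consensus))
        return out

    return expand(rows_a, ga), expand(rows_b, gb)


def progressive_align(
    sequences: Mapping[str, str],
    guide_order: Optional[Sequence[tuple[str, str]]] = None,
    **align_kwargs,
) -> dict[str, str]:
    """Progressive multiple alignment guided by a neighbor-joining tree.

    Sub-alignments are merged along the guide tree's join order; each
    merge aligns the two groups' consensus strings with the same affine
    DP used for pairwise comparisons and propagates the resulting gap
    columns into every member row.  Adequate for distance estimation and
    bootstrap column resampling; not a ClustalW replacement for curation.
    """
    from .trees import neighbor_joining  # deferred: trees imports align

    labels = list(sequences)
    if len(labels) == 1:
        return {labels[0]: sequences[labels[0]]}
    aligner = make_aligner(
        mode="global",
        matrix=align_kwargs.get("matrix", "BLOSUM62"),
        gap_open=align_kwargs.get("gap_open", 10.0),
        gap_extend=align_kwargs.get("gap_extend", 1.0),
    )
    if guide_order is None:
        if len(labels) == 2:
            guide_order = [(labels[0], labels[1])]
        else:
            d, labs = identity_distance_matrix(sequences, **align_kwargs)
            tree = neighbor_joining(d, labs)
            guide_order = tree.join_order()
    group_of: dict[str, int] = {lab: i for i, lab in enumerate(labels)}
    groups: dict[int, tuple[list[str], list[str]]] = {
        i: ([lab], [sequences[lab]]) for i, lab in enumerate(labels)
    }
    for a, b in guide_order:
        ga, gb = group_of[a], group_of[b]
        if ga == gb:
            continue
        names_a, rows_a = groups.pop(ga)
        names_b, rows_b = groups.pop(gb)
        rows_a, rows_b = _merge_groups(rows_a, rows_b, aligner)
        new_id = min(ga, gb)
        groups[new_id] = (names_a + names_b, rows_a + rows_b)
        for name in names_a + names_b:
            group_of[name] = new_id
    while len(groups) > 1:  # guide order may not connect everything
        ids = sorted(groups)
        names_a, rows_a = groups.pop(ids[0])
        names_b, rows_b = groups.pop(ids[1])
        rows_a, rows_b = _merge_groups(rows_a, rows_b, aligner)
        groups[ids[0]] = (names_a + names_b, rows_a + rows_b)
    names, rows = next(iter(groups.values()))
    return {n: r for n, r in zip(names, rows)}
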