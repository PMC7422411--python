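"""Alternative-transcript comparison: ID exclusion, truncation, intron retention.

For each gene the reference transcript is the isoform with the richest
domain content (most distinct accessions; ties broken by the longest
protein).  Every other transcript is compared against it: a reference ID
accession absent from the variant is *excluded*; present but shorter
than a configurable fraction of the reference instance it is
*truncated*.  Intron retention is read from exon geometry: a reference
intron fully covered by an exon of the variant is retained.  Intron
indices are 1-based in transcription order (5'->3').
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .classify import DEFAULT_CORE_ACCESSIONS, NBARC_ACCESSION
from .io import DomainHit, GeneModel, TranscriptModel

logger = logging.getLogger(__name__)

TRANSCRIPT_CLASSES = ("NLR-ID", "NLR-only", "ID-only", "neither")


@dataclass
class TranscriptRow:
    transcript_id: str
    domain_content: list[tuple[str, int, int]]
    transcript_class: str
    is_reference: bool = False
    excluded_ids: list[str] = field(default_factory=list)
    truncated_ids: list[str] = field(default_factory=list)
    retained_introns: list[int] = field(default_factory=list)
    expression: Optional[dict[str, float]] = None

    @property
    def id_excluded(self) -> bool:
        return bool(self.excluded_ids)

    @property
    def id_truncated(self) -> bool:
        return bool(self.truncated_ids)


@dataclass
class SpliceVariantReport:
    gene_id: str
    reference_transcript_id: str
    rows: list[TranscriptRow]

    def has_id_excluding_variant(self) -> bool:
        return any(r.id_excluded for r in self.rows if not r.is_reference)


def _transcript_class(accessions: set[str], core: Mapping[str, frozenset[str]]) -> str:
    all_core = frozenset().union(*core.values())
    has_nbarc = bool(accessions & core["NBARC"])
    has_id = bool(accessions - all_core)
    if has_nbarc and has_id:
        return "NLR-ID"
    if has_nbarc:
        return "NLR-only"
    if has_id:
        return "ID-only"
    return "neither"


def detect_retained_introns(
    transcript: TranscriptModel,
    reference_transcript: TranscriptModel,
) -> list[int]:
    """Reference intron indices fully covered by an exon of ``transcript``.

    Indices count introns 1..n in transcription order of the reference.
    Transcripts on different strands are an error.
    """
    if transcript.strand != reference_transcript.strand:
        raise ValueError(
            f"transcripts {transcript.transcript_id} and "
            f"{reference_transcript.transcript_id} are on different strands"
        )
    ref_exons = reference_transcript.exons_transcription_order()
    minus = reference_transcript.strand == "-"
    introns = []
    for i in range(len(ref_exons) - 1):
        a, b = ref_exons[i], ref_exons[i + 1]
        lo, hi = (b[1], a[0]) if minus else (a[1], b[0])
        introns.append((i + 1, lo, hi))
    retained = [
        idx
        for idx, lo, hi in introns
        if any(es <= lo and hi <= ee for es, ee in transcript.exons)
    ]
    return sorted(retained)


def compare_transcript_domains(
    gene: GeneModel,
    hits_by_transcript: Mapping[str, Sequence[DomainHit]],
    transcripts: Optional[Mapping[str, TranscriptModel]] = None,
    protein_lengths: Optional[Mapping[str, int]] = None,
    core_accessions: Mapping[str, frozenset[str]] = DEFAULT_CORE_ACCESSIONS,
    truncation_fraction: float = 0.8,
) -> SpliceVariantReport:
    """Per-gene comparison of each transcript's domain content.

    ``hits_by_transcript`` maps transcript IDs to the domain hits of the
    isoform's protein.  When transcript models with exon coordinates are
    supplied, retained introns relative to the reference are reported too.
    A single-transcript gene yields a report with no comparisons.
    """
    tids = [t for t in gene.transcript_ids if t in hits_by_transcript] or list(
        gene.transcript_ids
    )
    if not tids:
        raise ValueError(f"gene {gene.gene_id} has no transcripts")
    all_core = frozenset().union(*core_accessions.values())

    def plen(tid: str) -> int:
        if protein_lengths and tid in protein_lengths:
            return protein_lengths[tid]
        return max((h.end for h in hits_by_transcript.get(tid, [])), default=0)

    def richness(tid: str):
        accs = {h.accession for h in hits_by_transcript.get(tid, []) if h.is_pfam()}
        # full ties resolve to the earliest transcript in gene order
        return (len(accs), plen(tid), -tids.index(tid))

    ref_tid = max(tids, key=richness)
    ref_hits = list(hits_by_transcript.get(ref_tid, []))
    ref_ids = [h for h in ref_hits if h.is_pfam() and h.accession not in all_core]

    rows = []
    for tid in tids:
        hits = list(hits_by_transcript.get(tid, []))
        accs = {h.accession for h in hits if h.is_pfam()}
        row = TranscriptRow(
            transcript_id=tid,
            domain_content=sorted((h.accession, h.start, h.end) for h in hits),
            transcript_class=_transcript_class(accs, core_accessions),
            is_reference=(tid == ref_tid),
        )
        if tid != ref_tid:
            for ref_id in ref_ids:
                matching = [h for h in hits if h.accession == ref_id.accession]
                if not matching:
                    if ref_id.accession not in row.excluded_ids:
                        row.excluded_ids.append(ref_id.accession)
                else:
                    best_len = max(h.length for h in matching)
                    if best_len < truncation_fraction * ref_id.length:
                        if ref_id.accession not in row.truncated_ids:
                            row.truncated_ids.append(ref_id.accession)
            # excluded and truncated are mutually exclusive per accession
            row.truncated_ids = [a for a in row.truncated_ids if a not in row.excluded_ids]
            if transcripts and tid in transcripts and ref_tid in transcripts:
                row.retained_introns = detect_retained_introns(
                    transcripts[tid], transcripts[ref_tid]
                )
        rows.append(row)
    return SpliceVariantReport(gene.gene_id, ref_tid, rows)


def join_expression(
    report: SpliceVariantReport,
    expression_table: pd.DataFrame,
) -> SpliceVariantReport:
    """Attach per-transcript expression vectors from a transcript-keyed table.

    Transcripts absent from the table receive null vectors; if no
    transcript overlaps the table at all, the report is returned
    unmodified with a warning.
    """
    table = expression_table
    if "transcript_id" in table.columns:
        table = table.set_index("transcript_id")
    present = [r.transcript_id for r in report.rows if r.transcript_id in table.index]
    if not present:
        logger.warning(
            "no transcripts of gene %s found in the expression table", report.gene_id
        )
        return report
    n_missing = 0
    for row in report.rows:
        if row.transcript_id in table.index:
            row.expression = {
                str(c): float(v) for c, v in table.loc[row.transcript_id].items()
            }
        else:
            row.expression = None
            n_missing += 1
    if n_missing:
        logger.info("%d transcripts of %s missing expression", n_missing, report.gene_id)
    return report


def report_to_frame(reports: Iterable[SpliceVariantReport]) -> pd.DataFrame:
    rows = []
    for rep in reports:
        for r in rep.rows:
            rows.append(
                {
                    "gene_id": rep.gene_id,
                    "transcript_id": r.transcript_id,
                    "is_reference": r.is_reference,
                    "class": r.transcript_class,
                    "excluded_ids": ",".join(r.excluded_ids),
                    "truncated_ids": ",".join(r.truncated_ids),
                    "retained_introns": ",".join(map(str, r.retained_introns)),
                }
            )
    return pd.DataFrame(rows)
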