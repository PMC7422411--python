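"""Readers, writers and the internal coordinate convention.

Every coordinate held in memory is 0-based half-open.  Conversion to and
from the 1-based inclusive convention used by FASTA-adjacent tables, GFF3
and InterProScan TSV happens only here, at the I/O boundary.  BED output
is 0-based half-open by definition and therefore passes coordinates
through unchanged.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Optional, Sequence

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX*")

PFAM_RE = re.compile(r"^PF\d{5}$")

# chromosome names like "4A", "chr1D", "Chr3B" carry the subgenome letter
_SUBGENOME_RE = re.compile(r"(\d+)([ABD])$")


def to_internal(start: int, end: int) -> tuple[int, int]:
    """1-based inclusive -> 0-based half-open."""
    return start - 1, end


def to_external(start: int, end: int) -> tuple[int, int]:
    """0-based half-open -> 1-based inclusive."""
    return start + 1, end


# ---------------------------------------------------------------------------
# record types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence; ``length`` always equals ``len(sequence)``."""

    protein_id: str
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class GeneModel:
    """A gene locus.  ``start``/``end`` are internal (0-based half-open)."""

    gene_id: str
    chromosome: str
    start: int
    end: int
    strand: str
    transcript_ids: list[str] = field(default_factory=list)

    @property
    def subgenome(self) -> str:
        """Subgenome letter (A/B/D) parsed from the chromosome name."""
        m = _SUBGENOME_RE.search(self.chromosome)
        return m.group(2) if m else "unknown"


@dataclass
class TranscriptModel:
    """One transcript; exons and CDS segments are genomic, internal coords."""

    transcript_id: str
    gene_id: str
    strand: str
    exons: list[tuple[int, int]] = field(default_factory=list)
    cds_segments: list[tuple[int, int, int]] = field(default_factory=list)
    protein_id: Optional[str] = None

    def exons_transcription_order(self) -> list[tuple[int, int]]:
        ex = sorted(self.exons)
        return ex if self.strand != "-" else ex[::-1]


@dataclass(frozen=True)
class DomainHit:
    """One annotated domain interval on a protein (internal coordinates)."""

    protein_id: str
    accession: str
    name: str
    start: int
    end: int
    source: str = "Pfam"
    score: Optional[float] = None

    @property
    def length(self) -> int:
        return self.end - self.start

    def is_pfam(self) -> bool:
        return self.source == "Pfam" and bool(PFAM_RE.match(self.accession))


class DomainTable(list):
    """List of :class:`DomainHit` that remembers how many rows were rejected."""

    n_rejected: int = 0


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a protein FASTA; IDs are the first whitespace-delimited token.

    Duplicate IDs raise ``ValueError``; an empty file yields an empty list
    with a warning.
    """
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate protein ID in {path}: {rec.id!r}")
        seen.add(rec.id)
        records.append(ProteinRecord(rec.id, str(rec.seq).upper()))
    if not records:
        logger.warning("no FASTA records found in %s", path)
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    seqs = [SeqRecord(Seq(r.sequence), id=r.protein_id, description="") for r in records]
    SeqIO.write(seqs, str(path), "fasta")


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def read_gff3(path: str | Path) -> tuple[list[GeneModel], list[TranscriptModel]]:
    """Parse gene/mRNA/exon/CDS features into gene and transcript models.

    An mRNA whose Parent gene is absent from the file is wrapped in a
    synthesized single-transcript gene (with a warning).  A CDS segment
    not contained in any exon of its transcript is an error, as is an
    unknown strand symbol.
    """
    genes: dict[str, GeneModel] = {}
    transcripts: dict[str, TranscriptModel] = {}
    mrna_parent: dict[str, str] = {}

    feats = list(gffutils.iterators.DataIterator(str(path)))
    for f in feats:
        if f.strand not in ("+", "-", "."):
            raise ValueError(f"unknown strand symbol {f.strand!r} in {path}")

    def attr(f, key):
        vals = f.attributes.get(key, [])
        return vals[0] if vals else None

    for f in feats:
        if f.featuretype == "gene":
            gid = attr(f, "ID") or f"gene:{f.seqid}:{f.start}"
            s, e = to_internal(f.start, f.end)
            genes[gid] = GeneModel(gid, f.seqid, s, e, f.strand)
    for f in feats:
        if f.featuretype in ("mRNA", "transcript"):
            tid = attr(f, "ID") or f"mrna:{f.seqid}:{f.start}"
            parent = attr(f, "Parent")
            if parent is None or parent not in genes:
                # orphan mRNA: synthesize a host gene
                logger.warning("mRNA %s has no gene parent; synthesizing one", tid)
                parent = f"{tid}.gene"
                s, e = to_internal(f.start, f.end)
                genes[parent] = GeneModel(parent, f.seqid, s, e, f.strand)
            transcripts[tid] = TranscriptModel(tid, parent, f.strand)
            mrna_parent[tid] = parent
            genes[parent].transcript_ids.append(tid)
    for f in feats:
        if f.featuretype in ("exon", "CDS"):
            parent = attr(f, "Parent")
            if parent not in transcripts:
                continue
            s, e = to_internal(f.start, f.end)
            if f.featuretype == "exon":
                transcripts[parent].exons.append((s, e))
            else:
                phase = int(f.frame) if f.frame not in (None, ".") else 0
                transcripts[parent].cds_segments.append((s, e, phase))

    for t in transcripts.values():
        t.exons.sort()
        t.cds_segments.sort()
        for cs, ce, _ in t.cds_segments:
            if not any(es <= cs and ce <= ee for es, ee in t.exons):
                raise ValueError(
                    f"CDS segment {cs + 1}..{ce} of {t.transcript_id} not contained in any exon"
                )

    gene_list = sorted(genes.values(), key=lambda g: (g.chromosome, g.start, g.gene_id))
    tx_list = sorted(transcripts.values(), key=lambda t: t.transcript_id)
    return gene_list, tx_list


def write_gff3(
    genes: Sequence[GeneModel],
    transcripts: Sequence[TranscriptModel],
    path: str | Path,
) -> None:
    """Write gene/mRNA/exon/CDS features (1-based inclusive on disk)."""
    by_gene: dict[str, list[TranscriptModel]] = {}
    for t in transcripts:
        by_gene.setdefault(t.gene_id, []).append(t)
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda g: (g.chromosome, g.start, g.gene_id)):
            gs, ge = to_external(g.start, g.end)
            fh.write(
                f"{g.chromosome}\tnlrforge\tgene\t{gs}\t{ge}\t.\t{g.strand}\t.\tID={g.gene_id}\n"
            )
            for t in sorted(by_gene.get(g.gene_id, []), key=lambda t: t.transcript_id):
                if t.exons:
                    ts, te = to_external(min(s for s, _ in t.exons), max(e for _, e in t.exons))
                else:
                    ts, te = gs, ge
                fh.write(
                    f"{g.chromosome}\tnlrforge\tmRNA\t{ts}\t{te}\t.\t{g.strand}\t.\t"
                    f"ID={t.transcript_id};Parent={g.gene_id}\n"
                )
                for es, ee in sorted(t.exons):
                    xs, xe = to_external(es, ee)
                    fh.write(
                        f"{g.chromosome}\tnlrforge\texon\t{xs}\t{xe}\t.\t{g.strand}\t.\t"
                        f"Parent={t.transcript_id}\n"
                    )
                for cs, ce, phase in sorted(t.cds_segments):
                    xs, xe = to_external(cs, ce)
                    fh.write(
                        f"{g.chromosome}\tnlrforge\tCDS\t{xs}\t{xe}\t.\t{g.strand}\t{phase}\t"
                        f"Parent={t.transcript_id}\n"
                    )


# ---------------------------------------------------------------------------
# InterProScan-style domain tables
# ---------------------------------------------------------------------------

def read_domain_table(
    path: str | Path,
    proteome: Optional[Sequence[ProteinRecord]] = None,
) -> DomainTable:
    """Read a domain annotation TSV into a :class:`DomainTable`.

    Two dialects are auto-detected by column count: the full InterProScan 5
    layout (protein id in column 1, analysis in 4, accession in 5,
    description in 6, start in 7, end in 8) and a reduced 5-column layout
    (id, accession, name, start, end; an optional 6th column is the
    source).  Rows with end < start, unparseable fields, or (when a
    proteome is supplied) coordinates beyond the protein length are
    rejected with a warning and counted in ``table.n_rejected``.
    """
    lengths = {p.protein_id: p.length for p in proteome} if proteome is not None else None
    table = DomainTable()
    n_rejected = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if cols[0] == "protein_id":  # header row of the reduced dialect
                continue
            try:
                if len(cols) >= 9:
                    pid, source, acc, name = cols[0], cols[3], cols[4], cols[5]
                    start, end = int(cols[6]), int(cols[7])
                    score = None
                    if len(cols) >= 9 and cols[8] not in ("", "-", "."):
                        try:
                            score = float(cols[8])
                        except ValueError:
                            score = None
                elif len(cols) in (5, 6):
                    pid, acc, name = cols[0], cols[1], cols[2]
                    start, end = int(cols[3]), int(cols[4])
                    source = cols[5] if len(cols) == 6 else "Pfam"
                    score = None
                else:
                    raise ValueError(f"unrecognized column count {len(cols)}")
                if end < start:
                    raise ValueError("end < start")
                if lengths is not None and pid in lengths and end > lengths[pid]:
                    raise ValueError("hit extends past protein end")
                s, e = to_internal(start, end)
                table.append(DomainHit(pid, acc, name, s, e, source=source, score=score))
            except ValueError as exc:
                n_rejected += 1
                logger.warning("rejected row %d of %s: %s", lineno, path, exc)
    table.n_rejected = n_rejected
    return table


def write_domain_tsv(hits: Iterable[DomainHit], path: str | Path) -> None:
    """Write hits in the reduced 6-column dialect (1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("protein_id\taccession\tname\tstart\tend\tsource\n")
        for h in hits:
            s, e = to_external(h.start, h.end)
            fh.write(f"{h.protein_id}\t{h.accession}\t{h.name}\t{s}\t{e}\t{h.source}\n")


# ---------------------------------------------------------------------------
# generic writers
# ---------------------------------------------------------------------------

def write_bed(intervals: Iterable[tuple[str, int, int, str]], path: str | Path) -> None:
    """Write (chrom, start, end, name) tuples already in 0-based half-open."""
    with open(path, "w") as fh:
        for chrom, start, end, name in intervals:
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\n")


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def _json_default(obj):
    try:
        return asdict(obj)
    except TypeError:
        return str(obj)


def domain_hits_to_bed(hits: Iterable[DomainHit]) -> list[tuple[str, int, int, str]]:
    return [(h.protein_id, h.start, h.end, h.accession) for h in hits]


def write_outputs(objects, fmt: str, path: str | Path) -> None:
    """Dispatching writer for the formats the pipeline emits.

    ``fmt`` is one of TSV, JSON, BED, Newick (case-insensitive).  Unknown
    formats raise ``ValueError``.
    """
    fmt = fmt.upper()
    if not isinstance(objects, (list, tuple)) and not hasattr(objects, "to_newick"):
        objects = list(objects)
    if fmt == "JSON":
        write_json(objects, path)
    elif fmt == "NEWICK":
        with open(path, "w") as fh:
            fh.write(objects.to_newick() + "\n")
    elif fmt == "BED":
        if objects and isinstance(objects[0], DomainHit):
            write_bed(domain_hits_to_bed(objects), path)
        else:
            write_bed(objects, path)
    elif fmt == "TSV":
        if isinstance(objects, DomainTable) or (objects and isinstance(objects[0], DomainHit)):
            write_domain_tsv(objects, path)
        else:
            _write_generic_tsv(objects, path)
    else:
        raise ValueError(f"unknown output format: {fmt}")


def _write_generic_tsv(objects, path: str | Path) -> None:
    import pandas as pd

    if not objects:
        Path(path).write_text("\n")
        return
    rows = [asdict(o) if hasattr(o, "__dataclass_fields__") else dict(o) for o in objects]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_id_map(path: str | Path) -> dict[str, str]:
    """Two-column TSV mapping transcript/protein IDs between naming schemes."""
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 2 and parts[0] != "from":
                mapping[parts[0]] = parts[1]
    return mapping
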