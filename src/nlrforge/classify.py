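"""NB-ARC identification, motif scanning and NLR architecture classes.

NLR proteins are recognized purely from the domain-annotation table: any
protein with an NB-ARC (Pfam PF00931) hit is an NLR candidate.  Its
architecture class is composed from the N-terminal domain (coiled-coil,
TIR or RPW8), the NB-ARC, and the presence of leucine-rich repeats:
CNL/TNL/RNL with LRRs, CN/TN/RN without, NL/N when no N-terminal
signaling domain is annotated.  Motif completeness of the NB-ARC
(Walker-A P-loop, Walker-B Kinase-2, and the GLPL loop) is checked with
configurable regular expressions inside the NB-ARC interval.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .io import DomainHit, GeneModel, ProteinRecord

logger = logging.getLogger(__name__)

NBARC_ACCESSION = "PF00931"

#: Accession sets defining the canonical NLR domains.  Only the NB-ARC
#: accession is universal; the remaining sets are curated defaults and are
#: fully overrideable through configuration.
DEFAULT_CORE_ACCESSIONS: dict[str, frozenset[str]] = {
    "NBARC": frozenset({NBARC_ACCESSION}),
    "TIR": frozenset({"PF01582", "PF13676"}),
    "RPW8": frozenset({"PF05659"}),
    "CC": frozenset({"PF18052"}),
    "LRR": frozenset({"PF00560", "PF07725", "PF12799", "PF13306", "PF13855", "PF08263"}),
}

#: Domain-name keywords that also count as a coiled-coil call when the
#: annotation table carries non-Pfam coiled-coil predictions.
CC_NAME_KEYWORDS = ("rx-cc_like", "coiled-coil", "coiled coil")

#: Walker-A / Walker-B / GLPL-loop patterns.  Literature consensus forms;
#: the defaults accept the canonical plant NB-ARC P-loop ``GGVGKTT``.
DEFAULT_MOTIF_PATTERNS: dict[str, str] = {
    "P-loop": r"G.{1,4}GK[ST]",
    "Kinase-2": r"[LIVMF]{2}.{2}[DE]D.[WD]",
    "GLPL": r"G[LIVMF]P[LS]",
}

CLASS_LABELS = ("CNL", "TNL", "RNL", "CN", "TN", "RN", "NL", "N")


@dataclass(frozen=True)
class MotifHit:
    """A conserved NB-ARC motif occurrence; ``position`` is internal (0-based)."""

    protein_id: str
    motif_name: str
    position: int
    matched: str


@dataclass
class NLRArchitecture:
    protein_id: str
    has_nbarc: bool
    has_cc: bool
    has_tir: bool
    has_rpw8: bool
    has_lrr: bool
    motif_complete: bool
    class_label: str

    @property
    def n_domain_flags(self) -> int:
        return sum((self.has_cc, self.has_tir, self.has_rpw8, self.has_lrr))


def find_nbarc_proteins(
    domain_hits: Iterable[DomainHit],
    nbarc_accessions: frozenset[str] = DEFAULT_CORE_ACCESSIONS["NBARC"],
) -> set[str]:
    """Protein IDs with at least one NB-ARC hit (each counted once)."""
    hits = list(domain_hits)
    if not hits:
        logger.warning("empty domain hit list; no NB-ARC proteins found")
        return set()
    return {h.protein_id for h in hits if h.accession in nbarc_accessions}


def compile_motif_patterns(patterns: Mapping[str, str]) -> dict[str, re.Pattern]:
    compiled = {}
    for name, pat in patterns.items():
        try:
            compiled[name] = re.compile(pat)
        except re.error as exc:
            raise ValueError(f"motif pattern {name!r} does not compile: {exc}") from exc
    return compiled


def scan_motifs(
    protein: ProteinRecord,
    nbarc_hit: DomainHit,
    motif_patterns: Optional[Mapping[str, str]] = None,
    flank: int = 30,
    ordered: bool = True,
) -> list[MotifHit]:
    """Search the three NB-ARC motifs within the NB-ARC interval ± ``flank``.

    The first match of each motif is reported.  With ``ordered`` (default)
    the biological order P-loop < Kinase-2 < GLPL is enforced: each motif
    is searched downstream of the previous one.
    """
    patterns = compile_motif_patterns(motif_patterns or DEFAULT_MOTIF_PATTERNS)
    lo = max(0, nbarc_hit.start - flank)
    hi = min(protein.length, nbarc_hit.end + flank)
    region = protein.sequence[lo:hi]
    hits: list[MotifHit] = []
    offset = 0
    for name, pat in patterns.items():
        m = pat.search(region, offset)
        if m is None:
            continue
        pos = lo + m.start()
        hits.append(MotifHit(protein.protein_id, name, pos, m.group(0)))
        if ordered:
            offset = m.end()
    return hits


def motifs_complete(
    motif_hits: Sequence[MotifHit],
    motif_names: Iterable[str] = DEFAULT_MOTIF_PATTERNS,
) -> bool:
    found = {h.motif_name for h in motif_hits}
    return all(name in found for name in motif_names)


def classify_architecture(
    protein_id: str,
    domain_hits: Iterable[DomainHit],
    core_accessions: Mapping[str, frozenset[str]] = DEFAULT_CORE_ACCESSIONS,
    motif_complete: bool = False,
) -> NLRArchitecture:
    """Compose the class label from domain-presence flags.

    The N-terminal letter is taken from exactly one of TIR/CC/RPW8 with
    priority TIR > CC > RPW8 (a co-occurrence is logged as a conflict);
    the "L" suffix marks LRR presence.
    """
    hits = [h for h in domain_hits if h.protein_id == protein_id]
    accs = {h.accession for h in hits}
    has_nbarc = bool(accs & core_accessions["NBARC"])
    has_tir = bool(accs & core_accessions["TIR"])
    has_rpw8 = bool(accs & core_accessions["RPW8"])
    has_lrr = bool(accs & core_accessions["LRR"])
    has_cc = bool(accs & core_accessions["CC"]) or any(
        any(kw in h.name.lower() for kw in CC_NAME_KEYWORDS) for h in hits
    )
    if sum((has_tir, has_cc, has_rpw8)) > 1:
        logger.info(
            "protein %s carries multiple N-terminal domains; classifying by priority TIR > CC > RPW8",
            protein_id,
        )
    prefix = "T" if has_tir else ("C" if has_cc else ("R" if has_rpw8 else ""))
    label = prefix + "N" + ("L" if has_lrr else "")
    return NLRArchitecture(
        protein_id=protein_id,
        has_nbarc=has_nbarc,
        has_cc=has_cc,
        has_tir=has_tir,
        has_rpw8=has_rpw8,
        has_lrr=has_lrr,
        motif_complete=motif_complete,
        class_label=label,
    )


@dataclass
class CensusResult:
    """Gene- and protein-level counts of the NLR repertoire."""

    n_proteins: int
    n_genes: int
    n_motif_complete_genes: int
    by_class: "pd.Series"
    by_chromosome: "pd.Series"
    by_subgenome: "pd.Series"
    gene_class: dict[str, str]

    def to_frame(self) -> pd.DataFrame:
        rows = [("total", "genes", self.n_genes),
                ("total", "proteins", self.n_proteins),
                ("total", "motif_complete_genes", self.n_motif_complete_genes)]
        for section, series in (
            ("class", self.by_class),
            ("chromosome", self.by_chromosome),
            ("subgenome", self.by_subgenome),
        ):
            rows.extend((section, str(k), int(v)) for k, v in series.items())
        return pd.DataFrame(rows, columns=["section", "key", "count"])


def _richer(a: NLRArchitecture, b: NLRArchitecture) -> NLRArchitecture:
    """Architecture-richest protein wins (more domain flags; tie by label order)."""
    ka = (a.n_domain_flags, -CLASS_LABELS.index(a.class_label))
    kb = (b.n_domain_flags, -CLASS_LABELS.index(b.class_label))
    return a if ka >= kb else b


def census(
    architectures: Sequence[NLRArchitecture],
    genes: Optional[Sequence[GeneModel]] = None,
    protein_to_gene: Optional[Mapping[str, str]] = None,
) -> CensusResult:
    """Summarize class/chromosome/subgenome counts at the gene level.

    Multiple proteins of one gene collapse to the architecture-richest
    protein.  Without a protein->gene mapping every protein is treated as
    its own gene.
    """
    if protein_to_gene is None:
        protein_to_gene = {a.protein_id: a.protein_id for a in architectures}
    best: dict[str, NLRArchitecture] = {}
    complete: dict[str, bool] = {}
    for a in architectures:
        gid = protein_to_gene.get(a.protein_id, a.protein_id)
        best[gid] = _richer(best[gid], a) if gid in best else a
        complete[gid] = complete.get(gid, False) or a.motif_complete
    gene_class = {gid: a.class_label for gid, a in best.items()}
    by_class = pd.Series(gene_class, dtype=object).value_counts().reindex(
        CLASS_LABELS, fill_value=0
    )
    gene_info = {g.gene_id: g for g in genes} if genes else {}
    chroms = [gene_info[g].chromosome if g in gene_info else "unknown" for g in best]
    subg = [gene_info[g].subgenome if g in gene_info else "unknown" for g in best]
    return CensusResult(
        n_proteins=len(architectures),
        n_genes=len(best),
        n_motif_complete_genes=sum(complete.values()),
        by_class=by_class,
        by_chromosome=pd.Series(chroms, dtype=object).value_counts().sort_index(),
        by_subgenome=pd.Series(subg, dtype=object).value_counts().sort_index(),
        gene_class=gene_class,
    )
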