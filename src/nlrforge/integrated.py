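"""Integrated domains (IDs): extraction, relative position, categories.

Any Pfam domain on an NB-ARC-positive protein that is not part of the
canonical NLR structure (CC/TIR/RPW8, NB-ARC, LRR) is an integrated
domain.  Positions are expressed relative to protein length (0..1), and
each ID receives one functional category — kinase, DNA-binding,
other-signaling, or unknown — from a curated, user-extensible map.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .classify import DEFAULT_CORE_ACCESSIONS
from .io import DomainHit

CATEGORIES = ("kinase", "DNA-binding", "other-signaling", "unknown")

#: Accession-level category assignments for commonly integrated domains.
DEFAULT_CATEGORY_ACCESSIONS: dict[str, str] = {
    "PF00069": "kinase",        # Pkinase
    "PF07714": "kinase",        # PK_Tyr_Ser-Thr
    "PF03106": "DNA-binding",   # WRKY
    "PF00847": "DNA-binding",   # AP2
    "PF02362": "DNA-binding",   # B3
    "PF00249": "DNA-binding",   # Myb-like
    "PF02892": "DNA-binding",   # zf-BED
    "PF00046": "DNA-binding",   # homeobox
    "PF01419": "other-signaling",  # jacalin-like lectin
    "PF00085": "other-signaling",  # thioredoxin
    "PF00179": "other-signaling",  # ubiquitin-conjugating
    "PF01344": "other-signaling",  # kelch
    "PF03514": "other-signaling",  # GRAS
    "PF03081": "other-signaling",  # Exo70
    "PF00125": "other-signaling",  # core histone
    "PF10532": "other-signaling",  # proteasome subunit
    "PF00078": "other-signaling",  # reverse transcriptase
    "PF03184": "other-signaling",  # DDE endonuclease
}

#: Case-insensitive name keywords checked when the accession is unmapped.
DEFAULT_CATEGORY_KEYWORDS: list[tuple[str, str]] = [
    ("tyrosine kinase", "kinase"),
    ("kinase", "kinase"),
    ("wrky", "DNA-binding"),
    ("ap2", "DNA-binding"),
    ("b3", "DNA-binding"),
    ("myb", "DNA-binding"),
    ("zf-bed", "DNA-binding"),
    ("bed zinc finger", "DNA-binding"),
    ("homeobox", "DNA-binding"),
    ("dna-binding", "DNA-binding"),
    ("dna binding", "DNA-binding"),
    ("jacalin", "other-signaling"),
    ("thioredoxin", "other-signaling"),
    ("ubiquitin-conjugating", "other-signaling"),
    ("kelch", "other-signaling"),
    ("gras", "other-signaling"),
    ("exo70", "other-signaling"),
    ("calmodulin", "other-signaling"),
    ("dde", "other-signaling"),
    ("reverse transcriptase", "other-signaling"),
    ("histone", "other-signaling"),
    ("proteasome", "other-signaling"),
]


@dataclass(frozen=True)
class IntegratedDomain:
    protein_id: str
    domain: DomainHit
    rel_start: float
    rel_end: float
    rel_mid: float
    category: str
    n_copies_in_protein: int


def relative_position(domain_hit: DomainHit, protein_length: int) -> tuple[float, float, float]:
    """(rel_start, rel_end, rel_mid) of a hit on a protein of given length."""
    if protein_length <= 0:
        raise ValueError("protein length must be positive")
    rel_start = domain_hit.start / protein_length
    rel_end = domain_hit.end / protein_length
    return rel_start, rel_end, (rel_start + rel_end) / 2


def categorize_id(
    name_or_accession: str,
    accession_map: Optional[Mapping[str, str]] = None,
    keyword_map: Optional[Sequence[tuple[str, str]]] = None,
    name: Optional[str] = None,
) -> str:
    """Category lookup: accession first, then case-insensitive name keyword."""
    accession_map = DEFAULT_CATEGORY_ACCESSIONS if accession_map is None else accession_map
    keyword_map = DEFAULT_CATEGORY_KEYWORDS if keyword_map is None else keyword_map
    if name_or_accession in accession_map:
        return accession_map[name_or_accession]
    text = (name if name is not None else name_or_accession).lower()
    for kw, cat in keyword_map:
        if kw in text:
            return cat
    return "unknown"


def extract_ids(
    protein_id: str,
    domain_hits: Iterable[DomainHit],
    core_accessions: Mapping[str, frozenset[str]] = DEFAULT_CORE_ACCESSIONS,
    protein_length: Optional[int] = None,
    accession_map: Optional[Mapping[str, str]] = None,
    keyword_map: Optional[Sequence[tuple[str, str]]] = None,
) -> list[IntegratedDomain]:
    """All non-core Pfam hits on one NB-ARC-positive protein.

    Multiple copies of one accession are all retained, each carrying the
    per-protein copy count.  Non-Pfam rows (coils, TM helices, signal
    peptides) are not ID evidence and are skipped.
    """
    core = frozenset().union(*core_accessions.values())
    hits = [
        h
        for h in domain_hits
        if h.protein_id == protein_id and h.is_pfam() and h.accession not in core
    ]
    length = protein_length or max((h.end for h in hits), default=0)
    copies: dict[str, int] = {}
    for h in hits:
        copies[h.accession] = copies.get(h.accession, 0) + 1
    out = []
    for h in sorted(hits, key=lambda h: (h.start, h.accession)):
        rs, re_, rm = relative_position(h, length)
        out.append(
            IntegratedDomain(
                protein_id=protein_id,
                domain=h,
                rel_start=rs,
                rel_end=re_,
                rel_mid=rm,
                category=categorize_id(h.accession, accession_map, keyword_map, name=h.name),
                n_copies_in_protein=copies[h.accession],
            )
        )
    return out


def positional_profile(integrated_domains: Iterable[IntegratedDomain]) -> pd.DataFrame:
    """Per-ID-type occurrence counts and mean relative positions."""
    rows = [
        {
            "accession": d.domain.accession,
            "name": d.domain.name,
            "category": d.category,
            "rel_start": d.rel_start,
            "rel_end": d.rel_end,
            "rel_mid": d.rel_mid,
        }
        for d in integrated_domains
    ]
    if not rows:
        return pd.DataFrame(
            columns=["accession", "name", "category", "n", "mean_rel_start",
                     "mean_rel_end", "mean_rel_mid"]
        )
    df = pd.DataFrame(rows)
    prof = (
        df.groupby(["accession", "name", "category"], as_index=False)
        .agg(
            n=("rel_mid", "size"),
            mean_rel_start=("rel_start", "mean"),
            mean_rel_end=("rel_end", "mean"),
            mean_rel_mid=("rel_mid", "mean"),
        )
        .sort_values("accession", kind="stable")
        .reset_index(drop=True)
    )
    return prof
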