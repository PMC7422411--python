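"""Synthetic genome/proteome generator with planted ground truth.

Every analysis stage of the package can be validated against data whose
structure is known by construction: NLR proteins assembled from domain
blocks (CC/TIR/RPW8 + an NB-ARC carrying the P-loop, Kinase-2 and GLPL
motifs + LRR repeats), tandem-duplicated gene clusters with controlled
per-site divergence, integrated domains planted at a preferred terminus,
alternative transcripts that exclude or truncate ID-encoding exons or
retain introns, and progenitor/comparator proteomes produced by
diverging the same ancestors.  All randomness flows from a single seed;
identical seeds give byte-identical output files.

The divergence model is substitution-only (each mutated site switches to
a uniformly chosen different residue), which keeps expected identity
analytic: two sequences at rate ``r`` share ``1 - r + r/19`` of their
sites in expectation.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import yaml

from . import io as nio
from .io import DomainHit, GeneModel, ProteinRecord, TranscriptModel

AA = "ACDEFGHIKLMNPQRSTVWY"
# linker alphabet omits D/K/P/W so inter-domain sequence can never form a
# spurious P-loop / Kinase-2 / GLPL motif match
LINKER_AA = "ACEFGHILMNQRSTVY"

PLOOP = "GGVGKTT"
KINASE2 = "LLVLDDVW"
GLPL = "GLPL"

CC_SEQ = "ASNGHLFHTNIYCVILQMVFFHNQEHMEQQGGYRMVELGV"
TIR_SEQ = (
    "AMNVYTVIFYARCEFLTLFCIAGVSLLSGTHFNIFAMMLSYFIVAHGEVQVSCNVINQQTQFLTHCRMAARGLITNIRFF"
)
RPW8_SEQ = "LAQTNQIVAFFNFYTQTYEGQSILLFQECFVRFIGRHYREHTHFNAERAHHNALHAEIIH"
NB_PRE = "TSIMYHIHLGMCGNATEEVV"
NB_MID1 = "CQVQVQNTRHQIMMISFLSHGRCVIMREMEMYSLVCAQTI"
NB_MID2 = "SRQLISALIVVTNLEEFTLHYEYAMTNEITLLMLFMLCRL"
NB_SUF = "AVMEQEFLATTSCSCMLHMEFNRTYSGHAGSYYNFTYQAL"
LRR_UNIT = "LSGSLSSLTNLRELNLSGNSLTGS"
LRR_SEQ = LRR_UNIT * 4

#: accession -> (name, category, preferred terminus, consensus sequence)
DEFAULT_ID_LIBRARY: dict[str, tuple[str, str, str, str]] = {
    "PF00069": ("Protein kinase domain", "kinase", "N",
                "FYERTMSIIFSHALLACLIFKWGEEQFFWPGESLFMVKIWMQLREHFVCKSSPKCAEFLFQFGFY"),
    "PF07714": ("Protein tyrosine kinase", "kinase", "N",
                "WENATLRSNFCPRNSGHFDGINTQEPVLELICIAFLMYGPKVFVNWAGHQRHHFKSMERKRG"),
    "PF03106": ("WRKY DNA-binding domain", "DNA-binding", "C",
                "WQVFSMARSEPTQGLCKELMEYDMPEEYICPFGNTTGTSERMWHNWMAEFPKSMRYGH"),
    "PF00847": ("AP2 domain", "DNA-binding", "N",
                "SPVNRFSCFGLVVSKIRSIDWMPALKDYLDHAMADPCRLQETPSLRGHNTHCNCRVLSKN"),
    "PF02362": ("B3 DNA binding domain", "DNA-binding", "C",
                "KYGDKCSVWQVVCRSPDCQCCMHILASMGHNSFWKEAQNMNVPTDKQSIIVADTLAAIHSHCAD"),
    "PF00249": ("Myb-like DNA-binding domain", "DNA-binding", "N",
                "NVAKWCPIYSFYHYVDRYQDHVVSAGFDSAMKYAIMMMKFVPPPKYNQSDGA"),
    "PF02892": ("BED zinc finger", "DNA-binding", "N",
                "GHWIWINGVHVGEAPQIEDHQNMLQNMDMYEHISKHFGGEWVHKGTNGVIPIMH"),
    "PF01419": ("Jacalin-like lectin domain", "other-signaling", "C",
                "KLARASHQHVIYIINGQELLNPFKTWQCEVVSMPFNATMNWRSASKIHVHNRIYANVEYTRSHFKL"),
    "PF00085": ("Thioredoxin", "other-signaling", "C",
                "HDERHQDPTTDRWWNHQAESFYCCFNENMKNDNERGTSPPYHHQPMFMFCLHLWKSVRPY"),
    "PF00179": ("Ubiquitin-conjugating enzyme", "other-signaling", "C",
                "YPAHLDGGMWFACCVYHSCCRVNFMFFENFHKGWDGAQHMAKCAKNKGKFVIMWDPMAYGHM"),
    "PF01344": ("Kelch motif", "other-signaling", "C",
                "WNLMKDKHWDYTNVDVYPFRYIMDFMDFRVYRVQMMFCRRELMMKFQSCITRIYWF"),
    "PF03081": ("Exo70 exocyst complex subunit", "other-signaling", "C",
                "SSQQMMKQLRPRPAGNGTSFGTMSCVAKGAQCAQYQQIGGCLGMYDKHYWNLPEQGKLVKCHTTSTVI"),
    "PF09999": ("Domain of unknown function DUF9999", "unknown", "C",
                "DYTIFGGWLKHGPWICMLYEPVYHRSSTVKEYFQYWTYWHPNFAWNVGPS"),
}

#: class-label proportions shaped like the wheat census (CNL and NL dominate,
#: TIR-bearing classes rare in a monocot, RPW8 classes rarer still)
DEFAULT_CLASS_PROPORTIONS: dict[str, float] = {
    "CNL": 0.37, "NL": 0.35, "N": 0.15, "CN": 0.08,
    "TNL": 0.02, "TN": 0.01, "RNL": 0.01, "RN": 0.01,
}

DOMAIN_ACCESSION = {
    "CC": ("PF18052", "RX-CC_like coiled-coil"),
    "TIR": ("PF01582", "TIR domain"),
    "RPW8": ("PF05659", "RPW8 domain"),
    "NBARC": ("PF00931", "NB-ARC domain"),
    "LRR": ("PF13855", "Leucine rich repeat"),
}


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic genome.

    Defaults follow the statistical shape of a hexaploid wheat NLR
    repertoire: about 60% of NB-ARC genes in tandem clusters
    (``tandem_dup_prob`` 0.4 with geometric cluster extension), about 70%
    of NB-ARCs motif-complete, roughly one NLR in ten carrying an
    integrated domain, and progenitor proteomes closer to their own
    subgenome (5% divergence) than to the other (15%).
    """

    seed: int = 0
    n_chromosomes: int = 6
    genes_per_chromosome: int = 100
    nlr_fraction: float = 0.25
    class_proportions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_PROPORTIONS)
    )
    motif_complete_prob: float = 0.70
    tandem_dup_prob: float = 0.4
    cluster_extension_prob: float = 0.25
    dup_divergence: float = 0.10
    id_insertion_prob: float = 0.10
    wrky_double_prob: float = 0.15
    id_library: dict[str, tuple[str, str, str, str]] = field(
        default_factory=lambda: dict(DEFAULT_ID_LIBRARY)
    )
    alt_transcript_prob: float = 0.5
    id_exclusion_prob: float = 0.3
    id_truncation_prob: float = 0.15
    intron_retention_prob: float = 0.1
    progenitor_divergence: float = 0.05
    cross_progenitor_divergence: float = 0.15
    comparator_divergence: float = 0.12
    progenitor_presence: float = 0.95
    other_progenitor_presence: float = 0.9
    comparator_presence: float = 0.8
    nlr_homolog_frac: float = 0.685
    annotation_fn_rate: float = 0.0
    filler_domain_prob: float = 0.1
    comparator_species: tuple[str, ...] = ("HV",)
    n_decoys_per_proteome: int = 30
    expression_conditions: int = 6

    def validate(self) -> None:
        probs = {
            "nlr_fraction": self.nlr_fraction,
            "motif_complete_prob": self.motif_complete_prob,
            "tandem_dup_prob": self.tandem_dup_prob,
            "cluster_extension_prob": self.cluster_extension_prob,
            "dup_divergence": self.dup_divergence,
            "id_insertion_prob": self.id_insertion_prob,
            "alt_transcript_prob": self.alt_transcript_prob,
            "id_exclusion_prob": self.id_exclusion_prob,
            "id_truncation_prob": self.id_truncation_prob,
            "intron_retention_prob": self.intron_retention_prob,
            "progenitor_divergence": self.progenitor_divergence,
            "cross_progenitor_divergence": self.cross_progenitor_divergence,
            "annotation_fn_rate": self.annotation_fn_rate,
            "nlr_homolog_frac": self.nlr_homolog_frac,
            "filler_domain_prob": self.filler_domain_prob,
        }
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be a probability, got {p}")
        total = sum(self.class_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class_proportions must sum to 1, got {total}")
        if self.n_chromosomes < 1 or self.genes_per_chromosome < 1:
            raise ValueError("need at least one chromosome and one gene")

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["comparator_species"] = list(self.comparator_species)
        return d


def mutate_sequence(seq: str, rate: float, rng) -> str:
    """Per-site substitution to a uniformly chosen *different* residue."""
    if not 0.0 <= rate < 1.0 + 1e-12:
        raise ValueError("rate must be in [0, 1]")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    mask = rng.random(arr.size) < rate
    n = int(mask.sum())
    if n:
        aa_codes = np.frombuffer(AA.encode(), dtype=np.uint8)
        # offset 1..19 from the current residue's alphabet index
        idx = np.searchsorted(aa_codes, arr[mask])
        new_idx = (idx + rng.integers(1, 20, size=n)) % 20
        arr[mask] = aa_codes[new_idx]
    return arr.tobytes().decode()


def _rand_seq(rng, alphabet: str, n: int) -> str:
    return "".join(alphabet[i] for i in rng.integers(0, len(alphabet), n))


# ---------------------------------------------------------------------------
# protein assembly
# ---------------------------------------------------------------------------

@dataclass
class _Block:
    kind: str                      # CC/TIR/RPW8/NBARC/LRR/ID/linker
    seq: str
    accession: Optional[str] = None
    name: Optional[str] = None
    hits: list[tuple[str, str, int, int]] = field(default_factory=list)
    # hits: (accession, name, start, end) relative to block start; used for
    # blocks hosting more than one domain copy


def _nbarc_block(rng, scrub: frozenset[str]) -> tuple[_Block, dict[str, int]]:
    def piece(motif: str, name: str) -> str:
        return _rand_seq(rng, LINKER_AA, len(motif)) if name in scrub else motif

    seq = (
        NB_PRE
        + piece(PLOOP, "P-loop")
        + NB_MID1
        + piece(KINASE2, "Kinase-2")
        + NB_MID2
        + piece(GLPL, "GLPL")
        + NB_SUF
    )
    offsets = {
        "P-loop": len(NB_PRE),
        "Kinase-2": len(NB_PRE) + len(PLOOP) + len(NB_MID1),
        "GLPL": len(NB_PRE) + len(PLOOP) + len(NB_MID1) + len(KINASE2) + len(NB_MID2),
    }
    acc, name = DOMAIN_ACCESSION["NBARC"]
    block = _Block("NBARC", seq, acc, name)
    return block, {m: off for m, off in offsets.items() if m not in scrub}


def _id_block(rng, accession: str, library, double: bool) -> _Block:
    name, _cat, _term, seq = library[accession]
    if double:
        linker = _rand_seq(rng, LINKER_AA, 6)
        full = seq + linker + seq
        block = _Block("ID", full, accession, name)
        block.hits = [
            (accession, name, 0, len(seq)),
            (accession, name, len(seq) + len(linker), len(full)),
        ]
    else:
        block = _Block("ID", seq, accession, name)
        block.hits = [(accession, name, 0, len(seq))]
    return block


def _assemble_nlr(rng, class_label: str, scrub: frozenset[str],
                  id_acc: Optional[str], id_double: bool, library):
    """Block list + sequence + truth domain hits + motif offsets."""
    has_tir = class_label.startswith("T")
    has_cc = class_label.startswith("C")
    has_rpw8 = class_label.startswith("R")
    has_lrr = class_label.endswith("L")
    id_term = library[id_acc][2] if id_acc else None

    blocks: list[_Block] = []
    if id_acc and id_term == "N":
        blocks.append(_id_block(rng, id_acc, library, id_double))
        blocks.append(_Block("linker", _rand_seq(rng, LINKER_AA, int(rng.integers(35, 50)))))
    for kind, cond, seq in (
        ("CC", has_cc, CC_SEQ), ("TIR", has_tir, TIR_SEQ), ("RPW8", has_rpw8, RPW8_SEQ)
    ):
        if cond:
            acc, name = DOMAIN_ACCESSION[kind]
            blocks.append(_Block(kind, seq, acc, name))
            blocks.append(_Block("linker", _rand_seq(rng, LINKER_AA, int(rng.integers(8, 16)))))
    nb, motif_offsets = _nbarc_block(rng, scrub)
    blocks.append(nb)
    if has_lrr:
        blocks.append(_Block("linker", _rand_seq(rng, LINKER_AA, int(rng.integers(8, 16)))))
        acc, name = DOMAIN_ACCESSION["LRR"]
        blocks.append(_Block("LRR", LRR_SEQ, acc, name))
    if id_acc and id_term == "C":
        blocks.append(_Block("linker", _rand_seq(rng, LINKER_AA, int(rng.integers(35, 50)))))
        blocks.append(_id_block(rng, id_acc, library, id_double))

    seq_parts, hits, spans = [], [], []
    pos = 0
    nbarc_start = 0
    for b in blocks:
        spans.append((b.kind, pos, pos + len(b.seq)))
        if b.kind == "NBARC":
            nbarc_start = pos
        if b.accession:
            if b.hits:
                hits.extend((a, n, pos + s, pos + e) for a, n, s, e in b.hits)
            else:
                hits.append((b.accession, b.name, pos, pos + len(b.seq)))
        seq_parts.append(b.seq)
        pos += len(b.seq)
    seq = "".join(seq_parts)
    motifs = {m: nbarc_start + off for m, off in motif_offsets.items()}
    id_span = next(((s, e) for k, s, e in spans if k == "ID"), None)
    # with an N- and C-terminal ID simultaneously unsupported, span is unique
    return seq, hits, motifs, id_span


def _exon_aa_layout(rng, protein_len: int, id_span) -> list[tuple[int, int]]:
    """Exon boundaries in amino-acid space; the ID block is its own exon."""
    cuts = {0, protein_len}
    if id_span:
        cuts |= {id_span[0], id_span[1]}
    bounds = sorted(cuts)
    exons: list[tuple[int, int]] = []
    for a, b in zip(bounds, bounds[1:]):
        if id_span and (a, b) == tuple(id_span):
            exons.append((a, b))
            continue
        seg = b - a
        n_pieces = max(1, int(np.ceil(seg / 120)))
        edges = np.linspace(a, b, n_pieces + 1).astype(int)
        exons.extend((int(s), int(e)) for s, e in zip(edges, edges[1:]) if e > s)
    return exons


def _place_exons(exon_nt: Sequence[int], intron_nt: Sequence[int],
                 start: int, strand: str) -> list[tuple[int, int]]:
    """Genomic exon intervals in transcription order."""
    out = []
    if strand == "+":
        pos = start
        for i, L in enumerate(exon_nt):
            out.append((pos, pos + L))
            pos += L + (intron_nt[i] if i < len(intron_nt) else 0)
    else:
        total = sum(exon_nt) + sum(intron_nt)
        pos = start + total
        for i, L in enumerate(exon_nt):
            out.append((pos - L, pos))
            pos -= L + (intron_nt[i] if i < len(intron_nt) else 0)
    return out


# ---------------------------------------------------------------------------
# the generator
# ---------------------------------------------------------------------------

class TruthSet(dict):
    """Planted ground truth, JSON-serializable (a plain dict subclass)."""

    @classmethod
    def load(cls, path) -> "TruthSet":
        with open(path) as fh:
            return cls(json.load(fh))


def generate(config: SimulationConfig, outdir) -> tuple[TruthSet, dict[str, Path]]:
    """Emit the full synthetic data set and its truth description.

    Returns ``(truth, paths)`` where ``paths`` maps logical names
    (proteome, gff3, domains, expression, truth, and per-species
    progenitor/comparator files) to the files written under ``outdir``.
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)

    class_labels = sorted(config.class_proportions)
    class_probs = np.array([config.class_proportions[c] for c in class_labels])
    id_accessions = sorted(config.id_library)

    sub_letters = ("A", "B", "D")
    chrom_names = [
        f"{i // 3 + 1}{sub_letters[i % 3]}" for i in range(config.n_chromosomes)
    ]

    proteins: list[ProteinRecord] = []
    genes: list[GeneModel] = []
    transcripts: list[TranscriptModel] = []
    domain_rows: list[DomainHit] = []          # pre-noise truth annotation
    truth_genes: dict[str, dict] = {}
    truth_clusters: dict[str, list[str]] = {}
    progenitor_prot: dict[str, list[ProteinRecord]] = {"TU": [], "AT": []}
    progenitor_hits: dict[str, list[DomainHit]] = {"TU": [], "AT": []}
    for sp in config.comparator_species:
        progenitor_prot[sp] = []
        progenitor_hits[sp] = []

    n_cluster = 0
    gene_serial = 0

    def add_gene_models(gene_id, chrom, strand, ref_exons_tx, variants, cursor_start):
        """Register gene + transcripts; returns (gene_model, gene_end)."""
        all_exons = [iv for exons in [ref_exons_tx] + [v[1] for v in variants] for iv in exons]
        g_start = min(s for s, _ in all_exons)
        g_end = max(e for _, e in all_exons)
        gm = GeneModel(gene_id, chrom, g_start, g_end, strand)
        tx_models = []
        ref_tid = f"{gene_id}.1"
        tm = TranscriptModel(ref_tid, gene_id, strand,
                             exons=sorted(ref_exons_tx),
                             cds_segments=[(s, e, 0) for s, e in sorted(ref_exons_tx)])
        tx_models.append(tm)
        for k, (tid, exons, _info) in enumerate(variants, start=2):
            tm = TranscriptModel(tid, gene_id, strand,
                                 exons=sorted(exons),
                                 cds_segments=[(s, e, 0) for s, e in sorted(exons)])
            tx_models.append(tm)
        gm.transcript_ids = [t.transcript_id for t in tx_models]
        genes.append(gm)
        transcripts.extend(tx_models)
        return gm, g_end

    def make_nlr_gene(chrom, cursor, founder_truth=None):
        """Create one NLR gene (founder or a diverged tandem copy)."""
        nonlocal gene_serial
        gene_serial += 1
        gene_id = f"SynG{chrom}{gene_serial:05d}"
        strand = "+" if rng.random() < 0.5 else "-"

        if founder_truth is None:
            label = class_labels[int(rng.choice(len(class_labels), p=class_probs))]
            complete = rng.random() < config.motif_complete_prob
            scrub = frozenset()
            if not complete:
                motif_names = ["P-loop", "Kinase-2", "GLPL"]
                n_scrub = int(rng.integers(1, 4))
                scrub = frozenset(
                    motif_names[i] for i in rng.choice(3, size=n_scrub, replace=False)
                )
            id_acc = None
            id_double = False
            if rng.random() < config.id_insertion_prob:
                id_acc = id_accessions[int(rng.integers(0, len(id_accessions)))]
                if id_acc == "PF03106" and rng.random() < config.wrky_double_prob:
                    id_double = True
            seq, hits, motifs, id_span = _assemble_nlr(
                rng, label, scrub, id_acc, id_double, config.id_library
            )
        else:
            # tandem copy: diverge the founder protein; coordinates carry over
            label = founder_truth["class_label"]
            complete = founder_truth["motif_complete"]
            id_acc = founder_truth["_id_acc"]
            id_double = founder_truth["_id_double"]
            ref_seq = founder_truth["_ref_seq"]
            seq = mutate_sequence(ref_seq, config.dup_divergence, rng)
            # Walker/GLPL motifs are under strong purifying selection in
            # tandem duplicates: restore them after divergence
            motif_seqs = {"P-loop": PLOOP, "Kinase-2": KINASE2, "GLPL": GLPL}
            for mname, pos in founder_truth["motifs"].items():
                L = len(motif_seqs[mname])
                seq = seq[:pos] + ref_seq[pos: pos + L] + seq[pos + L:]
            hits = founder_truth["_hits"]
            motifs = founder_truth["motifs"]
            id_span = founder_truth["_id_span"]

        exon_aa = _exon_aa_layout(rng, len(seq), id_span)
        exon_nt = [3 * (b - a) for a, b in exon_aa]
        exon_nt[-1] += 3  # stop codon
        intron_nt = [int(rng.integers(150, 800)) for _ in range(len(exon_nt) - 1)]
        ref_exons = _place_exons(exon_nt, intron_nt, cursor, strand)
        id_exon_idx = exon_aa.index(tuple(id_span)) if id_span else None

        variants = []  # (tid, exons_tx_order, info)
        tx_truth = {f"{gene_id}.1": {"kind": "reference", "excluded_ids": [],
                                     "truncated_ids": [], "retained_introns": []}}
        next_tx = 2
        alt_id_variant = None  # transcript id of the alt ID-variant draw, if any

        def variant_protein_and_hits(keep_aa: Optional[int]):
            """Protein/hits after removing or shortening the ID block."""
            s, e = id_span
            kept_end = s + (keep_aa or 0)
            removed = e - kept_end
            vseq = seq[:kept_end] + seq[e:]
            vhits = []
            for acc, nm, hs, he in hits:
                if hs >= e:
                    vhits.append((acc, nm, hs - removed, he - removed))
                elif he <= s:
                    vhits.append((acc, nm, hs, he))
                else:  # inside the ID block: clip to the kept prefix
                    cs, ce = hs, min(he, kept_end)
                    if ce - cs > 0:
                        vhits.append((acc, nm, cs, ce))
            return vseq, vhits

        is_founder = founder_truth is None
        if is_founder and id_span and rng.random() < config.alt_transcript_prob:
            tid = f"{gene_id}.{next_tx}"
            next_tx += 1
            alt_id_variant = tid
            u = rng.random()
            ref_id_accs = sorted({a for a, _n, hs, he in hits
                                  if id_span[0] <= hs and he <= id_span[1]})
            if u < config.id_exclusion_prob:
                exons = [iv for i, iv in enumerate(ref_exons) if i != id_exon_idx]
                vseq, vhits = variant_protein_and_hits(keep_aa=None)
                info = {"kind": "exclusion", "excluded_ids": ref_id_accs,
                        "truncated_ids": [], "retained_introns": []}
            elif u < config.id_exclusion_prob + config.id_truncation_prob:
                s, e = id_span
                keep_aa = (e - s) // 2
                keep_nt = 3 * keep_aa
                gs, ge = ref_exons[id_exon_idx]
                cut = (gs, gs + keep_nt) if strand == "+" else (ge - keep_nt, ge)
                exons = list(ref_exons)
                exons[id_exon_idx] = cut
                vseq, vhits = variant_protein_and_hits(keep_aa=keep_aa)
                ref_lens = {a: he - hs for a, _n, hs, he in hits
                            if id_span[0] <= hs and he <= id_span[1]}
                v_lens: dict[str, int] = {}
                for a, _n, hs, he in vhits:
                    v_lens[a] = max(v_lens.get(a, 0), he - hs)
                excl = [a for a in ref_id_accs if a not in v_lens]
                trunc = [a for a in ref_id_accs
                         if a in v_lens and v_lens[a] < 0.8 * ref_lens[a]]
                info = {"kind": "truncation", "excluded_ids": excl,
                        "truncated_ids": trunc, "retained_introns": []}
            else:
                vseq, vhits = seq, hits
                exons, retained = _retention_exons(rng, ref_exons)
                info = {"kind": "plain" if not retained else "retention",
                        "excluded_ids": [], "truncated_ids": [],
                        "retained_introns": retained}
            variants.append((tid, exons, info))
            tx_truth[tid] = info
            proteins.append(ProteinRecord(tid, vseq))
            domain_rows.extend(
                DomainHit(tid, a, n, hs, he) for a, n, hs, he in vhits
            )
        if is_founder and rng.random() < config.intron_retention_prob and len(ref_exons) >= 2:
            tid = f"{gene_id}.{next_tx}"
            next_tx += 1
            exons, retained = _retention_exons(rng, ref_exons, force=True)
            info = {"kind": "retention", "excluded_ids": [], "truncated_ids": [],
                    "retained_introns": retained}
            variants.append((tid, exons, info))
            tx_truth[tid] = info
            proteins.append(ProteinRecord(tid, seq))
            domain_rows.extend(DomainHit(tid, a, n, hs, he) for a, n, hs, he in hits)

        gm, g_end = add_gene_models(gene_id, chrom, strand, ref_exons, variants, cursor)
        ref_tid = f"{gene_id}.1"
        proteins.append(ProteinRecord(ref_tid, seq))
        domain_rows.extend(DomainHit(ref_tid, a, n, hs, he) for a, n, hs, he in hits)

        ids_truth = [
            {
                "accession": a, "name": n, "start": hs, "end": he,
                "category": config.id_library[a][1],
                "terminus": config.id_library[a][2],
            }
            for a, n, hs, he in hits
            if a not in {v[0] for v in DOMAIN_ACCESSION.values()}
        ]
        truth_genes[gene_id] = {
            "chromosome": chrom,
            "subgenome": gm.subgenome,
            "strand": strand,
            "is_nlr": True,
            "class_label": label,
            "motif_complete": complete,
            "motifs": motifs,
            "cluster_id": None,
            "ids": ids_truth,
            "alt_id_variant": alt_id_variant,
            "transcripts": tx_truth,
            "progenitors": {},
            "_ref_seq": seq,
            "_hits": hits,
            "_id_acc": id_acc,
            "_id_double": id_double,
            "_id_span": id_span,
        }
        _make_homologs(rng, config, gene_id, gm.subgenome, seq, hits, id_span,
                       truth_genes[gene_id], progenitor_prot, progenitor_hits)
        return gene_id, g_end

    def make_filler_gene(chrom, cursor):
        nonlocal gene_serial
        gene_serial += 1
        gene_id = f"SynG{chrom}{gene_serial:05d}"
        strand = "+" if rng.random() < 0.5 else "-"
        plen = int(rng.integers(120, 300))
        seq = _rand_seq(rng, AA, plen)
        hits = []
        if rng.random() < config.filler_domain_prob:
            acc = id_accessions[int(rng.integers(0, len(id_accessions)))]
            name, _cat, _term, dseq = config.id_library[acc]
            if len(dseq) + 10 < plen:
                off = int(rng.integers(5, plen - len(dseq) - 5))
                seq = seq[:off] + dseq + seq[off + len(dseq):]
                hits.append((acc, name, off, off + len(dseq)))
        n_ex = int(rng.integers(1, 4))
        edges = np.linspace(0, plen, n_ex + 1).astype(int)
        exon_nt = [3 * int(e - s) for s, e in zip(edges, edges[1:]) if e > s]
        exon_nt[-1] += 3
        intron_nt = [int(rng.integers(150, 800)) for _ in range(len(exon_nt) - 1)]
        ref_exons = _place_exons(exon_nt, intron_nt, cursor, strand)
        gm, g_end = add_gene_models(gene_id, chrom, strand, ref_exons, [], cursor)
        tid = f"{gene_id}.1"
        proteins.append(ProteinRecord(tid, seq))
        domain_rows.extend(DomainHit(tid, a, n, hs, he) for a, n, hs, he in hits)
        truth_genes[gene_id] = {
            "chromosome": chrom, "subgenome": gm.subgenome, "strand": strand,
            "is_nlr": False, "class_label": None, "motif_complete": False,
            "motifs": {}, "cluster_id": None, "ids": [],
            "transcripts": {tid: {"kind": "reference", "excluded_ids": [],
                                  "truncated_ids": [], "retained_introns": []}},
            "progenitors": {},
        }
        return gene_id, g_end

    for chrom in chrom_names:
        cursor = 10_000
        for _slot in range(config.genes_per_chromosome):
            if rng.random() < config.nlr_fraction:
                founder_id, g_end = make_nlr_gene(chrom, cursor)
                cursor = g_end
                if rng.random() < config.tandem_dup_prob:
                    n_cluster += 1
                    cid = f"truth_cluster_{n_cluster:04d}"
                    members = [founder_id]
                    founder = truth_genes[founder_id]
                    while True:
                        # a few filler genes may sit between tandem copies
                        for _ in range(int(rng.integers(0, 3))):
                            cursor += int(rng.integers(500, 3_000))
                            _fid, f_end = make_filler_gene(chrom, cursor)
                            cursor = f_end
                        cursor += int(rng.integers(500, 5_000))
                        copy_id, g_end = make_nlr_gene(chrom, cursor, founder_truth=founder)
                        cursor = g_end
                        members.append(copy_id)
                        if len(members) >= 4 or rng.random() >= config.cluster_extension_prob:
                            break
                    for m in members:
                        truth_genes[m]["cluster_id"] = cid
                    truth_clusters[cid] = members
            else:
                _fid, g_end = make_filler_gene(chrom, cursor)
                cursor = g_end
            # spacing between units is well beyond the clustering gap rule
            cursor += int(rng.integers(210_000, 400_000))

    # ---- annotation false negatives -------------------------------------
    if config.annotation_fn_rate > 0:
        keep = rng.random(len(domain_rows)) >= config.annotation_fn_rate
        emitted_rows = [h for h, k in zip(domain_rows, keep) if k]
    else:
        emitted_rows = list(domain_rows)

    # ---- expression ------------------------------------------------------
    tx_ids = [t.transcript_id for t in transcripts]
    expr = rng.lognormal(mean=2.0, sigma=1.0,
                         size=(len(tx_ids), config.expression_conditions))

    # ---- decoys in homolog proteomes ------------------------------------
    for sp in sorted(progenitor_prot):
        for i in range(config.n_decoys_per_proteome):
            progenitor_prot[sp].append(
                ProteinRecord(f"{sp}_decoy{i:03d}", _rand_seq(rng, AA, int(rng.integers(150, 400))))
            )

    # ---- write files -----------------------------------------------------
    paths: dict[str, Path] = {}
    paths["proteome"] = outdir / "proteome.fasta"
    nio.write_fasta(sorted(proteins, key=lambda p: p.protein_id), paths["proteome"])
    paths["gff3"] = outdir / "genes.gff3"
    nio.write_gff3(genes, transcripts, paths["gff3"])
    paths["domains"] = outdir / "domains.tsv"
    nio.write_domain_tsv(
        sorted(emitted_rows, key=lambda h: (h.protein_id, h.start, h.accession)),
        paths["domains"],
    )
    paths["expression"] = outdir / "expression.tsv"
    with open(paths["expression"], "w") as fh:
        cols = [f"cond_{i + 1}" for i in range(config.expression_conditions)]
        fh.write("transcript_id\t" + "\t".join(cols) + "\n")
        for tid, row in zip(tx_ids, expr):
            fh.write(tid + "\t" + "\t".join(f"{v:.4f}" for v in row) + "\n")
    for sp in sorted(progenitor_prot):
        kind = "progenitor" if sp in ("TU", "AT") else "comparator"
        paths[f"{kind}_{sp}"] = outdir / f"{kind}_{sp}.fasta"
        nio.write_fasta(sorted(progenitor_prot[sp], key=lambda p: p.protein_id),
                        paths[f"{kind}_{sp}"])
        paths[f"{kind}_{sp}_domains"] = outdir / f"{kind}_{sp}.domains.tsv"
        nio.write_domain_tsv(
            sorted(progenitor_hits[sp], key=lambda h: (h.protein_id, h.start, h.accession)),
            paths[f"{kind}_{sp}_domains"],
        )

    truth = TruthSet(
        config=config.to_dict(),
        genes={
            gid: {k: v for k, v in info.items() if not k.startswith("_")}
            for gid, info in truth_genes.items()
        },
        clusters=truth_clusters,
    )
    paths["truth"] = outdir / "truth.json"
    with open(paths["truth"], "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return truth, paths


def _retention_exons(rng, ref_exons, force: bool = False):
    """Merge adjacent exons across one (sometimes two) reference introns."""
    n_introns = len(ref_exons) - 1
    if n_introns < 1:
        return list(ref_exons), []
    k = int(rng.integers(1, n_introns + 1))  # 1-based transcription order
    retained = [k]
    if k < n_introns and rng.random() < 0.3:
        retained.append(k + 1)
    first, last = retained[0] - 1, retained[-1]  # exon index range to merge
    merged_block = ref_exons[first: last + 1]
    lo = min(s for s, _ in merged_block)
    hi = max(e for _, e in merged_block)
    exons = ref_exons[:first] + [(lo, hi)] + ref_exons[last + 1:]
    return exons, retained


def _make_homologs(rng, config, gene_id, subgenome, seq, hits, id_span,
                   gene_truth, prot_store, hit_store):
    """Progenitor and comparator homologs for an ID-bearing NLR gene."""
    if not id_span:
        return
    expected = {"A": "TU", "D": "AT"}.get(subgenome)
    gene_truth["expected_progenitor"] = expected

    def plant(species, divergence, presence):
        if rng.random() >= presence:
            return None
        pid = f"{species}_{gene_id}"
        is_nlr = rng.random() < config.nlr_homolog_frac
        if is_nlr:
            hseq = mutate_sequence(seq, divergence, rng)
            hhits = hits
            offset = 0
        else:
            flank = 15
            s, e = max(0, id_span[0] - flank), min(len(seq), id_span[1] + flank)
            hseq = mutate_sequence(seq[s:e], divergence, rng)
            hhits = [(a, n, hs - s, he - s) for a, n, hs, he in hits
                     if id_span[0] <= hs and he <= id_span[1]]
            offset = s
        prot_store[species].append(ProteinRecord(pid, hseq))
        hit_store[species].extend(DomainHit(pid, a, n, hs, he) for a, n, hs, he in hhits)
        gene_truth["progenitors"][species] = {
            "protein_id": pid, "is_nlr": is_nlr, "divergence": divergence,
        }
        return pid

    if subgenome in ("A", "D"):
        same = "TU" if subgenome == "A" else "AT"
        other = "AT" if subgenome == "A" else "TU"
        plant(same, config.progenitor_divergence, config.progenitor_presence)
        plant(other, config.cross_progenitor_divergence, config.other_progenitor_presence)
    for sp in config.comparator_species:
        plant(sp, config.comparator_divergence, config.comparator_presence)
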