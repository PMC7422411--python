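# Methods

This note documents the models and procedures implemented in `nlrforge`,
the parameters that matter, the design choices made where a convention had
to be fixed, and what the synthetic-data generator does and does not
emulate.

## Coordinates

All in-memory coordinates are 0-based half-open; conversion to the 1-based
inclusive convention of GFF3 and InterProScan TSV happens only in the
readers and writers, and BED output is written 0-based half-open. This
keeps length and overlap arithmetic free of ±1 corrections and makes the
conversion self-inverse (property-tested).

## NB-ARC identification and architecture classes

NLR candidacy is decided entirely from the domain-annotation table, as in
database-driven surveys: a protein is an NLR candidate iff it has at least
one hit from the NB-ARC accession set (default `{PF00931}`). Architecture
flags come from accession membership in configurable core sets:

| component | default accessions |
|---|---|
| NB-ARC | PF00931 |
| TIR | PF01582, PF13676 |
| RPW8 | PF05659 |
| CC | PF18052, plus any hit whose name contains "RX-CC_like"/"coiled-coil" |
| LRR | PF00560, PF07725, PF12799, PF13306, PF13855, PF08263 |

Only the NB-ARC accession is canonical; the others are curated defaults
and overrideable, because annotation releases differ in which LRR and CC
models they emit. The class label is composed deterministically: one
N-terminal letter (priority TIR > CC > RPW8 when several co-occur, the
conflict is logged), then "N", then "L" iff LRRs are present — giving
CNL/TNL/RNL/CN/TN/RN/NL/N.

Motif completeness is a separate, sequence-level test. The three NB-ARC
motifs are searched as regular expressions inside the NB-ARC interval
extended by a 30-residue flank, in order (each motif downstream of the
previous match):

* P-loop (Walker A): `G.{1,4}GK[ST]` — accepts the canonical plant NB-ARC
  form `GGVGKTT` as well as longer spacers;
* Kinase-2 (Walker B): `[LIVMF]{2}.{2}[DE]D.[WD]`;
* GLPL loop: `G[LIVMF]P[LS]`.

These are literature consensus forms, not the output of a de novo motif
discovery run, and are fully configurable; surveys that derived motifs
from their own data will not split motif-complete counts identically.

Gene-level census counts collapse multiple isoform proteins of one gene to
the architecture-richest protein (most domain flags, ties broken by class
order). A gene is motif-complete if any of its proteins is.

## Gene clusters

Two consecutive NB-ARC genes on a chromosome are linked when (a) the gap
from the end of the upstream gene to the start of the downstream gene is
at most 200,000 bp and (b) at most 7 annotated non-NB-ARC genes lie
strictly between them ("fewer than eight"); NB-ARC genes never count as
intervening. Clusters are maximal chains of linked genes; singletons are
not reported. The chain-of-consecutive-genes reading was chosen over an
all-pairs window because it is the most literal form of the rule; an
`all_pairs` mode is provided for sensitivity analysis. The implementation
is tested against an independent oracle: connected components of the
pairwise link graph (networkx).

Within-cluster similarity is percent identity of an optimal global
affine-gap alignment (BLOSUM62, gap open 10, extend 1), with identity
counted over aligned columns including gap columns — one declared
convention, with a shorter-sequence denominator available. Identities are
binned [0,50), [50,75), [75,100), {100} for display-style edge lists.
Pairwise alignment is performed with Biopython's `PairwiseAligner`; its
optimality is cross-checked against exhaustive alignment enumeration on
short sequences, and the gap cost convention is `open + (L-1)·extend` for
a gap of length L. Because co-optimal alignments need not be unique,
`align_pair` canonicalizes input order so reported identity is symmetric.

## Trees, bootstrap, nesting

Neighbor joining follows the Saitou–Nei agglomeration with two determinism
rules: Q-matrix ties are broken by the smallest (row, col) index pair, and
a negative branch length is clamped to zero with the deficit moved to the
sister branch. A three-taxon closed form finishes the tree. The
implementation is verified to recover the generating topology on additive
matrices (4–8 leaves) and against scikit-bio's NJ as an independent
implementation.

Multiple alignments for bootstrapping are built by progressive alignment
along the NJ guide tree: at each join the two groups' per-column consensus
strings are aligned with the same pairwise DP and the resulting gap
columns are propagated into every member row. This is adequate for
distance estimation and bootstrap support; it is not a curation-grade
aligner. Bootstrap support of an internal edge is the fraction of 100
column-resampled replicate trees containing its bipartition (p-distances
over shared non-gap columns; seeded and deterministic).

Cluster nesting is a bipartition test on the unrooted tree: the cluster
nests iff some edge separates exactly its members. A two-member cluster
therefore nests iff it forms a cherry, and single members nest trivially
(leaf edges).

## Integrated domains

Any Pfam hit on an NB-ARC protein outside the core sets is an integrated
domain; non-Pfam rows (coiled-coil predictions, TM helices, signal
peptides) are never ID evidence. Every copy is retained with a per-protein
copy count. Positions are relative to protein length: rel_start =
start/L, rel_end = end/L under the half-open convention, and rel_mid is
their midpoint — the primary position statistic because it is robust for
short domains. Categories (kinase, DNA-binding, other-signaling, unknown)
are assigned by accession lookup first, then case-insensitive name
keywords; the shipped map covers the commonly integrated types (kinases,
WRKY/AP2/B3/Myb/BED zinc-finger DNA binders, jacalin, thioredoxin,
ubiquitin-conjugating, kelch, GRAS, Exo70, ...) and is user-extensible;
anything unmapped is "unknown".

## Homology and progenitor assignment

ID homology is searched with the ID subsequence as query (a full-protein
flag exists): subjects sharing at least one exact 5-mer are aligned
locally (Smith–Waterman, BLOSUM62 10/1), and hits must reach 70% identity
over aligned columns and 80% query coverage. The k-mer prefilter is
verified against all-pairs Smith–Waterman to lose nothing at ≥70%
identity for desk-scale queries. A subject is an NLR homolog iff its own
domain table carries PF00931.

For hexaploid subgenomes, the best *T. urartu* and *Ae. tauschii*
identities per gene feed the progenitor category: A/D genes are "Match"
when the better hit comes from the expected progenitor (A↔TU, D↔AT; the
expected progenitor wins exact ties), otherwise "A"/"D"; B-subgenome genes
are always "B" (no sequenced progenitor) and unknown subgenomes "U".
Identity bins >90 / 70–90 / <70 summarize the strength of the better hit;
genes without hits keep their subgenome label with bin "<70".

## Splice variants

The reference transcript of a gene is the isoform with the richest domain
content (most distinct Pfam accessions; ties to the longest protein, then
to the earliest transcript in gene order, so an isoform with identical
content never displaces the primary transcript). Against it, a variant
excludes an ID accession if the accession is absent, and truncates it if
present at less than 0.8 of the reference instance's length (a convention;
configurable). Exclusion and truncation are mutually exclusive per
accession. Intron retention is geometric: reference introns (1-based in
transcription order, so "the 4th intron" reads as in gene-structure
figures) are retained when fully covered by a variant exon. Expression
vectors are joined by transcript ID; missing transcripts get null vectors.

## The synthetic-data generator

The generator emulates the statistical structure the analysis assumes, on
wheat-like chromosomes named 1A/1B/1D/...:

* NLR proteins are assembled from fixed consensus blocks (CC/TIR/RPW8 +
  NB-ARC with the three motifs planted at known offsets + LRR repeats)
  joined by random linkers drawn from an alphabet that cannot form the
  motif patterns, so motif positions are exactly known. Class labels are
  drawn from proportions shaped like a real wheat census (CNL 0.37,
  NL 0.35, N 0.15, CN 0.08, rare TIR/RPW8 classes); 70% of NB-ARCs are
  motif-complete, the rest have 1–3 motifs scrubbed.
* Tandem clusters: with probability 0.4 a founder is copied adjacent to
  itself (geometric extension 0.25, max 4 members), each copy diverged by
  per-site substitution at rate 0.10 with the motifs restored (purifying
  selection); 0–2 filler genes sit between members. Non-cluster units are
  spaced > 200 kb apart so the planted clusters are exactly the detectable
  ones. These defaults put ~60% of NB-ARC genes in clusters, the scale
  seen in hexaploid wheat.
* Integrated domains: one ID per receptor with probability 0.10, drawn
  from a 13-entry library with a preferred terminus per type (kinases and
  Myb/BED at the N-terminus, WRKY/B3/jacalin/etc. at the C-terminus);
  WRKY occasionally doubles, giving multi-copy IDs. The ID occupies its
  own codon-aligned exon.
* Alternative transcripts: for ID-bearing founders, with probability 0.5
  a variant is emitted that excludes the ID exon (p = 0.3), truncates it
  to half length (p = 0.15), or retains an intron / duplicates the
  reference otherwise; independently, any NLR founder can gain an
  intron-retention variant (p = 0.1), sometimes spanning two consecutive
  introns. All exon edits are codon-aligned so isoform proteins are exact
  block edits of the reference.
* Progenitor and comparator proteomes: each ID-bearing gene's protein is
  diverged at 5% into its expected progenitor (TU for subgenome A, AT for
  D) and at 15% into the other, with presence probabilities 0.95/0.90; a
  barley-like comparator (HV) receives homologs at 12% divergence, 80%
  presence. 68.5% of homologs keep the whole NLR (and its PF00931 row);
  the rest are standalone ID fragments — mirroring the observation that
  most ID homologs outside close relatives are non-NLR proteins.
* The annotation table is written from truth with an optional per-row
  false-negative rate; expression values are lognormal.

Substitution is to a uniformly chosen *different* residue, so expected
identity after divergence at rate r is exactly 1 − r — kept analytic so
recovery tests have closed-form expectations. What the generator does not
emulate: indels (off by default), codon-level evolution, annotation false
positives or boundary noise, overlapping genes, UTRs, and nucleotide
sequences (gene models carry coordinates only). Passing recovery tests
therefore demonstrates correctness of the analysis logic under the stated
noise model, not robustness to every artifact of real annotation
pipelines.

## Problem sizes and checks

The acceptance script simulates 2,000 annotated loci on 10 chromosomes
(25% NLR; ~780 NLR genes with duplicates) — large enough for stable
fractions, small enough to run in seconds. Statistical-recovery tests use
25 seeds at the same scale with a 5% annotation false-negative rate and
check recovered rates against each seed's realized planted rate within a
99% binomial CI (variance floored near rate 0/1 to avoid a degenerate
interval). Alignment scores are checked against exhaustive enumeration on
≥10,000 random short pairs; NJ against 100 random additive matrices; all
stochastic steps take explicit seeds and are byte-reproducible.

## Known limitations

* CC detection inherits the weakness of annotation-driven surveys: real
  coiled-coils are underannotated by Pfam alone; the name-keyword fallback
  helps only if the input table carries coiled-coil rows.
* The progressive aligner is consensus-based and can misplace gaps in
  low-identity groups; bootstrap supports on such groups are
  correspondingly rough.
* The homology search is exact-k-mer seeded; extremely diverged homologs
  (< ~60% identity) can be missed, which is acceptable above the 70%
  reporting threshold but makes the tool unsuitable for remote homology.
* Progenitor categories depend on subgenome parsing from chromosome
  names; assemblies with non-standard naming need an ID map or yield "U".
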