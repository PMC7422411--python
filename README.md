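# nlrforge

Annotation-driven analysis of plant NLR immune receptor repertoires, built
for polyploid genomes like bread wheat (*Triticum aestivum*).

Plant nucleotide-binding leucine-rich repeat receptors (NLRs) detect
pathogen effectors and trigger immunity. A repertoire-scale survey of these
genes asks a recurring set of questions: which proteins carry the defining
NB-ARC domain (Pfam PF00931)? What architecture does each receptor have
(CNL, TNL, RNL, ... composed from coiled-coil/TIR/RPW8 N-termini, the
NB-ARC, and leucine-rich repeats)? Which genes sit in tandem-duplication
clusters? Which receptors carry *integrated domains* (IDs) — non-canonical
fusions such as kinase or WRKY domains that may act as effector baits or
signaling modules? Do ID homologs in related proteomes also encode NLRs,
and do hexaploid subgenomes match their expected progenitors? And do
alternative transcripts include or exclude the ID, e.g. via exon skipping
or intron retention?

`nlrforge` answers each question from standard inputs — a protein FASTA,
gene models in GFF3, and an InterProScan-style domain table — and ships a
synthetic-genome generator that plants every one of these structures with
known ground truth, so the whole pipeline is testable end to end.

## Core definitions

* **NB-ARC gene**: any gene with a protein carrying a PF00931 hit.
* **Motif-complete NB-ARC**: the Walker-A P-loop, Walker-B Kinase-2 and
  GLPL motifs all match (configurable regular expressions) inside the
  NB-ARC interval, in order.
* **Gene cluster**: a maximal chain of NB-ARC genes in which consecutive
  members are ≤ 200,000 bp apart (end-to-start) and separated by fewer
  than eight intervening non-NB-ARC genes.
* **Percent identity**: 100 × identical columns / aligned columns of an
  optimal affine-gap alignment (BLOSUM62, gap open 10, extend 1; global by
  default).
* **Integrated domain**: a Pfam hit on an NB-ARC protein outside the core
  CC/TIR/RPW8 + NB-ARC + LRR accession sets; positions are reported
  relative to protein length (0–1) and grouped into kinase / DNA-binding /
  other-signaling / unknown categories.
* **Cluster nesting**: cluster members are monophyletic on a
  neighbor-joining tree (bipartition test; 100 bootstrap replicates by
  column resampling).
* **Progenitor categories**: per ID-bearing gene, the better of the best
  *T. urartu* (A-genome progenitor) and *Ae. tauschii* (D-genome
  progenitor) hits gives "Match" when it comes from the expected
  progenitor, "A"/"D" when it does not, "B" for the B subgenome (no
  sequenced progenitor), "U" when the subgenome is unknown.

## Worked example

Generate a small synthetic genome and census it:

```sh
nlrforge simulate --seed 5 --out demo/sim
nlrforge census --proteins demo/sim/proteome.fasta \
                --domains demo/sim/domains.tsv \
                --gff demo/sim/genes.gff3 --out demo/census
head -12 demo/census/census.tsv
```

```
section	key	count
total	genes	218
total	proteins	236
total	motif_complete_genes	160
class	CNL	85
class	TNL	0
class	RNL	3
class	CN	25
class	TN	5
class	RN	7
class	NL	64
class	N	29
```

218 NB-ARC genes were found (236 proteins, since alternative transcripts
are annotated separately); 160 genes are motif-complete (73%, close to the
generator's planted 70%), and CNL (CC + NB-ARC + LRR) and NL are the
dominant classes, as in real wheat. `nlrforge cluster`, `nlrforge ids`,
`nlrforge homology` and `nlrforge splice` produce the remaining reports,
and `nlrforge run --config config.yaml` executes all stages with a run
manifest. The same functionality is available as a library
(`nlrforge.classify`, `nlrforge.clusters`, `nlrforge.integrated`,
`nlrforge.homology`, `nlrforge.splice`, `nlrforge.simulate`,
`nlrforge.pipeline`).

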