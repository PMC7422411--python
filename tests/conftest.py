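"""Shared fixtures: a small synthetic genome generated once per session."""

import collections

import pytest

from nlrforge import io as nio
from nlrforge.simulate import SimulationConfig, generate


@pytest.fixture(scope="session")
def small_dataset(tmp_path_factory):
    """Noise-free synthetic genome with planted truth (session-scoped)."""
    outdir = tmp_path_factory.mktemp("synth")
    # ID insertion raised above the repertoire-wide default so every ID
    # accession appears a few times in a genome this small
    cfg = SimulationConfig(
        seed=42, n_chromosomes=3, genes_per_chromosome=60, id_insertion_prob=0.35
    )
    truth, paths = generate(cfg, outdir)
    return truth, paths


@pytest.fixture(scope="session")
def small_parsed(small_dataset):
    truth, paths = small_dataset
    proteome = nio.read_fasta(paths["proteome"])
    genes, transcripts = nio.read_gff3(paths["gff3"])
    hits = nio.read_domain_table(paths["domains"], proteome=proteome)
    hits_by_protein = collections.defaultdict(list)
    for h in hits:
        hits_by_protein[h.protein_id].append(h)
    return {
        "truth": truth,
        "paths": paths,
        "proteome": proteome,
        "proteins_by_id": {p.protein_id: p for p in proteome},
        "genes": genes,
        "transcripts": transcripts,
        "hits": hits,
        "hits_by_protein": hits_by_protein,
        "p2g": {tid: g.gene_id for g in genes for tid in g.transcript_ids},
    }
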