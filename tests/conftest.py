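import numpy as np
import pytest

from splicearch.genemodel import GeneModel
from splicearch.synthetic import GenomeSpec, TruthConfig, generate_genome, simulate_reads


@pytest.fixture(scope="session")
def small_synth():
    """A small genome shared by read-free structural tests."""
    return generate_genome(GenomeSpec(n_genes=60, seed=101))


@pytest.fixture(scope="session")
def es_run():
    """Genome + deep reads with isolated planted skip events (no retention)."""
    spec = GenomeSpec(n_genes=150, seed=202)
    tc = TruthConfig(mode="isolated", retention_choices=(0.0,))
    syn = generate_genome(spec, tc)
    reads = simulate_reads(syn.models, syn.genome, syn.truth, 400_000, seed=203)
    return syn, reads


@pytest.fixture
def toy_gene():
    """Hand-built two-intron plus-strand gene on a known sequence.

    Exons: [0,30) [50,80) [110,140); introns: [30,50) [80,110).
    """
    rng = np.random.default_rng(7)
    seq = "".join(rng.choice(list("ACGT"), 140))
    model = GeneModel("gX", "gX.t1", "c1", "+", ((0, 30), (50, 80), (110, 140)))
    return model, {"c1": seq}


@pytest.fixture
def toy_gene_minus(toy_gene):
    """Same structure on the minus strand of a copied contig."""
    model, genome = toy_gene
    minus = GeneModel("gY", "gY.t1", "c1", "-", model.exons)
    return minus, genome
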