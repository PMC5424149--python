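import numpy as np
import pytest

from irtools.genome_annotation import GenomeSequence, derive_introns
from irtools.synthetic_data import (
    SimulationConfig,
    simulate_genome_annotation,
    simulate_fragments,
    simulate_methylation,
)


@pytest.fixture(scope="session")
def small_sim():
    """A compact simulated dataset shared across read-only tests."""
    cfg = SimulationConfig(seed=7, n_genes=6, fragments_per_gene=2000)
    genome, genes, truth = simulate_genome_annotation(cfg)
    introns = derive_introns(genes)
    fragments = simulate_fragments(cfg, genes, truth)
    return cfg, genome, genes, truth, introns, fragments


@pytest.fixture(scope="session")
def methylation_sim():
    """Larger gene set with a planted junction beta dip for profile tests."""
    cfg = SimulationConfig(seed=3, n_genes=40, retention_range=(0.0, 0.8))
    genome, genes, truth = simulate_genome_annotation(cfg)
    introns = derive_introns(genes)
    cpg, signals = simulate_methylation(cfg, genome, truth)
    labels = {r.intron_id: bool(r.retained) for r in truth.introns.itertuples()}
    return cfg, genome, introns, truth, cpg, signals, labels


@pytest.fixture(scope="session")
def random_genome():
    rng = np.random.default_rng(5)
    seq = "".join(rng.choice(list("ACGT"), size=2000))
    return GenomeSequence({"chr1": seq})
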