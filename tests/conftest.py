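import numpy as np
import pandas as pd
import pytest

from poeseq import SimConfig, make_design


@pytest.fixture(scope="session")
def default_design():
    return make_design(SimConfig(seed=0))


@pytest.fixture(scope="session")
def small_seq_sim():
    """One-colony sequence-level simulation, shared across read tests."""
    from poeseq import simulate_sequences

    cfg = SimConfig(
        n_genes=10,
        genome_contig_length=6000,
        mean_allelic_depth=15,
        snps_per_gene_mean=5,
        seed=3,
    )
    return cfg, simulate_sequences(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
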