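import numpy as np
import pytest

from zieqtl.sim import SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """Desk-scale panel reused by read-only tests: 60 accessions, 20 genes."""
    cfg = SimConfig(
        n_accessions=60, snps_per_chrom=400, n_genes=20, seed=7, dropout_tau=0.3
    )
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def default_dataset():
    """Panel at the default study-design scale (140 accessions)."""
    return simulate_dataset(SimConfig(seed=2))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
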