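import numpy as np
import pytest

from oscellkit.config import SimConfig
from oscellkit import synthetic


@pytest.fixture(scope="session")
def small_sim():
    """One small simulated dataset shared by read-only tests."""
    cfg = SimConfig(seed=11, n_genes=300, cells_per_sample=150,
                    n_cnv_genes=60, n_amplified_genes=10)
    return synthetic.simulate_counts(cfg)


@pytest.fixture(scope="session")
def small_cnv():
    cfg = SimConfig(seed=11, cells_per_sample=150, n_cnv_genes=60,
                    n_amplified_genes=10)
    return synthetic.simulate_cnv_states(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
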