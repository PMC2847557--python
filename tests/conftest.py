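import numpy as np
import pytest
from hypothesis import settings

import amplibias as ab

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_sim():
    """Default study-shaped simulation: 2000 genes, 2 tissues x 3 protocols
    x 3 replicates, 20 over + 20 under planted genes."""
    return ab.generate_probe_data(ab.SimConfig(seed=1))


@pytest.fixture(scope="session")
def default_expr(default_sim):
    data, _ = default_sim
    return ab.rma_summarize(data)


@pytest.fixture(scope="session")
def null_sim():
    """Shift-free simulation for null calibration."""
    cfg = ab.SimConfig(n_over=0, n_under=0, seed=7)
    return ab.generate_probe_data(cfg)


@pytest.fixture(scope="session")
def null_expr(null_sim):
    data, _ = null_sim
    return ab.rma_summarize(data)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
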