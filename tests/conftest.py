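import numpy as np
import pytest

from vtdeconf import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """A small confounded dataset shared by training-level tests."""
    cfg = SimulationConfig(n_treated=40, n_control=120, p=6, T=6,
                           gamma=0.3, seed=11)
    return simulate_dataset(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
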