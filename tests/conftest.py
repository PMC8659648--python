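import numpy as np
import pytest

from manifolddim import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def linear_ds_small():
    """Noise-free linear d=6 dataset at reduced sample count (fast)."""
    return simulate_dataset(SimulationConfig(d=6, M=1500, N=96, seed=101))


@pytest.fixture(scope="session")
def nonlinear_ds_small():
    """Noise-free nonlinear (alpha=16) d=6 dataset at reduced sample count."""
    return simulate_dataset(SimulationConfig(d=6, M=1500, N=96, alpha=16.0, seed=102))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
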