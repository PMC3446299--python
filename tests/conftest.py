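import numpy as np
import pytest

from polystress import SimulationConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_config():
    """A fast, fully planted configuration for ground-truth tests."""
    return SimulationConfig(n_genes=100, seed=42)


@pytest.fixture
def noiseless_config():
    """Zero-noise configuration: downstream statistics take identity values."""
    return SimulationConfig(
        n_genes=20,
        seed=7,
        noise_sd_log=0.0,
        planted_fractions={},
    )


def random_profiles(rng, n):
    """Random points on the 4-simplex scaled to percentages."""
    raw = rng.dirichlet(np.ones(4), size=n)
    return 100.0 * raw
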