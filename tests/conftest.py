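"""Shared fixtures: tiny phantom subjects and cohorts generated at test time."""

import numpy as np
import pytest

from dwianomaly import PhantomConfig, make_cohort, simulate_dwi


@pytest.fixture(scope="session")
def tiny_config():
    """Small fast phantom: 16³ grid, 6 diffusion directions."""
    return PhantomConfig(grid_shape=(16, 16, 16), n_channels=6, seed=7)


@pytest.fixture(scope="session")
def tiny_volume(tiny_config):
    vol, _ = simulate_dwi(tiny_config)
    return vol


@pytest.fixture(scope="session")
def tiny_cohort(tiny_config):
    """Six healthy subjects at the small scale (for fast training tests)."""
    return [v for v, _ in make_cohort(6, tiny_config, seed=3)]


@pytest.fixture(scope="session")
def tiny_lesioned(tiny_config):
    """Two lesioned subjects at the small scale."""
    return make_cohort(2, tiny_config, seed=21, lesioned=True)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
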