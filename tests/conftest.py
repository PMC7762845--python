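import numpy as np
import pytest

from neoqc import (
    SimulationConfig,
    build_nuisance_matrix,
    highpass_filter,
    regress_nuisance,
    simulate_scan,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def default_scan():
    """One default-condition synthetic scan, shared across tests."""
    return simulate_scan(seed=0)


@pytest.fixture(scope="session")
def filtered_scan(default_scan):
    """The default scan after drift filtering (the pre-denoise state)."""
    return highpass_filter(default_scan.volume)


@pytest.fixture(scope="session")
def denoised_scan(default_scan, filtered_scan):
    """The default scan after filtering and true-noise regression."""
    design = build_nuisance_matrix(default_scan.truth, default_scan.motion)
    return regress_nuisance(filtered_scan, design)


@pytest.fixture(scope="session")
def tiny_config():
    """A fast, small configuration for tests that build many scans."""
    return SimulationConfig(shape=(16, 16, 10, 120), n_networks=2,
                            n_motion_spikes=2)
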