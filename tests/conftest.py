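import numpy as np
import pytest

from ringmetrics import QuantConfig, SimParams, simulate_division_movie


@pytest.fixture(scope="session")
def noiseless_params():
    return SimParams(noise_model="none", bleach_rate_per_frame=0.0, background_level=0.0)


@pytest.fixture(scope="session")
def noiseless_sim(noiseless_params):
    """One clean simulated cell shared across tests (simulation is pure)."""
    return simulate_division_movie(noiseless_params)


@pytest.fixture(scope="session")
def realistic_sim():
    """Default study conditions: background, bleaching and Gaussian noise."""
    params = SimParams(seed=11)
    return params, simulate_division_movie(params)


@pytest.fixture
def config():
    return QuantConfig()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
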