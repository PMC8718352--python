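import numpy as np
import pytest
from hypothesis import settings, HealthCheck

from sulcimap.preprocess import preprocess_recording
from sulcimap.simulate import SimulationParams, simulate_session

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_params():
    """Reference conditions with a reduced trial count to keep unit tests
    fast; the full trial count is exercised in the acceptance tests."""
    return SimulationParams(seed=11, n_trials=30)


@pytest.fixture(scope="session")
def session(small_params):
    return simulate_session(small_params)


@pytest.fixture(scope="session")
def traces(session):
    recording, _, _ = session
    return preprocess_recording(recording)


@pytest.fixture(scope="session")
def clean_session():
    """Noise-free, jitter-free session: deterministic round-trip oracle."""
    params = SimulationParams(seed=0, n_trials=2, noise_sd_uV=0.0,
                              latency_jitter_ms=0.0, emg_noise_sd_uV=0.0)
    return params, simulate_session(params)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
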