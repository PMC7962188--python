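import numpy as np
import pytest
from hypothesis import settings

from wavebp.preprocess import FilterSpec, design_bandpass

settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")
from wavebp.synth import SimulationParams, simulate_record


@pytest.fixture(scope="session")
def filter_taps():
    """Default band-pass design, shared across tests (remez is not free)."""
    return design_bandpass(FilterSpec())


@pytest.fixture(scope="session")
def clean_record():
    """Noise-free 60 s record with known targets 120/80 and lag 10."""
    return simulate_record(SimulationParams(
        duration_s=60.0, sbp_target=120.0, dbp_target=80.0,
        transit_lag_samples=10, noise_sd=0.0, baseline_wander_amp=0.0,
        artifact_rate=0.0, seed=11))


@pytest.fixture(scope="session")
def noisy_record():
    """60 s record with mild noise and wander, lag 15."""
    return simulate_record(SimulationParams(
        duration_s=60.0, sbp_target=135.0, dbp_target=88.0,
        transit_lag_samples=15, noise_sd=0.02, baseline_wander_amp=0.05,
        artifact_rate=0.0, seed=12))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
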