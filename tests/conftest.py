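"""Shared fixtures: small simulated stacks reused across test modules."""

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from pemkit import synthetic_data as sd

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def bulk_small():
    """Default-condition bulk run on a reduced 60x80 grid (full schedule)."""
    cfg = sd.BulkConfig(shape=(60, 80))
    stack, truth = sd.simulate_bulk(cfg, seed=1)
    return cfg, stack, truth


@pytest.fixture(scope="session")
def bulk_noise_free():
    """Noise-free, fast-kinetics bulk run where calibration must be exact."""
    cfg = sd.BulkConfig(
        shape=(40, 50),
        kinetics=sd.GrowthKinetics(tau_s=1e-3, spike_amplitude_mdeg=0.0),
        noise_sigma_au=0.0,
    )
    stack, truth = sd.simulate_bulk(cfg, seed=0)
    return cfg, stack, truth


@pytest.fixture(scope="session")
def local_default():
    """Default-condition localized delivery on a reduced 240x320 grid."""
    cfg = sd.LocalConfig(shape=(240, 320), duration_s=12.0)
    stack, truth = sd.simulate_local(cfg, seed=3)
    return cfg, stack, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
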