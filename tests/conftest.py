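import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from ucachar.synthetic import BolusConfig, SimulationConfig


@pytest.fixture
def clean_cfg():
    """Noise-free two-harmonic scatter configuration."""
    return SimulationConfig(
        f0=2.25,
        n_cycles=20,
        noise_rms=0.0,
        harmonic_ratios={1: 1.0, 2: 0.1},
        seed=11,
    )


@pytest.fixture
def noisy_cfg():
    """Default-noise single-tone configuration (SNR 40 dB)."""
    return SimulationConfig(f0=2.25, n_cycles=20, noise_rms=0.01, seed=11)


@pytest.fixture
def dceus_cfg():
    return SimulationConfig(f0=3.5, n_cycles=3, noise_rms=0.01, seed=11)


@pytest.fixture
def bolus():
    return BolusConfig()


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
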