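import numpy as np
import pytest

from pivotshift import SimulationConfig, simulate_cohort, simulate_recording


@pytest.fixture(scope="session")
def default_cfg():
    return SimulationConfig()


@pytest.fixture(scope="session")
def small_cohort():
    """50-test labeled cohort at default conditions (seeded)."""
    return simulate_cohort(50, seed=7)


@pytest.fixture()
def clean_recording():
    """One noiseless standardized recording (class 3, grade 2)."""
    cfg = SimulationConfig(noise_sd_deg_s=0.0)
    return simulate_recording(2, 3, cfg, seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
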