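import numpy as np
import pytest

from skewage import AgeStats, SynthConfig, generate, make_schedule


@pytest.fixture(scope="session")
def camcan_like():
    """Default synthetic cohort: 650 subjects, uniform ages 18-88, five
    features with per-feature attenuation slope ~0.7."""
    return generate(SynthConfig(seed=0))


@pytest.fixture(scope="session")
def dilution_r05():
    """Single-feature cohort with noise_sd = sd(ages): attenuation slope 0.5,
    population ADC = -1/sqrt(2)."""
    sd_y = 70.0 / np.sqrt(12.0)
    return generate(SynthConfig(n=10_000, p=1, noise_sd=sd_y, seed=11))


@pytest.fixture
def centered_schedule():
    return make_schedule(AgeStats(0.0, 100.0, 50.0), 1.0, "piecewise_median")
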