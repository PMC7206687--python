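import numpy as np
import pytest

from echtkin.cohort import default_design, default_hyper, simulate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(20231031)


@pytest.fixture(scope="session")
def small_cohort():
    """Noisy cohort at the default study conditions, 3 animals per arm."""
    return simulate_cohort(default_design(3), default_hyper(), seed=42)


@pytest.fixture(scope="session")
def noiseless_cohort():
    """Deterministic-trajectory cohort: no measurement noise, no attrition."""
    hyper = default_hyper(noise_cv=0.0, hazard_pre=0.0, hazard_post=0.0)
    return simulate_cohort(default_design(2), hyper, seed=7)
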