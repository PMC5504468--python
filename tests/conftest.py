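import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import scalpmap as sm

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

COHORT_SEED = 1234


@pytest.fixture(scope="session")
def sphere100():
    """Unit-test head: icosphere of radius 100 mm."""
    return sm.icosphere(100.0, 4)


@pytest.fixture(scope="session")
def sphere_fiducials():
    return {
        "Nz": np.array([0.0, 100.0, 0.0]),
        "Iz": np.array([0.0, -100.0, 0.0]),
        "AL": np.array([-100.0, 0.0, 0.0]),
        "AR": np.array([100.0, 0.0, 0.0]),
    }


@pytest.fixture(scope="session")
def default_model():
    return sm.GrowthModel(seed=COHORT_SEED)


@pytest.fixture(scope="session")
def cohort16(default_model):
    """The stated-world cohort: n=16, ages 3-22 months, default growth/noise."""
    return sm.make_cohort(default_model, 16, (3.0, 22.0), seed=COHORT_SEED)


@pytest.fixture(scope="session")
def montages16(cohort16):
    return {s.subject_id: sm.place_montage(s.scalp, s.fiducials, "10-10") for s in cohort16}


@pytest.fixture(scope="session")
def template16(cohort16):
    return min(cohort16, key=lambda s: abs(s.age_months - 12.0))
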