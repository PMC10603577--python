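import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import lungscreen as ls
from lungscreen.synthetic_cohort import SyntheticSpec, generate_cohort

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def original_model():
    return ls.load_original_model()


@pytest.fixture(scope="session")
def packaged_counts():
    return ls.load_packaged_counts()


@pytest.fixture(scope="session")
def cohort_100k_null(original_model):
    """Large cohort drawn from the packaged model (intercept tuned to the
    1.4% target); attrs carry the tuned offset."""
    return generate_cohort(SyntheticSpec(n=100_000, seed=7))


@pytest.fixture(scope="session")
def true_model_100k_null(original_model, cohort_100k_null):
    """The exact model the null cohort's outcomes were drawn from."""
    return original_model.with_race_update(
        cohort_100k_null.attrs["true_intercept_offset"],
        original_model.race_coefficients,
        "-true",
    )


@pytest.fixture(scope="session")
def cohort_20k(original_model):
    return generate_cohort(SyntheticSpec(n=20_000, seed=3))


def toy_record(**overrides):
    """A fixed, fully specified participant for scalar-operation tests."""
    fields = dict(
        id="p1",
        race_ethnicity="white",
        age=60.0,
        sex="male",
        education=3,
        bmi=26.0,
        copd_emphysema=False,
        personal_cancer_history=False,
        family_history_lung_cancer=False,
        smoking_status="former",
        intensity=20.0,
        duration=30.0,
        quit_years=10.0,
        pack_years=30.0,
        lung_cancer_6yr=False,
    )
    fields.update(overrides)
    return ls.ParticipantRecord(**fields)


@pytest.fixture
def record_factory():
    return toy_record
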