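import numpy as np
import pytest

from rhythmrec.core import (
    Action,
    FeatureScaler,
    OutcomeRecord,
    PatientRecord,
    fit_scaler,
)
from rhythmrec.synthetic import (
    default_world,
    q_oracle_scaler,
    q_oracle_world,
    sample_cohort,
    suboptimal_expert_world,
)


@pytest.fixture
def valid_record():
    return PatientRecord(
        age=67.0,
        af_duration_months=18.0,
        heart_failure=0,
        la_enlargement=1,
        resting_hr=92.0,
        hypertension=1,
        bmi=31.5,
        symptomatic=1,
        patient_id="p001",
    )


@pytest.fixture
def unit_scaler():
    """Scaler with zero means and unit SDs: encoding passes raw values."""
    return FeatureScaler(means=(0.0, 0.0, 0.0, 0.0), sds=(1.0, 1.0, 1.0, 1.0))


@pytest.fixture(scope="session")
def world():
    return default_world()


@pytest.fixture(scope="session")
def oracle_world():
    return q_oracle_world()


@pytest.fixture(scope="session")
def oracle_scaler():
    return q_oracle_scaler()


@pytest.fixture(scope="session")
def subopt_world():
    return suboptimal_expert_world()


@pytest.fixture(scope="session")
def labeled_cohort(world):
    return sample_cohort(world, 200, seed=42)


@pytest.fixture(scope="session")
def cohort_scaler(labeled_cohort):
    return fit_scaler(labeled_cohort)


def make_record(**overrides):
    base = dict(
        age=60.0,
        af_duration_months=12.0,
        heart_failure=0,
        la_enlargement=0,
        resting_hr=80.0,
        hypertension=0,
        bmi=27.0,
        symptomatic=0,
    )
    base.update(overrides)
    return PatientRecord(**base)
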