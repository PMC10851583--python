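import pytest

from varprio.classifier import classify_records
from varprio.cohort import Patient
from varprio.simulate import CohortConfig, build_synthetic_cds, generate_cohort, table4_fixture


@pytest.fixture(scope="session")
def table4():
    return table4_fixture()


@pytest.fixture(scope="session")
def table4_calls(table4):
    return classify_records(table4)


@pytest.fixture(scope="session")
def default_cds():
    return build_synthetic_cds()


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort plus its classified variant calls."""
    cohort, records = generate_cohort(CohortConfig(), seed=11)
    return cohort, classify_records(records)


_PATIENT_DEFAULTS = dict(
    age=40.0, sex="M", bmi=27.0, wbc=14.0, crp=100.0, bun=5.0,
    creatinine=70.0, calcium=2.1, glucose=9.0, tg=15.0, tc=8.0,
)


def make_patient(pid: str, arm: str = "HLAP", **overrides) -> Patient:
    kwargs = dict(_PATIENT_DEFAULTS)
    kwargs.update(overrides)
    return Patient(id=pid, arm=arm, **kwargs)


@pytest.fixture
def patient_factory():
    return make_patient
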