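import pytest

from vitalindex.cohort import Cohort, PatientRecord
from vitalindex.synthetic import GeneratorConfig, generate_cohort


def make_record(**overrides) -> PatientRecord:
    """A clinically unremarkable admission, field-overridable."""
    base = dict(
        patient_id="p1",
        age=40,
        sex="male",
        sbp=110.0,
        dbp=70.0,
        pulse=80.0,
        resp_rate=16.0,
        temperature=36.8,
        gcs=15,
        wbc=8.0,
        platelets=250.0,
        suspected_infection=True,
        died_in_hospital=False,
    )
    base.update(overrides)
    return PatientRecord(**base)


@pytest.fixture
def record_factory():
    return make_record


@pytest.fixture
def small_cohort(record_factory) -> Cohort:
    records = [
        record_factory(patient_id="a", pulse=108, resp_rate=28, sbp=100, dbp=60,
                       temperature=37.0, gcs=15, died_in_hospital=False),
        record_factory(patient_id="b", pulse=110, resp_rate=30, sbp=85, dbp=50,
                       temperature=38.5, gcs=12, died_in_hospital=True),
        record_factory(patient_id="c", pulse=60, resp_rate=12, sbp=120, dbp=80,
                       temperature=36.5, gcs=15, died_in_hospital=False),
    ]
    return Cohort(label="small", records=records)


@pytest.fixture(scope="session")
def medium_synthetic_cohort() -> Cohort:
    """One mid-size generated cohort reused by several statistical tests."""
    return generate_cohort(GeneratorConfig(n=5000, seed=101))
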