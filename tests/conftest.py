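import datetime as dt

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from vpapkpd.dataset import (
    Cohort,
    ConcentrationRecord,
    SubjectCovariates,
    default_uln_table,
)

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def uln():
    return default_uln_table()


def make_subject(subject_id="S001", **kw):
    defaults = dict(
        subject_id=subject_id,
        age=18.0,
        sex="male",
        body_weight=50.0,
        daily_dose=1000.0,
        sod2="ValVal",
        cyp2c9="*1/*1",
        cyp2c19="homEM",
        gstm1="present",
        gstt1="null",
        intellectual_disability=False,
        comeds=frozenset(),
        vpa_start_date=dt.date(2005, 3, 1),
    )
    defaults.update(kw)
    return SubjectCovariates(**defaults)


@pytest.fixture
def three_subject_cohort():
    subjects = [
        make_subject("S001"),
        make_subject("S002", sex="female", daily_dose=600.0, sod2="ValAla"),
        make_subject("S003", intellectual_disability=True, comeds=frozenset({"CBZ"})),
    ]
    records = [
        ConcentrationRecord(sid, t, 500.0, 24.0, v)
        for sid, t, v in [
            ("S001", 4.0, 70.2), ("S001", 14.0, 62.1),
            ("S002", 6.5, 55.3), ("S002", 20.0, 48.8),
            ("S003", 2.0, 81.0), ("S003", 10.0, 74.4),
        ]
    ]
    return Cohort(subjects, records, [])


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(42)
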