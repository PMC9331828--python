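import datetime as dt

import pytest

from fcs_screen.records_io import (
    CriteriaConfig,
    DiagnosisEvent,
    LabMeasurement,
    Patient,
    PatientHistory,
)


@pytest.fixture
def cfg() -> CriteriaConfig:
    return CriteriaConfig()


def make_history(
    tg=(),
    codes=(),
    birth_year=1975,
    sex="male",
    start=dt.date(2010, 1, 15),
    fasting=True,
    patient_id="P1",
    extra_labs=(),
):
    """Build a history with monthly TG measurements and dated diagnoses.

    ``tg`` may contain floats (uses the default fasting flag) or
    ``(value, fasting)`` pairs. ``codes`` may contain codes (consecutive
    monthly dates) or ``(code, date)`` pairs.
    """
    patient = Patient(patient_id, sex, birth_year)
    labs = []
    for i, item in enumerate(tg):
        if isinstance(item, tuple):
            value, flag = item
        else:
            value, flag = item, fasting
        date = _add_months(start, i)
        labs.append(LabMeasurement(patient_id, date, "TG", float(value), flag))
    labs.extend(extra_labs)
    labs.sort(key=lambda l: l.date)
    diagnoses = []
    for i, item in enumerate(codes):
        if isinstance(item, tuple):
            code, date = item
        else:
            code, date = item, _add_months(dt.date(2011, 1, 10), i)
        diagnoses.append(DiagnosisEvent(patient_id, date, code))
    diagnoses.sort(key=lambda d: d.date)
    return PatientHistory(patient=patient, labs=labs, diagnoses=diagnoses)


def _add_months(date: dt.date, months: int) -> dt.date:
    month = date.month - 1 + months
    return dt.date(date.year + month // 12, month % 12 + 1, date.day)
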