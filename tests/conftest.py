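from datetime import datetime, timedelta

import numpy as np
import pytest

from aki_impact.records import AdmissionRecord, ScrSeries

EPOCH = datetime(2015, 1, 5, 14, 0)

ALL_FALSE = {
    "ckd": False,
    "diabetes": False,
    "heart_failure": False,
    "liver_disease": False,
    "hypertension": False,
    "vascular_disease": False,
}


def make_record(
    scr_pairs,
    *,
    history=(),
    age=72.0,
    los_days=5.0,
    died_day=None,
    site="intervention",
    period="pre",
    specialty="medical",
    direct_ed_to_icu=False,
    icu=False,
    comorbidities=None,
    news=1,
    patient_id="p0",
    admission_id="p0-a0",
):
    """Minimal valid admission around an SCr series, for unit tests."""
    admission = EPOCH
    death_time = admission + timedelta(days=died_day) if died_day is not None else None
    discharge = death_time if death_time else admission + timedelta(days=los_days)
    return AdmissionRecord(
        patient_id=patient_id,
        admission_id=admission_id,
        site=site,
        period=period,
        age=age,
        comorbidities=dict(comorbidities or ALL_FALSE),
        news=news,
        resp_rate_ge20=False,
        avpu_below_alert=False,
        admission_time=admission,
        discharge_time=discharge,
        death_in_hospital=death_time is not None,
        death_time=death_time,
        icu_escalation=icu,
        icu_time=admission + timedelta(days=1) if icu else None,
        specialty=specialty,
        direct_ed_to_icu=direct_ed_to_icu,
        baseline_scr_history=list(history),
        scr_series=ScrSeries.from_pairs(scr_pairs),
    )


@pytest.fixture
def flat_record():
    return make_record([(0, 80), (24, 81), (48, 79), (72, 80)])


def random_series(rng: np.random.Generator) -> ScrSeries:
    """Random series spanning threshold-relevant and horizon-relevant cases."""
    n = int(rng.integers(2, 12))
    gaps = rng.uniform(2.0, 40.0, n - 1)
    times = np.concatenate([[0.0], np.cumsum(gaps)])
    values = rng.uniform(40.0, 400.0, n)
    return ScrSeries(times, values)
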