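"""Cohort construction: study inclusion/exclusion rules and per-admission
analysis outcomes.

Inclusion requires age >= 18, a medical-specialty admission, at least one
night in hospital (discharge on a later calendar day than admission), a
repeated serum-creatinine measurement, and no direct emergency-department to
ICU transfer.  An excluded admission carries exactly one reason — the first
matching in the order the study lists its exclusion criteria: direct ED->ICU,
under 18, non-medical, no overnight stay — with the repeat-creatinine
(inclusion-derived) reason last.
"""
from __future__ import annotations

from dataclasses import dataclass
from datetime import timedelta
from typing import Iterable, Optional, Sequence

import pandas as pd

from .alerts import AlertState
from .detect import DEFAULT_THRESHOLDS, Thresholds, classify_admission
from .exceptions import DataError
from .records import COMORBIDITY_FLAGS, AdmissionRecord, AkiClassification

EXCLUSION_ORDER = ("direct_ed_icu", "under18", "non_medical", "no_overnight", "single_scr")


@dataclass
class CohortRow:
    """One admission, analysis-ready (or excluded with its reason)."""

    admission_id: str
    patient_id: str
    site: str
    period: str
    age: float
    comorbidities: dict[str, bool]
    included: bool
    exclusion_reason: Optional[str] = None
    aps_score: Optional[int] = None
    alert_state: Optional[str] = None
    aki_category: Optional[str] = None
    aki_onset_hours: Optional[float] = None
    aki_max_stage: Optional[int] = None
    peak_rise_umol_l: Optional[float] = None
    died_in_hospital: Optional[bool] = None
    died_by_day7: Optional[bool] = None
    icu_escalation: Optional[bool] = None
    length_of_stay: Optional[float] = None  # days
    news: Optional[int] = None
    resp_rate_ge20: Optional[bool] = None
    avpu_below_alert: Optional[bool] = None

    def __post_init__(self):
        if self.included and self.exclusion_reason is not None:
            raise DataError("included rows cannot carry an exclusion reason")
        if not self.included and self.exclusion_reason not in EXCLUSION_ORDER:
            raise DataError("excluded rows need exactly one known reason")
        if self.died_by_day7 and not self.died_in_hospital:
            raise DataError("died_by_day7 implies died_in_hospital")


def exclusion_reason(record: AdmissionRecord) -> Optional[str]:
    """First matching exclusion reason, or None if the admission is included."""
    if record.direct_ed_to_icu:
        return "direct_ed_icu"
    if record.age < 18:
        return "under18"
    if record.specialty != "medical":
        return "non_medical"
    if record.discharge_time.date() <= record.admission_time.date():
        return "no_overnight"
    if len(record.scr_series) < 2:
        return "single_scr"
    return None


def apply_inclusion(
    records: Iterable[AdmissionRecord],
) -> tuple[list[CohortRow], dict[str, int]]:
    """Partition admissions into included and per-reason excluded rows.

    Returns skeleton rows (outcomes unfilled; see :func:`derive_outcomes`)
    and a tally whose counts, with ``included``, sum to the input size — the
    flow-diagram accounting every run reports.
    """
    rows: list[CohortRow] = []
    tally = {reason: 0 for reason in EXCLUSION_ORDER}
    tally["included"] = 0
    for r in records:
        reason = exclusion_reason(r)
        if reason is None:
            tally["included"] += 1
        else:
            tally[reason] += 1
        rows.append(
            CohortRow(
                admission_id=r.admission_id,
                patient_id=r.patient_id,
                site=r.site,
                period=r.period,
                age=r.age,
                comorbidities=dict(r.comorbidities),
                included=reason is None,
                exclusion_reason=reason,
            )
        )
    return rows, tally


def derive_outcomes(
    record: AdmissionRecord,
    aki: AkiClassification,
    aps_score: Optional[int] = None,
    alert: Optional[AlertState] = None,
) -> CohortRow:
    """Analysis row for one included admission.

    Seven-day mortality is anchored at the admission timestamp; length of
    stay runs to discharge or in-hospital death, in days.
    """
    if record.death_in_hospital and record.death_time is None:
        raise DataError(f"{record.admission_id}: death flag set without death_time")
    end = record.death_time if record.death_in_hospital else record.discharge_time
    los = (end - record.admission_time).total_seconds() / 86400.0
    died7 = bool(
        record.death_in_hospital
        and record.death_time <= record.admission_time + timedelta(days=7)
    )
    return CohortRow(
        admission_id=record.admission_id,
        patient_id=record.patient_id,
        site=record.site,
        period=record.period,
        age=record.age,
        comorbidities=dict(record.comorbidities),
        included=True,
        aps_score=aps_score,
        alert_state=alert.state if alert else None,
        aki_category=aki.category,
        aki_onset_hours=aki.onset_hours,
        aki_max_stage=aki.max_stage,
        peak_rise_umol_l=aki.peak_rise_umol_l,
        died_in_hospital=bool(record.death_in_hospital),
        died_by_day7=died7,
        icu_escalation=bool(record.icu_escalation),
        length_of_stay=los,
        news=record.news,
        resp_rate_ge20=bool(record.resp_rate_ge20),
        avpu_below_alert=bool(record.avpu_below_alert),
    )


def rows_to_frame(rows: Sequence[CohortRow]) -> pd.DataFrame:
    """Flatten cohort rows into the analysis DataFrame the stats layer uses."""
    data = []
    for r in rows:
        d = {
            "admission_id": r.admission_id,
            "patient_id": r.patient_id,
            "site": r.site,
            "period": r.period,
            "age": r.age,
            "included": r.included,
            "exclusion_reason": r.exclusion_reason,
            "aps_score": r.aps_score,
            "alert_state": r.alert_state,
            "aki_category": r.aki_category,
            "aki_onset_hours": r.aki_onset_hours,
            "aki_max_stage": r.aki_max_stage,
            "peak_rise_umol_l": r.peak_rise_umol_l,
            "death_in_hospital": r.died_in_hospital,
            "died_by_day7": r.died_by_day7,
            "icu_escalation": r.icu_escalation,
            "length_of_stay": r.length_of_stay,
            "news": r.news,
            "resp_rate_ge20": r.resp_rate_ge20,
            "avpu_below_alert": r.avpu_below_alert,
        }
        d.update({k: bool(v) for k, v in r.comorbidities.items()})
        data.append(d)
    return pd.DataFrame(data)


def single_admission_subset(rows: pd.DataFrame) -> pd.DataFrame:
    """Admissions of patients seen exactly once within their site across
    both periods (sites are analysed separately, so counting is per site)."""
    if rows.empty:
        return rows.copy()
    counts = rows.groupby(["site", "patient_id"])["admission_id"].transform("count")
    return rows.loc[counts == 1].copy()


def build_cohort(
    records: Sequence[AdmissionRecord],
    th: Thresholds = DEFAULT_THRESHOLDS,
    weights=None,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """records -> (analysis frame of included admissions, exclusion tally).

    Runs inclusion filtering, AKI ascertainment, APS scoring and alert
    assignment, then derives outcomes.  ``weights`` defaults to the packaged
    synthetic APS table.
    """
    from .alerts import assign_state, compute_aps, default_weights

    if weights is None:
        weights = default_weights()
    skeleton, tally = apply_inclusion(records)
    by_id = {r.admission_id: r for r in records}
    full_rows = []
    for row in skeleton:
        if not row.included:
            continue
        rec = by_id[row.admission_id]
        aki = classify_admission(rec, th)
        aps = compute_aps(rec, weights)
        alert = assign_state(aps, aki, weights.cutoff)
        full_rows.append(derive_outcomes(rec, aki, aps_score=aps, alert=alert))
    return rows_to_frame(full_rows), tally
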