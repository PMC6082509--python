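"""Core record types: serum-creatinine series, admissions and AKI classifications.

All creatinine values are in µmol/l; in-series times are hours from admission;
pre-admission history times are days before admission.
"""
from __future__ import annotations

from dataclasses import dataclass
from datetime import datetime
from typing import Literal, Optional, Sequence

import numpy as np

from .exceptions import DataError

Site = Literal["intervention", "control"]
Period = Literal["pre", "post"]
AkiCategory = Literal["none", "CA", "HA"]

COMORBIDITY_FLAGS = (
    "ckd",
    "diabetes",
    "heart_failure",
    "liver_disease",
    "hypertension",
    "vascular_disease",
)


@dataclass(frozen=True)
class ScrSeries:
    """Time-stamped serum-creatinine measurements for one admission.

    ``times`` are hours from admission (first measurement at t >= 0, strictly
    increasing); ``values`` are µmol/l and strictly positive.
    """

    times: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)
        if t.shape != v.shape or t.ndim != 1:
            raise DataError("times and values must be 1-d arrays of equal length")
        if t.size and t[0] < 0:
            raise DataError("SCr times must be non-negative hours from admission")
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise DataError("SCr times must be strictly increasing")
        if np.any(v <= 0):
            raise DataError("SCr values must be positive (µmol/l)")

    @classmethod
    def from_pairs(cls, pairs: Sequence[tuple[float, float]]) -> "ScrSeries":
        if not pairs:
            return cls(np.empty(0), np.empty(0))
        t, v = zip(*pairs)
        return cls(np.asarray(t, float), np.asarray(v, float))

    def __len__(self) -> int:
        return int(self.times.size)

    @property
    def admission_value(self) -> float:
        if len(self) == 0:
            raise DataError("empty SCr series has no admission value")
        return float(self.values[0])


@dataclass
class AdmissionRecord:
    """One hospital admission with everything the downstream stages need."""

    patient_id: str
    admission_id: str
    site: Site
    period: Period
    age: float
    comorbidities: dict[str, bool]
    news: int
    resp_rate_ge20: bool
    avpu_below_alert: bool
    admission_time: datetime
    discharge_time: datetime
    death_in_hospital: bool
    death_time: Optional[datetime]
    icu_escalation: bool
    icu_time: Optional[datetime]
    specialty: Literal["medical", "non_medical"]
    direct_ed_to_icu: bool
    baseline_scr_history: list[tuple[float, float]]  # (days before admission, µmol/l)
    scr_series: ScrSeries

    def __post_init__(self):
        if self.age < 0:
            raise DataError(f"{self.admission_id}: negative age")
        if self.discharge_time < self.admission_time:
            raise DataError(f"{self.admission_id}: discharge before admission")
        if self.death_time is not None and not (
            self.admission_time <= self.death_time <= self.discharge_time
        ):
            raise DataError(f"{self.admission_id}: death_time outside the stay")
        missing = [f for f in COMORBIDITY_FLAGS if f not in self.comorbidities]
        if missing:
            raise DataError(f"{self.admission_id}: missing comorbidity flags {missing}")


@dataclass(frozen=True)
class AkiClassification:
    """Outcome of AKI ascertainment for one admission.

    ``category`` is none / CA (present on admission) / HA (develops in
    hospital); ``onset_hours`` is 0 for CA and in (0, horizon] for HA;
    ``max_stage`` is the creatinine-only KDIGO stage; ``peak_rise_umol_l`` is
    max(0, max series value − admission value).
    """

    category: AkiCategory
    onset_hours: Optional[float]
    max_stage: int
    peak_rise_umol_l: float
    baseline_used: Optional[float] = None

    def __post_init__(self):
        if (self.category == "none") != (self.max_stage == 0):
            raise DataError("category none iff stage 0")
        if self.category != "none" and self.onset_hours is None:
            raise DataError("AKI without onset")
        if self.category == "CA" and self.onset_hours != 0:
            raise DataError("CA-AKI onset must be 0")
        if self.category == "HA" and not (self.onset_hours or 0) > 0:
            raise DataError("HA-AKI onset must be > 0")
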