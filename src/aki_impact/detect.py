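"""Creatinine-based AKI ascertainment.

Implements KDIGO-style, creatinine-only detection as used by NHS acute-care
e-alerting: community-acquired AKI (CA-AKI) is judged at admission against a
historical baseline (ratio >= 1.5, or an absolute level >= 354 µmol/l when no
baseline exists); hospital-acquired AKI (HA-AKI) is a rise from the admission
value of >= 1.5-fold, or of >= 26.5 µmol/l within a rolling 48-hour window,
occurring during the first seven days of the stay.  Severity staging uses the
creatinine-ratio bands only (no urine-output or renal-replacement criteria).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .exceptions import DataError
from .records import AdmissionRecord, AkiClassification, ScrSeries


@dataclass(frozen=True)
class Thresholds:
    """Detection and staging thresholds.

    Defaults follow the national creatinine e-alert rules: 1.5-fold rise,
    26.5 µmol/l rolling 48 h rise, 354 µmol/l absolute level, 7-day (168 h)
    detection horizon, and KDIGO stage bands at 2x and 3x the reference.
    """

    ratio_threshold: float = 1.5
    absolute_rise: float = 26.5  # µmol/l within the rolling window
    absolute_level: float = 354.0  # µmol/l, CA-AKI without a baseline
    window: float = 48.0  # hours
    horizon: float = 168.0  # hours (7 days)
    stage2_ratio: float = 2.0
    stage3_ratio: float = 3.0

    def __post_init__(self):
        vals = (
            self.ratio_threshold,
            self.absolute_rise,
            self.absolute_level,
            self.window,
            self.horizon,
            self.stage2_ratio,
            self.stage3_ratio,
        )
        if any(v <= 0 for v in vals):
            raise DataError("all thresholds must be positive")
        if self.window > self.horizon:
            raise DataError("rolling window cannot exceed the detection horizon")


DEFAULT_THRESHOLDS = Thresholds()


def derive_baseline(
    history: Sequence[tuple[float, float]],
    lookback_short: float = 7.0,
    lookback_long: float = 365.0,
) -> Optional[float]:
    """Baseline SCr from pre-admission history, national-algorithm style.

    Uses the lowest value within ``lookback_short`` days before admission if
    any exists; otherwise the median of values between ``lookback_short``
    (exclusive) and ``lookback_long`` days (an even count averages the two
    central values); otherwise ``None``.

    ``history`` is (days-before-admission, µmol/l) pairs.
    """
    if not history:
        return None
    days = np.asarray([d for d, _ in history], dtype=float)
    vals = np.asarray([v for _, v in history], dtype=float)
    if np.any(days < 0):
        raise DataError("history days-before-admission must be >= 0")
    recent = vals[days <= lookback_short]
    if recent.size:
        return float(recent.min())
    older = vals[(days > lookback_short) & (days <= lookback_long)]
    if older.size:
        return float(np.median(older))
    return None


def classify_ca(
    admission_scr: float,
    baseline: Optional[float],
    th: Thresholds = DEFAULT_THRESHOLDS,
) -> bool:
    """Community-acquired AKI at admission.

    True iff admission SCr / baseline >= ratio_threshold, or — with or
    without a baseline — admission SCr >= absolute_level.  With no baseline,
    CA-AKI is assumed absent below the absolute level.
    """
    if admission_scr <= 0:
        raise DataError("admission SCr must be positive")
    if admission_scr >= th.absolute_level:
        return True
    return baseline is not None and admission_scr / baseline >= th.ratio_threshold


def detect_ha(series: ScrSeries, th: Thresholds = DEFAULT_THRESHOLDS) -> Optional[float]:
    """Earliest hospital-acquired AKI onset, or None.

    Onset is the earliest measurement time t <= horizon at which either
    value(t) / admission value >= ratio_threshold, or value(t) minus the
    minimum value over [t − window, t] >= absolute_rise.  Measurements after
    the horizon never trigger detection.  Requires >= 2 measurements (a
    single value cannot show a change and fails study inclusion anyway).
    """
    if len(series) < 2:
        raise DataError("HA-AKI detection needs at least two SCr measurements")
    t, v = series.times, series.values
    adm = v[0]
    for i in range(t.size):
        if t[i] > th.horizon:
            break
        if v[i] / adm >= th.ratio_threshold:
            if t[i] > 0:
                return float(t[i])
            continue  # the admission value itself is CA territory, not HA
        in_window = (t >= t[i] - th.window) & (t <= t[i])
        if v[i] - v[in_window].min() >= th.absolute_rise and t[i] > 0:
            return float(t[i])
    return None


def stage(
    series: ScrSeries,
    reference: float,
    th: Thresholds = DEFAULT_THRESHOLDS,
    detected: bool = True,
) -> int:
    """Creatinine-only KDIGO stage from the peak ratio to ``reference``.

    reference is the baseline for CA-AKI and the admission value for HA-AKI.
    With r = max(series) / reference: stage 3 if r >= stage3_ratio, stage 2
    if stage2_ratio <= r < stage3_ratio, stage 1 if the detection rule fired
    but r is below the stage-2 band, else 0.
    """
    if reference <= 0:
        raise DataError("stage reference must be positive")
    if len(series) == 0:
        raise DataError("cannot stage an empty series")
    r = float(series.values.max()) / reference
    if r >= th.stage3_ratio:
        return 3
    if r >= th.stage2_ratio:
        return 2
    if detected:
        return 1
    return 0


def classify_admission(
    record: AdmissionRecord, th: Thresholds = DEFAULT_THRESHOLDS
) -> AkiClassification:
    """Full ascertainment for one admission.

    CA-AKI takes precedence (judged at admission, onset 0); HA-AKI is only
    sought in non-CA admissions.  Peak rise is relative to the admission
    value and floored at 0.  For CA-AKI detected via the absolute-level rule
    with no baseline, the admission value serves as the staging reference.
    """
    series = record.scr_series
    if len(series) < 2:
        raise DataError(
            f"{record.admission_id}: ascertainment needs a repeated SCr measurement"
        )
    adm = series.admission_value
    baseline = derive_baseline(record.baseline_scr_history)
    peak_rise = max(0.0, float(series.values.max()) - adm)

    if classify_ca(adm, baseline, th):
        ref = baseline if baseline is not None else adm
        return AkiClassification(
            category="CA",
            onset_hours=0.0,
            max_stage=stage(series, ref, th, detected=True),
            peak_rise_umol_l=peak_rise,
            baseline_used=baseline,
        )
    onset = detect_ha(series, th)
    if onset is not None:
        return AkiClassification(
            category="HA",
            onset_hours=onset,
            max_stage=stage(series, adm, th, detected=True),
            peak_rise_umol_l=peak_rise,
            baseline_used=baseline,
        )
    return AkiClassification(
        category="none",
        onset_hours=None,
        max_stage=0,
        peak_rise_umol_l=peak_rise,
        baseline_used=baseline,
    )
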