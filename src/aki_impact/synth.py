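"""Synthetic two-site, two-period acute-admission EHR generator.

Emulates the statistical structure of a controlled before-after e-alerting
study: two hospital sites (intervention / control) observed over a pre and a
post period; patients may have several admissions (clustering); each
admission carries demographics, comorbidity flags, admission physiology, a
time-stamped serum-creatinine series and outcome timestamps.  CA-AKI and
HA-AKI are *planted* — community-acquired cases get an elevated admission
creatinine relative to their historical baseline (or an absolute value above
the no-baseline threshold), hospital-acquired cases get a piecewise-linear
creatinine rise the detection module provably recovers — so configured rates
are recovered by ascertainment, not merely labelled.

Intervention effects are multiplicative odds effects applied only in the
intervention-site post-period cell: ``intervention_or_ha`` on HA-AKI
incidence, ``intervention_or_mort`` on death given HA-AKI.

Randomness: ``generate_cohort`` derives one substream per patient from the
config seed (SeedSequence spawn), so enlarging a cell never perturbs
previously generated patients.  ``simulate_admission_frame`` is a vectorised
fast path (no creatinine series) for replicate simulation studies; it is
deterministic per (config, seed) but does not share streams with the full
generator.
"""
from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field, replace
from datetime import datetime, timedelta
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .detect import DEFAULT_THRESHOLDS, Thresholds, derive_baseline
from .exceptions import ConfigurationError, DataError
from .records import COMORBIDITY_FLAGS, AdmissionRecord, ScrSeries

CELLS = (
    ("intervention", "pre"),
    ("intervention", "post"),
    ("control", "pre"),
    ("control", "post"),
)

PERIOD_START = {"pre": datetime(2014, 10, 1), "post": datetime(2015, 10, 1)}
PERIOD_DAYS = 300  # ~ten-month accrual window per period

# default comorbidity prevalences of an elderly acute general-medical intake
DEFAULT_COMORBIDITY_PREVS = {
    "ckd": 0.47,
    "diabetes": 0.23,
    "heart_failure": 0.24,
    "liver_disease": 0.025,
    "hypertension": 0.585,
    "vascular_disease": 0.09,
}

# log-odds effects of covariates on in-hospital death (centred at the
# population means, so configured marginal rates are preserved)
MORTALITY_BETAS = {
    "age": 0.02,
    "heart_failure": 0.4,
    "ckd": 0.3,
    "vascular_disease": 0.2,
    "hypertension": 0.1,
    "diabetes": 0.15,
    "liver_disease": 0.5,
}

# maximal-stage mix among planted HA-AKI cases (stage 1 / 2 / 3)
STAGE_MIX = ((1, 0.72), (2, 0.20), (3, 0.08))

INVALID_KINDS = ("under18", "non_medical", "no_overnight", "single_scr", "direct_ed_icu")

_EPS = 1e-9  # headroom so planted ratios survive floating-point division


def _logit(p: float) -> float:
    return math.log(p / (1 - p))


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated cohort.

    Rates default to the two-site study this generator emulates: CA-AKI
    prevalence 8.3%, HA-AKI base rates 8.3% / 6.6% per site, HA-conditional
    in-hospital mortality 25%, background mortality 7%, age 74.5 +/- 17 y,
    and within-site intervention odds effects 0.93 (HA-AKI) and 0.73
    (mortality given HA-AKI).
    """

    n_patients_per_cell: int = 6000
    mean_admissions_per_patient: float = 1.15
    ca_aki_prev: float = 0.083
    ha_aki_base_rate: dict[str, float] = field(
        default_factory=lambda: {"intervention": 0.083, "control": 0.066}
    )
    intervention_or_ha: float = 0.93
    intervention_or_mort: float = 0.73
    mort_given_ha: float = 0.25
    mort_background: float = 0.07
    baseline_scr_missing_prob: float = 0.2
    comorbidity_prevs: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COMORBIDITY_PREVS)
    )
    age_mean_sd: tuple[float, float] = (74.5, 17.0)
    invalid_fraction: float = 0.03
    seed: int = 0

    def __post_init__(self):
        probs = {
            "ca_aki_prev": self.ca_aki_prev,
            "mort_given_ha": self.mort_given_ha,
            "mort_background": self.mort_background,
            "baseline_scr_missing_prob": self.baseline_scr_missing_prob,
            "invalid_fraction": self.invalid_fraction,
            **{f"ha_aki_base_rate[{k}]": v for k, v in self.ha_aki_base_rate.items()},
            **{f"comorbidity_prevs[{k}]": v for k, v in self.comorbidity_prevs.items()},
        }
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"{name}={p} is not a probability")
        if self.intervention_or_ha <= 0 or self.intervention_or_mort <= 0:
            raise ConfigurationError("odds-effect parameters must be positive")
        if self.n_patients_per_cell < 0:
            raise ConfigurationError("n_patients_per_cell must be >= 0")
        if self.mean_admissions_per_patient < 1:
            raise ConfigurationError("mean_admissions_per_patient must be >= 1")
        if set(self.ha_aki_base_rate) != {"intervention", "control"}:
            raise ConfigurationError("ha_aki_base_rate needs both sites")
        if set(self.comorbidity_prevs) != set(COMORBIDITY_FLAGS):
            raise ConfigurationError(
                f"comorbidity_prevs must cover exactly {sorted(COMORBIDITY_FLAGS)}"
            )

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), sort_keys=True, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "SimConfig":
        raw = json.loads(text)
        raw["age_mean_sd"] = tuple(raw["age_mean_sd"])
        return cls(**raw)


def _ha_rate(config: SimConfig, site: str, period: str) -> float:
    lp = _logit(config.ha_aki_base_rate[site])
    if site == "intervention" and period == "post":
        lp += math.log(config.intervention_or_ha)
    return 1.0 / (1.0 + math.exp(-lp))


def _death_logit(config: SimConfig, ha: bool, site: str, period: str) -> float:
    base = config.mort_given_ha if ha else config.mort_background
    lp = _logit(base)
    if ha and site == "intervention" and period == "post":
        lp += math.log(config.intervention_or_mort)
    return lp


def _covariate_shift(age: float, flags: dict[str, bool], config: SimConfig) -> float:
    """Centred covariate contribution to the mortality log-odds."""
    shift = MORTALITY_BETAS["age"] * (age - config.age_mean_sd[0])
    for name, beta in MORTALITY_BETAS.items():
        if name == "age":
            continue
        shift += beta * (float(flags[name]) - config.comorbidity_prevs[name])
    return shift


def plant_ha_aki_trajectory(
    record: AdmissionRecord,
    onset_hours: float,
    severity_ratio: float,
    th: Thresholds = DEFAULT_THRESHOLDS,
) -> AdmissionRecord:
    """Rewrite an admission's SCr series so HA-AKI detection fires at
    ``onset_hours`` with the maximal stage implied by ``severity_ratio``.

    Pre-onset measurements are preserved; a measurement exactly at onset
    reaches the 1.5-fold ratio, then the series rises piecewise-linearly to
    ``severity_ratio`` x admission value over 48 h and plateaus.  Original
    post-onset measurements are dropped.
    """
    if onset_hours > th.horizon:
        raise DataError(f"HA onset {onset_hours}h beyond the {th.horizon}h horizon")
    if onset_hours <= 0:
        raise DataError("HA onset must be after admission")
    if severity_ratio < th.ratio_threshold:
        raise DataError(f"severity_ratio must be >= {th.ratio_threshold}")
    series = record.scr_series
    adm = series.admission_value
    keep = series.times < onset_hours
    times = list(series.times[keep])
    values = list(series.values[keep])
    peak = adm * (severity_ratio + _EPS)
    start = adm * (min(th.ratio_threshold, severity_ratio) + _EPS)
    ramp = [
        (onset_hours, start),
        (onset_hours + 24.0, start + (peak - start) / 2.0),
        (onset_hours + 48.0, peak),
        (onset_hours + 72.0, peak),
    ]
    for t, v in ramp:
        times.append(t)
        values.append(v)
    return replace(record, scr_series=ScrSeries(np.asarray(times), np.asarray(values)))


def _history(rng: np.random.Generator, base: float, available: bool):
    if not available:
        return []
    entries = []
    if rng.random() < 0.6:  # a recent result within the 7-day window
        entries.append((float(rng.uniform(1, 7)), base * (1 + rng.uniform(0, 0.10))))
    for _ in range(1 + rng.poisson(1.2)):
        entries.append((float(rng.uniform(8, 365)), base * (1 + rng.uniform(0, 0.20))))
    return entries


def _flat_series(rng: np.random.Generator, adm_value: float, los_days: float) -> ScrSeries:
    """Daily creatinine around the admission value with bounded +/-4% noise,
    guaranteed not to trigger HA detection."""
    n_follow = min(int(los_days), 13)
    times = [0.0]
    values = [adm_value]
    for k in range(1, n_follow + 1):
        times.append(24.0 * k + rng.uniform(-3, 3))
        values.append(adm_value * (1 + rng.uniform(-0.04, 0.04)))
    return ScrSeries(np.asarray(times), np.asarray(values))


def _draw_stage_ratio(rng: np.random.Generator) -> float:
    u = rng.random()
    acc = 0.0
    for stg, p in STAGE_MIX:
        acc += p
        if u < acc:
            break
    bands = {1: (1.52, 1.95), 2: (2.05, 2.90), 3: (3.05, 3.80)}
    lo, hi = bands[stg]
    return float(rng.uniform(lo, hi))


def _generate_patient(
    config: SimConfig, site: str, period: str, index: int, rng: np.random.Generator
) -> list[AdmissionRecord]:
    pid = f"{site[:3]}-{period}-p{index:06d}"
    age_mean, age_sd = config.age_mean_sd
    age = float(np.clip(rng.normal(age_mean, age_sd), 18.5, 105.0))
    flags = {k: bool(rng.random() < p) for k, p in config.comorbidity_prevs.items()}
    scr_base = float(np.clip(rng.lognormal(math.log(75.0), 0.25), 40.0, 220.0))
    has_history = rng.random() >= config.baseline_scr_missing_prob
    history = _history(rng, scr_base, has_history)
    derived = derive_baseline(history)

    n_adm = 1 + rng.poisson(config.mean_admissions_per_patient - 1.0)
    start_days = np.sort(rng.uniform(0, PERIOD_DAYS, n_adm))
    p_ha = _ha_rate(config, site, period)
    records = []
    for k in range(n_adm):
        adm_id = f"{pid}-a{k}"
        invalid = rng.random() < config.invalid_fraction
        kind = INVALID_KINDS[rng.integers(len(INVALID_KINDS))] if invalid else None

        ca = bool(rng.random() < config.ca_aki_prev)
        ha = bool((not ca) and rng.random() < p_ha)

        # admission creatinine: CA cases are planted detectably (ratio to the
        # derived baseline, or the absolute level when no baseline exists)
        if ca:
            if derived is not None:
                adm_scr = derived * (rng.uniform(1.52, 2.9) + _EPS)
            else:
                adm_scr = float(rng.uniform(360.0, 480.0))
        else:
            adm_scr = scr_base * (1 + rng.uniform(-0.03, 0.03))

        onset = float(rng.uniform(24.0, 144.0)) if ha else None
        los = float(max(1.1, rng.lognormal(2.078, 0.8)))
        if ha:
            los = max(los, onset / 24.0 + 3.5)

        lp = _death_logit(config, ha, site, period) + _covariate_shift(age, flags, config)
        died = bool(rng.random() < _sigmoid(lp))

        adm_hour = float(rng.uniform(8.0, 18.0))
        admission_time = PERIOD_START[period] + timedelta(days=float(start_days[k]), hours=adm_hour)
        if kind == "no_overnight":
            los = float(rng.uniform(0.1, 0.35))
            adm_hour = float(rng.uniform(0.0, 10.0))
            admission_time = admission_time.replace(hour=int(adm_hour), minute=0)
            died = False
        death_time = None
        if died:
            earliest = (onset / 24.0 + 0.5) if ha else 0.5
            death_day = float(rng.uniform(earliest, max(earliest + 0.5, los)))
            los = death_day
            death_time = admission_time + timedelta(days=death_day)
        discharge_time = admission_time + timedelta(days=los)
        if death_time is not None:
            discharge_time = death_time

        icu = bool(rng.random() < (0.07 if ha else 0.02))
        icu_time = admission_time + timedelta(days=float(rng.uniform(0.2, 0.8)) * los) if icu else None

        series = _flat_series(rng, adm_scr, los)

        record = AdmissionRecord(
            patient_id=pid,
            admission_id=adm_id,
            site=site,
            period=period,
            age=age,
            comorbidities=dict(flags),
            news=int(min(rng.poisson(1.7), 15)),
            resp_rate_ge20=bool(rng.random() < 0.24),
            avpu_below_alert=bool(rng.random() < 0.012),
            admission_time=admission_time,
            discharge_time=discharge_time,
            death_in_hospital=died,
            death_time=death_time,
            icu_escalation=icu,
            icu_time=icu_time,
            specialty="medical",
            direct_ed_to_icu=False,
            baseline_scr_history=history,
            scr_series=series,
        )
        if ha:
            record = plant_ha_aki_trajectory(record, onset, _draw_stage_ratio(rng))

        # inclusion-violating records keep the pipeline's filters honest
        if kind == "under18":
            record = replace(record, age=float(rng.uniform(16.0, 17.9)))
        elif kind == "non_medical":
            record = replace(record, specialty="non_medical")
        elif kind == "single_scr":
            s = record.scr_series
            record = replace(record, scr_series=ScrSeries(s.times[:1], s.values[:1]))
        elif kind == "direct_ed_icu":
            record = replace(
                record, direct_ed_to_icu=True, icu_escalation=True, icu_time=record.admission_time
            )
        records.append(record)
    return records


def generate_cohort(config: SimConfig) -> list[AdmissionRecord]:
    """Generate all four site x period cells of admissions.

    Deterministic per (config, seed); each patient draws from an independent
    substream keyed by (seed, cell, patient index), so growing a cell leaves
    earlier patients byte-identical.
    """
    records: list[AdmissionRecord] = []
    for cell_idx, (site, period) in enumerate(CELLS):
        cell_ss = np.random.SeedSequence([config.seed, cell_idx])
        children = cell_ss.spawn(config.n_patients_per_cell)
        for j, child in enumerate(children):
            rng = np.random.default_rng(child)
            records.extend(_generate_patient(config, site, period, j, rng))
    return records


def simulate_admission_frame(config: SimConfig) -> pd.DataFrame:
    """Vectorised admission-level outcome frame (no creatinine series).

    Plants CA/HA-AKI and death flags directly from the same probability
    model as :func:`generate_cohort`; intended for replicate studies of the
    difference-in-differences estimators (coverage, type-I error) where only
    the analysis columns are needed.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 97]))
    age_mean, age_sd = config.age_mean_sd
    frames = []
    for site, period in CELLS:
        n_pat = config.n_patients_per_cell
        if n_pat == 0:
            continue
        n_adm = 1 + rng.poisson(config.mean_admissions_per_patient - 1.0, n_pat)
        pid = np.repeat([f"{site[:3]}-{period}-p{j:06d}" for j in range(n_pat)], n_adm)
        age = np.repeat(np.clip(rng.normal(age_mean, age_sd, n_pat), 18.5, 105.0), n_adm)
        flags = {
            k: np.repeat(rng.random(n_pat) < p, n_adm)
            for k, p in config.comorbidity_prevs.items()
        }
        m = int(n_adm.sum())
        ca = rng.random(m) < config.ca_aki_prev
        ha = (~ca) & (rng.random(m) < _ha_rate(config, site, period))
        lp = np.where(
            ha,
            _death_logit(config, True, site, period),
            _death_logit(config, False, site, period),
        )
        lp = lp + MORTALITY_BETAS["age"] * (age - age_mean)
        for name, beta in MORTALITY_BETAS.items():
            if name == "age":
                continue
            lp = lp + beta * (flags[name].astype(float) - config.comorbidity_prevs[name])
        died = rng.random(m) < _sigmoid(lp)
        df = pd.DataFrame(
            {
                "patient_id": pid,
                "site": site,
                "period": period,
                "age": age,
                "ca_aki": ca,
                "ha_aki": ha,
                "death_in_hospital": died,
                **flags,
            }
        )
        frames.append(df)
    if not frames:
        cols = ["patient_id", "site", "period", "age", "ca_aki", "ha_aki", "death_in_hospital",
                *config.comorbidity_prevs]
        return pd.DataFrame(columns=cols)
    out = pd.concat(frames, ignore_index=True)
    out["admission_id"] = [f"a{i:07d}" for i in range(len(out))]
    return out


# ---------------------------------------------------------------------------
# CSV round-trip (one admissions table + one long-format SCr table + config)

ADMISSION_COLUMNS = [
    "admission_id", "patient_id", "site", "period", "age",
    *COMORBIDITY_FLAGS,
    "news", "resp_rate_ge20", "avpu_below_alert",
    "admission_time", "discharge_time", "death_in_hospital", "death_time",
    "icu_escalation", "icu_time", "specialty", "direct_ed_to_icu",
]


def cohort_to_frames(records: list[AdmissionRecord]) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """(admissions, scr_long, baseline_history_long) DataFrames."""
    adm_rows, scr_rows, hist_rows = [], [], []
    for r in records:
        adm_rows.append(
            {
                "admission_id": r.admission_id,
                "patient_id": r.patient_id,
                "site": r.site,
                "period": r.period,
                "age": r.age,
                **{k: r.comorbidities[k] for k in COMORBIDITY_FLAGS},
                "news": r.news,
                "resp_rate_ge20": r.resp_rate_ge20,
                "avpu_below_alert": r.avpu_below_alert,
                "admission_time": r.admission_time.isoformat(),
                "discharge_time": r.discharge_time.isoformat(),
                "death_in_hospital": r.death_in_hospital,
                "death_time": r.death_time.isoformat() if r.death_time else "",
                "icu_escalation": r.icu_escalation,
                "icu_time": r.icu_time.isoformat() if r.icu_time else "",
                "specialty": r.specialty,
                "direct_ed_to_icu": r.direct_ed_to_icu,
            }
        )
        for t, v in zip(r.scr_series.times, r.scr_series.values):
            scr_rows.append({"admission_id": r.admission_id, "hours": float(t), "scr_umol_l": float(v)})
        for d, v in r.baseline_scr_history:
            hist_rows.append(
                {"patient_id": r.patient_id, "admission_id": r.admission_id,
                 "days_before": float(d), "scr_umol_l": float(v)}
            )
    adm = pd.DataFrame(adm_rows, columns=ADMISSION_COLUMNS)
    scr = pd.DataFrame(scr_rows, columns=["admission_id", "hours", "scr_umol_l"])
    hist = pd.DataFrame(hist_rows, columns=["patient_id", "admission_id", "days_before", "scr_umol_l"])
    return adm, scr, hist


def write_cohort(records: list[AdmissionRecord], out_dir: str | Path,
                 config: Optional[SimConfig] = None) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    adm, scr, hist = cohort_to_frames(records)
    adm.to_csv(out / "admissions.csv", index=False)
    scr.to_csv(out / "scr_long.csv", index=False)
    hist.to_csv(out / "baseline_history.csv", index=False)
    if config is not None:
        (out / "sim_config.json").write_text(config.to_json())


def _parse_dt(s) -> Optional[datetime]:
    if s is None or (isinstance(s, float) and math.isnan(s)) or s == "":
        return None
    return datetime.fromisoformat(str(s))


def read_cohort(in_dir: str | Path) -> list[AdmissionRecord]:
    """Rebuild AdmissionRecords from the CSV layout written by write_cohort."""
    src = Path(in_dir)
    adm = pd.read_csv(src / "admissions.csv", float_precision="round_trip")
    scr = pd.read_csv(src / "scr_long.csv", float_precision="round_trip")
    hist_path = src / "baseline_history.csv"
    hist = pd.read_csv(hist_path, float_precision="round_trip") if hist_path.exists() else pd.DataFrame(
        columns=["patient_id", "admission_id", "days_before", "scr_umol_l"]
    )
    scr_groups = {k: g for k, g in scr.groupby("admission_id", sort=False)}
    hist_groups = {k: g for k, g in hist.groupby("admission_id", sort=False)}
    records = []
    for row in adm.itertuples(index=False):
        g = scr_groups.get(row.admission_id)
        if g is None:
            series = ScrSeries(np.empty(0), np.empty(0))
        else:
            series = ScrSeries(g["hours"].to_numpy(float), g["scr_umol_l"].to_numpy(float))
        h = hist_groups.get(row.admission_id)
        history = (
            list(zip(h["days_before"].astype(float), h["scr_umol_l"].astype(float)))
            if h is not None
            else []
        )
        records.append(
            AdmissionRecord(
                patient_id=str(row.patient_id),
                admission_id=str(row.admission_id),
                site=row.site,
                period=row.period,
                age=float(row.age),
                comorbidities={k: bool(getattr(row, k)) for k in COMORBIDITY_FLAGS},
                news=int(row.news),
                resp_rate_ge20=bool(row.resp_rate_ge20),
                avpu_below_alert=bool(row.avpu_below_alert),
                admission_time=_parse_dt(row.admission_time),
                discharge_time=_parse_dt(row.discharge_time),
                death_in_hospital=bool(row.death_in_hospital),
                death_time=_parse_dt(row.death_time),
                icu_escalation=bool(row.icu_escalation),
                icu_time=_parse_dt(row.icu_time),
                specialty=row.specialty,
                direct_ed_to_icu=bool(row.direct_ed_to_icu),
                baseline_scr_history=history,
                scr_series=series,
            )
        )
    return records
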