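"""End-to-end orchestration: simulate (or load) -> ascertain -> alert ->
cohort -> impact statistics, with a reproducible report bundle.

The bundle mirrors the study's reporting surface: a flow-diagram exclusion
tally, a demographics comparison, an HA-AKI incidence table, an HA-AKI
outcomes table, subgroup mortality tables (CA-AKI cases and score-flagged
admissions), and difference-in-differences model summaries.  A manifest
records the config hash, seed and package version; identical config + seed
yields a byte-identical bundle.
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, model_validator

from . import __version__
from .alerts import ApsWeights, default_weights
from .cohort import build_cohort, single_admission_subset
from .detect import DEFAULT_THRESHOLDS, Thresholds
from .exceptions import FitFailureError, ValidationError
from .records import COMORBIDITY_FLAGS
from .stats import (
    DEFAULT_COVARIATES,
    DidSpec,
    build_two_by_two,
    compare_continuous,
    did_binary,
    did_continuous,
    or_estimate,
)
from .synth import ADMISSION_COLUMNS, SimConfig, generate_cohort, read_cohort, write_cohort

SITES = ("intervention", "control")

BINARY_OUTCOMES = {
    "death_in_hospital": "In-patient mortality",
    "died_by_day7": "7-day mortality",
    "stage3": "Stage 3 AKI",
    "icu_escalation": "ICU escalation",
}


class RunConfig(BaseModel):
    """Declarative description of one pipeline run.

    Exactly one of ``simulate`` (a SimConfig) or ``input_dir`` (a cohort CSV
    directory) must be active.
    """

    model_config = ConfigDict(arbitrary_types_allowed=True)

    out_dir: Path
    simulate: Optional[dict] = None
    input_dir: Optional[Path] = None
    seed: Optional[int] = None  # overrides the simulate seed when given
    aps_weights_path: Optional[Path] = None
    covariates: tuple[str, ...] = DEFAULT_COVARIATES
    formats: tuple[Literal["csv", "json"], ...] = ("csv", "json")

    @model_validator(mode="after")
    def _one_source(self):
        if (self.simulate is None) == (self.input_dir is None):
            raise ValueError("exactly one of simulate / input_dir must be set")
        return self

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))

    def sim_config(self) -> Optional[SimConfig]:
        if self.simulate is None:
            return None
        raw = dict(self.simulate)
        if self.seed is not None:
            raw["seed"] = self.seed
        if "age_mean_sd" in raw:
            raw["age_mean_sd"] = tuple(raw["age_mean_sd"])
        return SimConfig(**raw)


@dataclass
class ReportBundle:
    out_dir: Path
    exclusion_tally: dict
    incidence: pd.DataFrame
    ha_outcomes: pd.DataFrame
    subgroups: pd.DataFrame
    demographics: pd.DataFrame
    did_summaries: dict
    manifest: dict


def validate_input(in_dir: str | Path) -> dict:
    """Schema checks for a cohort CSV directory; raises ValidationError
    listing every offending admission/row, else returns a summary."""
    src = Path(in_dir)
    problems: list[str] = []
    adm_path, scr_path = src / "admissions.csv", src / "scr_long.csv"
    for p in (adm_path, scr_path):
        if not p.exists():
            problems.append(f"missing file: {p.name}")
    if problems:
        raise ValidationError(problems)
    adm = pd.read_csv(adm_path)
    scr = pd.read_csv(scr_path)
    missing = [c for c in ADMISSION_COLUMNS if c not in adm.columns]
    if missing:
        problems.append(f"admissions.csv missing columns: {missing}")
    for col in ("admission_id", "hours", "scr_umol_l"):
        if col not in scr.columns:
            problems.append(f"scr_long.csv missing column: {col}")
    if problems:
        raise ValidationError(problems)
    if adm["admission_id"].duplicated().any():
        dup = adm.loc[adm["admission_id"].duplicated(), "admission_id"].tolist()[:5]
        problems.append(f"duplicate admission ids: {dup}")
    if (adm["age"] < 0).any():
        bad = adm.loc[adm["age"] < 0, "admission_id"].tolist()[:5]
        problems.append(f"negative age for admissions {bad}")
    bad_site = set(adm["site"].unique()) - set(SITES)
    if bad_site:
        problems.append(f"unknown site values: {sorted(bad_site)}")
    bad_period = set(adm["period"].unique()) - {"pre", "post"}
    if bad_period:
        problems.append(f"unknown period values: {sorted(bad_period)}")
    known = set(adm["admission_id"])
    orphan = set(scr["admission_id"]) - known
    if orphan:
        problems.append(f"SCr rows reference unknown admissions: {sorted(orphan)[:5]}")
    if (scr["scr_umol_l"] <= 0).any():
        bad = scr.loc[scr["scr_umol_l"] <= 0, "admission_id"].unique().tolist()[:5]
        problems.append(f"non-positive creatinine for admissions {bad}")
    if (scr["hours"] < 0).any():
        bad = scr.loc[scr["hours"] < 0, "admission_id"].unique().tolist()[:5]
        problems.append(f"negative SCr times for admissions {bad}")
    for aid, g in scr.groupby("admission_id", sort=False):
        t = g["hours"].to_numpy()
        if t.size > 1 and not np.all(np.diff(t) > 0):
            problems.append(f"SCr timestamps not strictly increasing for admission {aid}")
    disch = pd.to_datetime(adm["discharge_time"])
    admit = pd.to_datetime(adm["admission_time"])
    if (disch < admit).any():
        bad = adm.loc[disch < admit, "admission_id"].tolist()[:5]
        problems.append(f"discharge before admission for {bad}")
    if problems:
        raise ValidationError(problems)
    return {"n_admissions": len(adm), "n_scr_rows": len(scr)}


def _site_tables(df: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Incidence, HA-outcome and subgroup tables in the published layout."""
    work = df.loc[df["included"]].copy()
    work["ha_aki"] = (work["aki_category"] == "HA").astype(int)
    work["stage3"] = ((work["aki_category"] == "HA") & (work["aki_max_stage"] == 3)).astype(int)
    non_ca = work["aki_category"] != "CA"
    ha = work["aki_category"] == "HA"
    ca = work["aki_category"] == "CA"
    amber = work["alert_state"] == "AMBER"

    inc_rows = []
    for site in SITES:
        t = build_two_by_two(work, "ha_aki", site, stratum=non_ca)
        est = or_estimate(t)
        inc_rows.append(
            {
                "site": site,
                "n_pre": t.c + t.d,
                "n_post": t.a + t.b,
                "events_pre": t.c,
                "events_post": t.a,
                "pct_pre": round(t.pct_group2(), 2),
                "pct_post": round(t.pct_group1(), 2),
                "odds_ratio": round(est.or_point, 3),
                "ci_low": round(est.ci_low, 3),
                "ci_high": round(est.ci_high, 3),
                "p_value": round(est.p_value, 3),
            }
        )

    out_rows = []
    for site in SITES:
        for outcome, label in BINARY_OUTCOMES.items():
            t = build_two_by_two(work, outcome, site, stratum=ha, outcome_label=label)
            if t.is_empty or t.has_zero_cell:
                est = None
            else:
                est = or_estimate(t)
            out_rows.append(
                {
                    "site": site,
                    "outcome": label,
                    "n_pre": t.c + t.d,
                    "n_post": t.a + t.b,
                    "events_pre": t.c,
                    "events_post": t.a,
                    "pct_pre": round(t.pct_group2(), 2) if t.c + t.d else float("nan"),
                    "pct_post": round(t.pct_group1(), 2) if t.a + t.b else float("nan"),
                    "odds_ratio": round(est.or_point, 3) if est else float("nan"),
                    "ci_low": round(est.ci_low, 3) if est else float("nan"),
                    "ci_high": round(est.ci_high, 3) if est else float("nan"),
                    "p_value": round(est.p_value, 3) if est else float("nan"),
                }
            )
        for outcome, label in (("peak_rise_umol_l", "Peak SCr rise"), ("length_of_stay", "Length of stay")):
            pre = work.loc[ha & (work["period"] == "pre") & (work["site"] == site), outcome].dropna()
            post = work.loc[ha & (work["period"] == "post") & (work["site"] == site), outcome].dropna()
            p = compare_continuous(pre, post, "t") if len(pre) > 1 and len(post) > 1 else float("nan")
            out_rows.append(
                {
                    "site": site,
                    "outcome": label,
                    "n_pre": len(pre),
                    "n_post": len(post),
                    "events_pre": float("nan"),
                    "events_post": float("nan"),
                    "pct_pre": round(float(pre.mean()), 1) if len(pre) else float("nan"),
                    "pct_post": round(float(post.mean()), 1) if len(post) else float("nan"),
                    "odds_ratio": float("nan"),
                    "ci_low": float("nan"),
                    "ci_high": float("nan"),
                    "p_value": round(p, 3) if p == p else p,
                }
            )

    sub_rows = []
    for group, mask in (("CA-AKI cases", ca), ("AMBER (APS >= cutoff)", amber)):
        for site in SITES:
            t = build_two_by_two(work, "death_in_hospital", site, stratum=mask,
                                 outcome_label="In-patient mortality")
            est = None if (t.is_empty or t.has_zero_cell) else or_estimate(t)
            sub_rows.append(
                {
                    "group": group,
                    "site": site,
                    "n_pre": t.c + t.d,
                    "n_post": t.a + t.b,
                    "pct_pre": round(t.pct_group2()) if t.c + t.d else float("nan"),
                    "pct_post": round(t.pct_group1()) if t.a + t.b else float("nan"),
                    "odds_ratio": round(est.or_point, 2) if est else float("nan"),
                    "ci_low": round(est.ci_low, 2) if est else float("nan"),
                    "ci_high": round(est.ci_high, 2) if est else float("nan"),
                    "p_value": round(est.p_value, 3) if est else float("nan"),
                }
            )
    return pd.DataFrame(inc_rows), pd.DataFrame(out_rows), pd.DataFrame(sub_rows)


def _demographics(df: pd.DataFrame) -> pd.DataFrame:
    work = df.loc[df["included"]]
    rows = []
    for site in SITES:
        pre = work.loc[(work["site"] == site) & (work["period"] == "pre")]
        post = work.loc[(work["site"] == site) & (work["period"] == "post")]
        if pre.empty or post.empty:
            continue
        rows.append(
            {
                "site": site,
                "variable": "age",
                "pre": f"{pre['age'].mean():.1f} ({pre['age'].std():.1f})",
                "post": f"{post['age'].mean():.1f} ({post['age'].std():.1f})",
                "p_value": round(compare_continuous(pre["age"], post["age"], "t"), 3),
            }
        )
        if pre["news"].notna().all() and post["news"].notna().all():
            rows.append(
                {
                    "site": site,
                    "variable": "news",
                    "pre": f"{pre['news'].median():.0f} ({pre['news'].quantile(0.25):.0f}-{pre['news'].quantile(0.75):.0f})",
                    "post": f"{post['news'].median():.0f} ({post['news'].quantile(0.25):.0f}-{post['news'].quantile(0.75):.0f})",
                    "p_value": round(
                        compare_continuous(pre["news"], post["news"], "mann_whitney"), 3
                    ),
                }
            )
        for flag in ("resp_rate_ge20", "avpu_below_alert", *COMORBIDITY_FLAGS):
            t = build_two_by_two(work, flag, site)
            rows.append(
                {
                    "site": site,
                    "variable": flag,
                    "pre": f"{t.pct_group2():.1f}%",
                    "post": f"{t.pct_group1():.1f}%",
                    "p_value": round(or_estimate(t).p_value, 3) if not t.has_zero_cell else float("nan"),
                }
            )
    return pd.DataFrame(rows)


def _did_summaries(df: pd.DataFrame, covariates: tuple[str, ...]) -> dict:
    work = df.loc[df["included"]].copy()
    work["ha_aki"] = (work["aki_category"] == "HA").astype(int)
    work["death_in_hospital"] = work["death_in_hospital"].astype(int)
    work["died_by_day7"] = work["died_by_day7"].astype(int)
    work["icu_escalation"] = work["icu_escalation"].astype(int)
    non_ca = work.loc[work["aki_category"] != "CA"]
    ha = work.loc[work["aki_category"] == "HA"]
    jobs = [
        ("ha_aki_incidence", non_ca, DidSpec("ha_aki", covariates), did_binary),
        ("mortality_given_ha", ha, DidSpec("death_in_hospital", covariates), did_binary),
        ("day7_mortality_given_ha", ha, DidSpec("died_by_day7", covariates), did_binary),
        ("icu_escalation_given_ha", ha, DidSpec("icu_escalation", covariates), did_binary),
        ("peak_scr_rise_given_ha", ha, DidSpec("peak_rise_umol_l", covariates, link="identity"), did_continuous),
        ("length_of_stay_given_ha", ha, DidSpec("length_of_stay", covariates, link="identity"), did_continuous),
    ]
    out = {"note": "p-values are unadjusted for multiple testing"}
    for name, rows, spec, fitter in jobs:
        if rows.empty:
            out[name] = {"error": "no rows"}
            continue
        try:
            r = fitter(rows, spec)
        except FitFailureError as exc:
            out[name] = {"error": str(exc), **exc.diagnostics}
            continue
        out[name] = {
            "effect": r.interaction_or,
            "scale": r.scale,
            "ci_low": r.ci_low,
            "ci_high": r.ci_high,
            "p_value": r.p_value,
            "n_obs": r.n_obs,
            "n_clusters": r.n_clusters,
            "method": r.method,
            "converged": r.converged,
        }
    return out


def run_pipeline(config: RunConfig) -> ReportBundle:
    """Execute one full run and write the report bundle under out_dir."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sim = config.sim_config()
    if sim is not None:
        records = generate_cohort(sim)
        write_cohort(records, out / "cohort", config=sim)
    else:
        validate_input(config.input_dir)
        records = read_cohort(config.input_dir)
    weights = (
        ApsWeights.from_yaml(config.aps_weights_path)
        if config.aps_weights_path
        else default_weights()
    )
    df, tally = build_cohort(records, DEFAULT_THRESHOLDS, weights)
    tally_doc = {
        "total_admissions": len(records),
        "analysed": tally["included"],
        "excluded": {k: v for k, v in tally.items() if k != "included"},
    }
    incidence, ha_outcomes, subgroups = _site_tables(df)
    demographics = _demographics(df)
    did = _did_summaries(df, config.covariates)

    single = single_admission_subset(df.loc[df["included"]])
    single = single.loc[single["aki_category"] != "CA"].copy()
    single["ha_aki"] = (single["aki_category"] == "HA").astype(int)
    single_rows = []
    for site in SITES:
        t = build_two_by_two(single, "ha_aki", site)
        if not (t.is_empty or t.has_zero_cell):
            est = or_estimate(t)
            single_rows.append(
                {"site": site, "odds_ratio": round(est.or_point, 3),
                 "ci_low": round(est.ci_low, 3), "ci_high": round(est.ci_high, 3),
                 "p_value": round(est.p_value, 3)}
            )

    cfg_payload = config.model_dump(mode="json")
    cfg_payload.pop("out_dir", None)  # location, not content: keeps reruns comparable
    manifest = {
        "package_version": __version__,
        "seed": sim.seed if sim is not None else None,
        "config": cfg_payload,
        "config_hash": hashlib.sha256(
            json.dumps(cfg_payload, sort_keys=True).encode()
        ).hexdigest(),
        "n_input_admissions": len(records),
        "n_analysed": int(tally["included"]),
    }

    if "csv" in config.formats:
        incidence.to_csv(out / "incidence.csv", index=False)
        ha_outcomes.to_csv(out / "ha_outcomes.csv", index=False)
        subgroups.to_csv(out / "subgroups.csv", index=False)
        demographics.to_csv(out / "demographics.csv", index=False)
        df.to_csv(out / "cohort_rows.csv", index=False)
    (out / "exclusion_tally.json").write_text(json.dumps(tally_doc, sort_keys=True, indent=2))
    (out / "did_summaries.json").write_text(json.dumps(did, sort_keys=True, indent=2))
    (out / "single_admission_incidence.json").write_text(
        json.dumps(single_rows, sort_keys=True, indent=2)
    )
    (out / "manifest.json").write_text(json.dumps(manifest, sort_keys=True, indent=2))
    return ReportBundle(
        out_dir=out,
        exclusion_tally=tally_doc,
        incidence=incidence,
        ha_outcomes=ha_outcomes,
        subgroups=subgroups,
        demographics=demographics,
        did_summaries=did,
        manifest=manifest,
    )
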