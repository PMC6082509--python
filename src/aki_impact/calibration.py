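"""Simulation studies calibrating the difference-in-differences estimator.

The planted truth is a multiplicative odds effect on in-hospital death given
HA-AKI, applied only in the intervention-site post-period cell, with all
other study conditions symmetric between sites.  Each replicate generates an
admission frame, keeps the HA-AKI cases, fits the adjusted cluster-robust
DiD logistic model, and records whether the 95% CI covers the truth and
whether the null is rejected at alpha = 0.05.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .exceptions import FitFailureError
from .stats import DEFAULT_COVARIATES, DidSpec, did_binary
from .synth import SimConfig, simulate_admission_frame


@dataclass(frozen=True)
class DidStudyResult:
    """Replicate-study summary for one planted interaction odds ratio."""

    true_or: float
    n_reps: int
    n_admissions_per_cell: int
    coverage: float  # fraction of replicates whose 95% CI covers true_or
    rejection_rate: float  # fraction with p < 0.05
    mean_log_or: float
    mae_log_or: float  # mean |log estimate - log truth| over replicates
    n_failures: int  # replicates whose fit failed (excluded from rates)


def _symmetric_config(
    n_admissions_per_cell: int,
    true_or: float,
    seed: int,
    mean_admissions_per_patient: float = 1.15,
    ha_rate: float = 0.08,
    mort_given_ha: float = 0.25,
) -> SimConfig:
    n_patients = max(1, round(n_admissions_per_cell / mean_admissions_per_patient))
    return SimConfig(
        n_patients_per_cell=n_patients,
        mean_admissions_per_patient=mean_admissions_per_patient,
        ha_aki_base_rate={"intervention": ha_rate, "control": ha_rate},
        intervention_or_ha=1.0,
        intervention_or_mort=true_or,
        mort_given_ha=mort_given_ha,
        invalid_fraction=0.0,
        seed=seed,
    )


def did_mortality_study(
    true_or: float,
    n_admissions_per_cell: int = 5000,
    n_reps: int = 200,
    seed: int = 0,
    adjusted: bool = True,
    alpha: float = 0.05,
) -> DidStudyResult:
    """Coverage and rejection rate of the DiD CI over simulated replicates."""
    rep_seeds = (np.random.SeedSequence(seed).generate_state(n_reps) >> 1).astype(int)
    spec = DidSpec(
        outcome="death_in_hospital",
        covariates=DEFAULT_COVARIATES if adjusted else (),
    )
    log_true = math.log(true_or)
    covered = rejected = failures = 0
    errors = []
    log_ors = []
    for s in rep_seeds:
        cfg = _symmetric_config(n_admissions_per_cell, true_or, int(s))
        frame = simulate_admission_frame(cfg)
        ha = frame.loc[frame["ha_aki"]].copy()
        ha["death_in_hospital"] = ha["death_in_hospital"].astype(int)
        try:
            res = did_binary(ha, spec)
        except FitFailureError:
            failures += 1
            continue
        if res.ci_low <= true_or <= res.ci_high:
            covered += 1
        if res.p_value < alpha:
            rejected += 1
        log_ors.append(math.log(res.interaction_or))
        errors.append(abs(log_ors[-1] - log_true))
    n_ok = n_reps - failures
    return DidStudyResult(
        true_or=true_or,
        n_reps=n_reps,
        n_admissions_per_cell=n_admissions_per_cell,
        coverage=covered / n_ok if n_ok else float("nan"),
        rejection_rate=rejected / n_ok if n_ok else float("nan"),
        mean_log_or=float(np.mean(log_ors)) if log_ors else float("nan"),
        mae_log_or=float(np.mean(errors)) if errors else float("nan"),
        n_failures=failures,
    )


def did_consistency_study(
    true_or: float = 0.7,
    n_small: int = 600,
    n_large: int = 5000,
    n_reps: int = 30,
    seed: int = 0,
) -> dict[str, DidStudyResult]:
    """The same planted-effect study at two problem sizes.

    A consistent estimator's mean absolute error on the log scale must
    shrink as cells grow; callers compare ``small.mae_log_or`` against
    ``large.mae_log_or``.
    """
    return {
        "small": did_mortality_study(true_or, n_admissions_per_cell=n_small, n_reps=n_reps, seed=seed),
        "large": did_mortality_study(true_or, n_admissions_per_cell=n_large, n_reps=n_reps, seed=seed + 1),
    }
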