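"""Impact statistics: 2x2 odds ratios, Woolf CIs, exact and chi-square tests,
CMH stratified tests, continuous comparisons, and the adjusted
difference-in-differences (DiD) models with patient-level clustering.

The DiD estimator targets the site x period interaction: on the odds scale it
is the change at the intervention site divided by the contemporaneous change
at the control site.  Binary outcomes use a logistic model with
cluster-robust (GEE) variance for repeated admissions per patient; continuous
outcomes use a linear mixed model with a patient random intercept.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Literal, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from statsmodels.stats.contingency_tables import StratifiedTable

from .exceptions import DataError, FitFailureError

DEFAULT_COVARIATES = (
    "age",
    "heart_failure",
    "ckd",
    "vascular_disease",
    "hypertension",
    "diabetes",
    "liver_disease",
)


@dataclass(frozen=True)
class TwoByTwoTable:
    """Exposure x outcome counts: (a, b) events/non-events in group 1
    (conventionally the post period) and (c, d) in group 2 (pre)."""

    a: int
    b: int
    c: int
    d: int
    group1: str = "post"
    group2: str = "pre"
    outcome: str = "event"

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise DataError("2x2 cell counts must be non-negative")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def is_empty(self) -> bool:
        return self.total == 0

    @property
    def has_zero_cell(self) -> bool:
        return min(self.a, self.b, self.c, self.d) == 0

    def pct_group1(self) -> float:
        return 100.0 * self.a / (self.a + self.b)

    def pct_group2(self) -> float:
        return 100.0 * self.c / (self.c + self.d)

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)


@dataclass(frozen=True)
class EffectEstimate:
    or_point: float
    ci_low: float
    ci_high: float
    p_value: float
    method: Literal["woolf_chi2", "woolf_fisher", "cluster_logistic"]
    haldane_corrected: bool = False

    def __post_init__(self):
        if not (self.ci_low <= self.or_point <= self.ci_high):
            raise DataError("CI must contain the point estimate")


@dataclass(frozen=True)
class DidSpec:
    """Design of one difference-in-differences model."""

    outcome: str
    covariates: tuple[str, ...] = DEFAULT_COVARIATES
    cluster_key: str = "patient_id"
    link: Literal["logistic", "identity"] = "logistic"


@dataclass(frozen=True)
class DidResult:
    """Interaction estimate from one DiD fit.

    ``interaction_or`` is exp(coefficient) for logistic models; for identity
    link it carries the raw interaction effect (see ``scale``).
    """

    interaction_or: float
    ci_low: float
    ci_high: float
    p_value: float
    n_obs: int
    n_clusters: int
    method: str
    scale: Literal["odds_ratio", "difference"] = "odds_ratio"
    converged: bool = True


def build_two_by_two(
    rows: pd.DataFrame,
    outcome: str,
    site: str,
    stratum: Optional[pd.Series] = None,
    outcome_label: Optional[str] = None,
) -> TwoByTwoTable:
    """Tally post-vs-pre counts of a binary outcome within one site.

    ``stratum`` is an optional boolean mask aligned with ``rows`` (e.g.
    HA-AKI cases only).  Empty strata yield an all-zero table with
    ``is_empty`` set rather than an error.
    """
    mask = rows["site"] == site
    if stratum is not None:
        mask &= stratum.astype(bool)
    sub = rows.loc[mask]
    y = sub[outcome].astype(bool)
    post = sub["period"] == "post"
    return TwoByTwoTable(
        a=int((y & post).sum()),
        b=int((~y & post).sum()),
        c=int((y & ~post).sum()),
        d=int((~y & ~post).sum()),
        outcome=outcome_label or outcome,
    )


def _cells(t: TwoByTwoTable) -> tuple[np.ndarray, bool]:
    """Cell counts with Haldane-Anscombe +0.5 applied when any cell is zero."""
    if t.is_empty:
        raise DataError("all-zero 2x2 table: odds ratio undefined")
    cells = np.array([t.a, t.b, t.c, t.d], dtype=float)
    if t.has_zero_cell:
        return cells + 0.5, True
    return cells, False


def odds_ratio(t: TwoByTwoTable) -> float:
    """(a/b) / (c/d); zero cells get the Haldane-Anscombe +0.5 correction."""
    a, b, c, d = _cells(t)[0]
    return (a / b) / (c / d)


def woolf_ci(t: TwoByTwoTable, level: float = 0.95) -> tuple[float, float]:
    """Asymptotic log-OR interval: exp(ln OR ± z · sqrt(1/a+1/b+1/c+1/d))."""
    (a, b, c, d), _ = _cells(t)
    z = sps.norm.ppf(0.5 + level / 2)
    log_or = np.log((a / b) / (c / d))
    half = z * np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return float(np.exp(log_or - half)), float(np.exp(log_or + half))


def chi2_p(t: TwoByTwoTable, correction: bool = False) -> float:
    """Pearson chi-square p-value; continuity correction off by default."""
    arr = t.as_array()
    if np.any(arr.sum(axis=0) == 0) or np.any(arr.sum(axis=1) == 0):
        raise DataError("degenerate margins: chi-square undefined")
    if np.allclose(arr[0] / arr[0].sum(), arr[1] / arr[1].sum()):
        return 1.0  # zero statistic; avoids spurious tiny negatives
    return float(sps.chi2_contingency(arr, correction=correction)[1])


def fisher_p(t: TwoByTwoTable) -> float:
    """Two-sided Fisher exact p-value."""
    return float(sps.fisher_exact(t.as_array().astype(int))[1])


def or_estimate(
    t: TwoByTwoTable,
    level: float = 0.95,
    p_method: Literal["chi2", "fisher"] = "fisher",
) -> EffectEstimate:
    """Point OR, Woolf CI and p-value bundled for table reporting."""
    lo, hi = woolf_ci(t, level)
    p = fisher_p(t) if p_method == "fisher" else chi2_p(t)
    return EffectEstimate(
        or_point=odds_ratio(t),
        ci_low=lo,
        ci_high=hi,
        p_value=p,
        method="woolf_fisher" if p_method == "fisher" else "woolf_chi2",
        haldane_corrected=t.has_zero_cell,
    )


def cmh_test(strata: Sequence[TwoByTwoTable]) -> tuple[float, float]:
    """Cochran-Mantel-Haenszel chi-square across 2x2 strata -> (stat, p)."""
    usable = [t for t in strata if not t.is_empty]
    if not usable:
        raise DataError("CMH test needs at least one non-empty stratum")
    tables = [t.as_array() for t in usable]
    res = StratifiedTable(tables).test_null_odds(correction=False)
    return float(res.statistic), float(res.pvalue)


def compare_continuous(
    x: Iterable[float],
    y: Iterable[float],
    method: Literal["t", "mann_whitney"] = "t",
) -> float:
    """Two-sided p-value comparing two samples.

    Mann-Whitney uses scipy's tie-corrected two-sided test; exactly identical
    samples give p = 1 by construction.
    """
    x = np.asarray(list(x), float)
    y = np.asarray(list(y), float)
    if x.size == 0 or y.size == 0:
        raise DataError("both samples must be non-empty")
    if method == "t":
        if x.size < 2 or y.size < 2:
            raise DataError("t-test needs n >= 2 per sample")
        return float(sps.ttest_ind(x, y, equal_var=False).pvalue)
    if x.size == y.size and np.array_equal(np.sort(x), np.sort(y)):
        return 1.0
    return float(sps.mannwhitneyu(x, y, alternative="two-sided").pvalue)


def _did_design(rows: pd.DataFrame, spec: DidSpec) -> tuple[pd.DataFrame, str]:
    df = rows.copy()
    df["treated"] = (df["site"] == "intervention").astype(int)
    df["post"] = (df["period"] == "post").astype(int)
    missing = [c for c in spec.covariates if c not in df.columns]
    if missing:
        raise DataError(f"missing covariate columns: {missing}")
    for c in spec.covariates:
        if df[c].dtype == bool:
            df[c] = df[c].astype(int)
    terms = ["treated", "post", "treated:post", *spec.covariates]
    formula = f"{spec.outcome} ~ " + " + ".join(terms)
    return df, formula


def did_binary(rows: pd.DataFrame, spec: DidSpec) -> DidResult:
    """Difference-in-differences logistic model with patient clustering.

    Fits outcome ~ site + period + site x period + covariates.  With repeated
    admissions per patient the model is estimated by GEE (exchangeable
    working correlation, robust sandwich variance); when every cluster has a
    single admission this reduces to the independence GEE, computed as a
    binomial GLM with HC0 robust covariance.  Returns the interaction odds
    ratio, the paper-style DiD effect.
    """
    df, formula = _did_design(rows, spec)
    y = df[spec.outcome].astype(int)
    if set(y.unique()) - {0, 1}:
        raise DataError(f"{spec.outcome} is not binary")
    df[spec.outcome] = y
    groups = df[spec.cluster_key]
    n_clusters = groups.nunique()
    if n_clusters < 2:
        raise DataError("DiD needs at least two clusters")
    singleton = groups.value_counts().max() == 1
    method = "glm_hc0" if singleton else "gee_exchangeable"
    try:
        with warnings.catch_warnings(), np.errstate(all="ignore"):
            warnings.simplefilter("ignore")
            if singleton:
                model = sm.GLM.from_formula(formula, data=df, family=sm.families.Binomial())
                res = model.fit(cov_type="HC0", maxiter=200)
                converged = bool(res.converged)
            else:
                # warm start from the independence MLE, then GEE iterations
                start = sm.GLM.from_formula(
                    formula, data=df, family=sm.families.Binomial()
                ).fit(maxiter=200)
                res = sm.GEE.from_formula(
                    formula,
                    groups=groups,
                    data=df,
                    family=sm.families.Binomial(),
                    cov_struct=sm.cov_struct.Exchangeable(),
                ).fit(start_params=start.params, maxiter=20)
                converged = bool(getattr(res, "converged", True))
                if not np.all(np.isfinite(res.params)) or not np.all(np.isfinite(res.bse)):
                    # exchangeable correlation inestimable (almost no repeated
                    # admissions): fall back to the independence working model,
                    # keeping the cluster-robust sandwich variance
                    res = sm.GEE.from_formula(
                        formula,
                        groups=groups,
                        data=df,
                        family=sm.families.Binomial(),
                        cov_struct=sm.cov_struct.Independence(),
                    ).fit(start_params=start.params, maxiter=20)
                    converged = bool(getattr(res, "converged", True))
                    method = "gee_independence"
    except Exception as exc:  # separation, singular design, ...
        raise FitFailureError(
            f"DiD logistic fit failed for {spec.outcome}: {exc}",
            diagnostics={"n_obs": len(df), "n_clusters": int(n_clusters)},
        ) from exc
    term = "treated:post"
    coef = float(res.params[term])
    se = float(res.bse[term])
    if not np.isfinite(coef) or not np.isfinite(se) or se == 0:
        raise FitFailureError(
            f"DiD logistic fit degenerate for {spec.outcome} (coef={coef}, se={se})",
            diagnostics={"n_obs": len(df), "n_clusters": int(n_clusters)},
        )
    z = sps.norm.ppf(0.975)
    return DidResult(
        interaction_or=float(np.exp(coef)),
        ci_low=float(np.exp(coef - z * se)),
        ci_high=float(np.exp(coef + z * se)),
        p_value=float(res.pvalues[term]),
        n_obs=len(df),
        n_clusters=int(n_clusters),
        method=method,
        converged=converged,
    )


def did_continuous(rows: pd.DataFrame, spec: DidSpec) -> DidResult:
    """DiD linear mixed model with a patient random intercept.

    A singular or non-converging random-effect fit falls back to ordinary
    least squares (independence), recorded in ``method``.
    """
    df, formula = _did_design(rows, spec)
    groups = df[spec.cluster_key]
    n_clusters = groups.nunique()
    term = "treated:post"
    z = sps.norm.ppf(0.975)
    method = "mixed_lm"
    res = None
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            mod = sm.MixedLM.from_formula(formula, groups=groups, data=df)
            fit = mod.fit(reml=True)
        if fit.converged and np.isfinite(fit.bse.get(term, np.nan)):
            res = fit
    except Exception:
        res = None
    if res is None:
        method = "ols_fallback"
        res = sm.OLS.from_formula(formula, data=df).fit()
    coef = float(res.params[term])
    se = float(res.bse[term])
    return DidResult(
        interaction_or=coef,
        ci_low=coef - z * se,
        ci_high=coef + z * se,
        p_value=float(res.pvalues[term]),
        n_obs=len(df),
        n_clusters=int(n_clusters),
        method=method,
        scale="difference",
        converged=True,
    )
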