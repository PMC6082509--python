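"""Odds ratios, Woolf intervals, exact/chi-square/CMH tests, DiD models."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import statsmodels.api as sm

from aki_impact.exceptions import DataError
from aki_impact.stats import (
    DidSpec,
    TwoByTwoTable,
    build_two_by_two,
    chi2_p,
    cmh_test,
    compare_continuous,
    did_binary,
    did_continuous,
    fisher_p,
    odds_ratio,
    or_estimate,
    woolf_ci,
)

from .oracles import mantel_haenszel_chi2

MORT = TwoByTwoTable(132, 477, 156, 412)  # post vs pre mortality among HA cases
DAY7 = TwoByTwoTable(64, 545, 92, 476)


class TestOddsRatio:
    @pytest.mark.parametrize(
        "table, expected",
        [(MORT, 0.731), (TwoByTwoTable(1, 1, 1, 1), 1.0), (DAY7, 0.608)],
    )
    def test_point_estimates(self, table, expected):
        assert odds_ratio(table) == pytest.approx(expected, abs=5e-4)

    def test_row_scaling_invariance(self):
        t1 = TwoByTwoTable(10, 20, 5, 40)
        t2 = TwoByTwoTable(30, 60, 5, 40)  # first row tripled
        assert odds_ratio(t1) == pytest.approx(odds_ratio(t2))

    def test_zero_cell_haldane_corrected(self):
        t = TwoByTwoTable(0, 10, 5, 5)
        assert odds_ratio(t) == pytest.approx((0.5 / 10.5) / (5.5 / 5.5))
        assert or_estimate(t).haldane_corrected

    def test_all_zero_rejected(self):
        with pytest.raises(DataError):
            odds_ratio(TwoByTwoTable(0, 0, 0, 0))


class TestWoolfCi:
    def test_reproduces_published_interval(self):
        lo, hi = woolf_ci(MORT)
        assert (round(lo, 3), round(hi, 3)) == (0.560, 0.954)

    def test_icu_interval(self):
        lo, hi = woolf_ci(TwoByTwoTable(42, 567, 42, 526))
        assert (round(lo, 3), round(hi, 3)) == (0.595, 1.446)

    def test_symmetric_on_log_scale_around_unity(self):
        lo, hi = woolf_ci(TwoByTwoTable(1, 1, 1, 1))
        assert lo < 1 < hi
        assert np.log(hi) == pytest.approx(-np.log(lo))

    def test_contains_point_and_shrinks_with_counts(self):
        t = TwoByTwoTable(12, 34, 9, 41)
        big = TwoByTwoTable(48, 136, 36, 164)
        lo, hi = woolf_ci(t)
        assert lo <= odds_ratio(t) <= hi
        blo, bhi = woolf_ci(big)
        assert (bhi - blo) < (hi - lo)


class TestPValues:
    def test_zero_statistic_gives_one(self):
        assert chi2_p(TwoByTwoTable(1, 1, 1, 1)) == 1.0
        assert chi2_p(TwoByTwoTable(10, 30, 20, 60)) == 1.0  # identical proportions

    def test_mortality_table_p(self):
        assert chi2_p(MORT) == pytest.approx(0.021, abs=5e-4)
        assert fisher_p(MORT) == pytest.approx(0.021, abs=5e-4)

    def test_degenerate_margin_rejected(self):
        with pytest.raises(DataError):
            chi2_p(TwoByTwoTable(0, 0, 5, 5))


class TestCmh:
    def test_single_stratum_equals_mantel_haenszel(self):
        stat, p = cmh_test([MORT])
        expected = mantel_haenszel_chi2([MORT])
        assert stat == pytest.approx(expected, rel=1e-9)
        assert p == pytest.approx(sps.chi2.sf(expected, 1), rel=1e-9)

    def test_duplicated_stratum_doubles_statistic(self):
        one, _ = cmh_test([MORT])
        two, p2 = cmh_test([MORT, MORT])
        assert two == pytest.approx(2 * one, rel=1e-9)
        assert p2 < sps.chi2.sf(one, 1)

    def test_null_strata_give_p_near_one(self):
        strata = [TwoByTwoTable(10, 10, 10, 10), TwoByTwoTable(7, 7, 7, 7)]
        _, p = cmh_test(strata)
        assert p > 0.99

    def test_no_usable_strata_rejected(self):
        with pytest.raises(DataError):
            cmh_test([TwoByTwoTable(0, 0, 0, 0)])


class TestCompareContinuous:
    def test_identical_samples_give_one(self):
        x = [1.0, 2.0, 3.0, 4.0]
        assert compare_continuous(x, list(x), "mann_whitney") == 1.0

    def test_distant_samples_give_tiny_p(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, 200)
        y = rng.normal(8, 1, 200)
        assert compare_continuous(x, y, "t") < 1e-10
        assert compare_continuous(x, y, "mann_whitney") < 1e-10

    def test_t_needs_two_per_sample(self):
        with pytest.raises(DataError):
            compare_continuous([1.0], [1.0, 2.0], "t")

    def test_type_i_error_near_nominal(self):
        rng = np.random.default_rng(42)
        rejections = 0
        reps = 1000
        for _ in range(reps):
            x = rng.normal(0, 1, 30)
            y = rng.normal(0, 1, 30)
            rejections += compare_continuous(x, y, "t") < 0.05
        assert 0.03 <= rejections / reps <= 0.07


def expand_cells(cells):
    """cells: {(site, period): (events, n)} -> one row per admission."""
    frames = []
    for (site, period), (k, n) in cells.items():
        frames.append(
            pd.DataFrame(
                {"site": site, "period": period, "y": np.r_[np.ones(k, int), np.zeros(n - k, int)]}
            )
        )
    df = pd.concat(frames, ignore_index=True)
    df["patient_id"] = [f"p{i}" for i in range(len(df))]
    return df


class TestDidBinary:
    CELLS = {
        ("intervention", "pre"): (30, 200),
        ("intervention", "post"): (24, 210),
        ("control", "pre"): (25, 190),
        ("control", "post"): (28, 205),
    }

    def test_saturated_interaction_equals_ratio_of_odds_ratios(self):
        df = expand_cells(self.CELLS)
        res = did_binary(df, DidSpec("y", covariates=()))
        def orr(site):
            k1, n1 = self.CELLS[(site, "post")]
            k0, n0 = self.CELLS[(site, "pre")]
            return (k1 / (n1 - k1)) / (k0 / (n0 - k0))
        assert res.interaction_or == pytest.approx(orr("intervention") / orr("control"), rel=1e-7)
        assert res.method == "glm_hc0"
        assert res.n_clusters == res.n_obs

    def test_clustered_data_uses_gee(self):
        df = expand_cells(self.CELLS)
        df["patient_id"] = ["p%d" % (i // 2) for i in range(len(df))]
        res = did_binary(df, DidSpec("y", covariates=()))
        assert res.method.startswith("gee")
        assert res.n_clusters < res.n_obs
        assert res.ci_low <= res.interaction_or <= res.ci_high

    def test_non_binary_outcome_rejected(self):
        df = expand_cells(self.CELLS)
        df["y"] = df["y"] * 3
        with pytest.raises(DataError):
            did_binary(df, DidSpec("y", covariates=()))

    def test_missing_covariate_rejected(self):
        df = expand_cells(self.CELLS)
        with pytest.raises(DataError):
            did_binary(df, DidSpec("y", covariates=("age",)))

    def test_needs_at_least_two_clusters(self):
        df = expand_cells(self.CELLS)
        df["patient_id"] = "p0"
        with pytest.raises(DataError):
            did_binary(df, DidSpec("y", covariates=()))


class TestDidContinuous:
    def simulated(self, seed=3, n_per_cell=150, interaction=-5.0, sigma_patient=0.0):
        rng = np.random.default_rng(seed)
        rows = []
        pid = 0
        for site in ("intervention", "control"):
            for period in ("pre", "post"):
                for _ in range(n_per_cell):
                    effect = interaction if (site == "intervention" and period == "post") else 0.0
                    u = rng.normal(0, sigma_patient)
                    rows.append(
                        {
                            "site": site,
                            "period": period,
                            "patient_id": f"p{pid}",
                            "y": 70 + effect + u + rng.normal(0, 10),
                        }
                    )
                    pid += 1
        return pd.DataFrame(rows)

    def test_singleton_clusters_match_ols(self):
        df = self.simulated()
        res = did_continuous(df, DidSpec("y", covariates=(), link="identity"))
        df2 = df.copy()
        df2["treated"] = (df2["site"] == "intervention").astype(int)
        df2["post"] = (df2["period"] == "post").astype(int)
        ols = sm.OLS.from_formula("y ~ treated + post + treated:post", data=df2).fit()
        assert res.interaction_or == pytest.approx(ols.params["treated:post"], abs=1e-6)

    def test_recovers_planted_interaction(self):
        df = self.simulated(seed=9, n_per_cell=400, interaction=-5.0)
        res = did_continuous(df, DidSpec("y", covariates=(), link="identity"))
        assert res.ci_low <= -5.0 <= res.ci_high

    def test_null_centred_under_permutation(self):
        rng = np.random.default_rng(11)
        estimates = []
        df = self.simulated(seed=12, n_per_cell=120, interaction=0.0)
        for _ in range(40):
            shuffled = df.copy()
            shuffled["site"] = rng.permutation(shuffled["site"].to_numpy())
            res = did_continuous(shuffled, DidSpec("y", covariates=(), link="identity"))
            estimates.append(res.interaction_or)
        mean = np.mean(estimates)
        se = np.std(estimates, ddof=1) / np.sqrt(len(estimates))
        assert abs(mean) < 3 * se + 0.2


class TestBuildTwoByTwo:
    def frame(self):
        return pd.DataFrame(
            {
                "site": ["intervention"] * 4 + ["control"] * 2,
                "period": ["pre", "pre", "post", "post", "pre", "post"],
                "dead": [True, False, True, False, False, True],
                "ha": [True, True, True, False, False, False],
            }
        )

    def test_counts_and_stratum(self):
        df = self.frame()
        t = build_two_by_two(df, "dead", "intervention")
        assert (t.a, t.b, t.c, t.d) == (1, 1, 1, 1)
        t2 = build_two_by_two(df, "dead", "intervention", stratum=df["ha"])
        assert (t2.a, t2.b, t2.c, t2.d) == (1, 0, 1, 1)

    def test_empty_stratum_flagged(self):
        df = self.frame()
        t = build_two_by_two(df, "dead", "control", stratum=df["ha"])
        assert t.is_empty
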