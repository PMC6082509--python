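"""Synthetic cohort generator: determinism, planted-rate recovery, planting."""
import numpy as np
import pytest

from aki_impact.cohort import build_cohort
from aki_impact.detect import classify_admission
from aki_impact.exceptions import ConfigurationError, DataError
from aki_impact.synth import (
    SimConfig,
    cohort_to_frames,
    generate_cohort,
    plant_ha_aki_trajectory,
    read_cohort,
    simulate_admission_frame,
    write_cohort,
)

from .conftest import make_record


def small_config(**kw):
    base = dict(n_patients_per_cell=120, seed=11)
    base.update(kw)
    return SimConfig(**base)


class TestConfig:
    @pytest.mark.parametrize(
        "kw",
        [
            {"ca_aki_prev": 1.2},
            {"mort_background": -0.1},
            {"intervention_or_ha": 0.0},
            {"mean_admissions_per_patient": 0.8},
            {"ha_aki_base_rate": {"intervention": 0.08}},
        ],
    )
    def test_invalid_rejected(self, kw):
        with pytest.raises(ConfigurationError):
            small_config(**kw)

    def test_json_round_trip(self):
        cfg = small_config()
        assert SimConfig.from_json(cfg.to_json()) == cfg


class TestGenerateCohort:
    def test_zero_patients_gives_empty_cohort(self):
        assert generate_cohort(small_config(n_patients_per_cell=0)) == []

    def test_same_config_and_seed_is_identical(self):
        cfg = small_config()
        a, _, _ = cohort_to_frames(generate_cohort(cfg))
        b, _, _ = cohort_to_frames(generate_cohort(cfg))
        assert a.equals(b)

    def test_different_seed_differs(self):
        a, _, _ = cohort_to_frames(generate_cohort(small_config(seed=1)))
        b, _, _ = cohort_to_frames(generate_cohort(small_config(seed=2)))
        assert not a.equals(b)

    def test_growing_a_cell_preserves_earlier_patients(self):
        small = generate_cohort(small_config(n_patients_per_cell=15))
        big = generate_cohort(small_config(n_patients_per_cell=40))
        small_ids = {r.patient_id for r in small}
        big_by_adm = {r.admission_id: r for r in big}
        for r in small:
            assert r.admission_id in big_by_adm
            other = big_by_adm[r.admission_id]
            assert np.array_equal(r.scr_series.values, other.scr_series.values)
            assert r.death_in_hospital == other.death_in_hospital
        assert {r.patient_id for r in big} > small_ids

    def test_clustering_present_when_mean_admissions_above_one(self):
        recs = generate_cohort(small_config(mean_admissions_per_patient=1.4))
        pids = [r.patient_id for r in recs]
        assert len(pids) > len(set(pids))

    def test_all_cells_and_invalid_records_present(self):
        recs = generate_cohort(small_config(invalid_fraction=0.1))
        cells = {(r.site, r.period) for r in recs}
        assert cells == {
            ("intervention", "pre"),
            ("intervention", "post"),
            ("control", "pre"),
            ("control", "post"),
        }
        assert any(r.age < 18 for r in recs)
        assert any(r.specialty == "non_medical" for r in recs)
        assert any(len(r.scr_series) < 2 for r in recs)
        assert any(r.direct_ed_to_icu for r in recs)


class TestRateRecovery:
    """Ascertainment must recover the configured rates (3 binomial SE)."""

    @pytest.fixture(scope="class")
    def cohort_frame(self):
        # ~5,000 admissions per cell, no intervention effect on incidence
        cfg = SimConfig(
            n_patients_per_cell=4348,
            ha_aki_base_rate={"intervention": 0.08, "control": 0.08},
            intervention_or_ha=1.0,
            invalid_fraction=0.0,
            seed=5,
        )
        df, _ = build_cohort(generate_cohort(cfg))
        return df.loc[df["included"]]

    def test_ha_rate_recovered_per_cell(self, cohort_frame):
        non_ca = cohort_frame.loc[cohort_frame["aki_category"] != "CA"]
        for (site, period), cell in non_ca.groupby(["site", "period"]):
            p_hat = (cell["aki_category"] == "HA").mean()
            se = np.sqrt(0.08 * 0.92 / len(cell))
            assert abs(p_hat - 0.08) < 3 * se, (site, period, p_hat)

    def test_ca_prevalence_recovered(self, cohort_frame):
        p_hat = (cohort_frame["aki_category"] == "CA").mean()
        se = np.sqrt(0.083 * 0.917 / len(cohort_frame))
        assert abs(p_hat - 0.083) < 3 * se

    def test_ha_conditional_mortality_recovered(self, cohort_frame):
        ha = cohort_frame.loc[cohort_frame["aki_category"] == "HA"]
        pre = ha.loc[ha["period"] == "pre"]
        p_hat = pre["death_in_hospital"].mean()
        se = np.sqrt(0.25 * 0.75 / len(pre))
        assert abs(p_hat - 0.25) < 3 * se


class TestPlanting:
    def base(self, los=8.0):
        return make_record([(0, 80), (22, 82), (46, 78), (70, 81), (94, 80)], los_days=los)

    def test_boundary_severity_gives_stage_one_at_requested_onset(self):
        rec = plant_ha_aki_trajectory(self.base(), onset_hours=48, severity_ratio=1.5)
        c = classify_admission(rec)
        assert c.category == "HA"
        assert c.onset_hours == 48
        assert c.max_stage == 1

    def test_threefold_severity_gives_stage_three(self):
        rec = plant_ha_aki_trajectory(self.base(), onset_hours=48, severity_ratio=3.0)
        assert classify_admission(rec).max_stage == 3

    def test_twofold_severity_gives_stage_two(self):
        rec = plant_ha_aki_trajectory(self.base(), onset_hours=30, severity_ratio=2.0)
        assert classify_admission(rec).max_stage == 2

    def test_unplanted_flat_series_never_triggers(self):
        assert classify_admission(self.base()).category == "none"

    def test_onset_beyond_horizon_rejected(self):
        with pytest.raises(DataError):
            plant_ha_aki_trajectory(self.base(), onset_hours=169, severity_ratio=2.0)

    def test_subthreshold_severity_rejected(self):
        with pytest.raises(DataError):
            plant_ha_aki_trajectory(self.base(), onset_hours=48, severity_ratio=1.4)


class TestAdmissionFrame:
    def test_deterministic_and_structured(self):
        cfg = small_config(n_patients_per_cell=400)
        a = simulate_admission_frame(cfg)
        b = simulate_admission_frame(cfg)
        assert a.equals(b)
        assert set(a["site"]) == {"intervention", "control"}
        assert not (a["ca_aki"] & a["ha_aki"]).any()

    def test_ha_rate_matches_cohort_model(self):
        cfg = SimConfig(
            n_patients_per_cell=8000,
            ha_aki_base_rate={"intervention": 0.08, "control": 0.08},
            intervention_or_ha=1.0,
            seed=17,
        )
        frame = simulate_admission_frame(cfg)
        non_ca = frame.loc[~frame["ca_aki"]]
        p_hat = non_ca["ha_aki"].mean()
        se = np.sqrt(0.08 * 0.92 / len(non_ca))
        assert abs(p_hat - 0.08) < 3 * se


class TestCsvRoundTrip:
    def test_write_then_read_preserves_records(self, tmp_path):
        cfg = small_config(n_patients_per_cell=25)
        recs = generate_cohort(cfg)
        write_cohort(recs, tmp_path, config=cfg)
        back = read_cohort(tmp_path)
        a, s1, h1 = cohort_to_frames(recs)
        b, s2, h2 = cohort_to_frames(back)
        assert a.equals(b)
        assert np.allclose(s1["scr_umol_l"], s2["scr_umol_l"])
        assert np.allclose(h1["scr_umol_l"], h2["scr_umol_l"])
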