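"""Engine orchestration: gating, determinism, common random numbers,
subgroups, PSA/CEAC."""

import copy
import dataclasses

import numpy as np
import pandas as pd
import pytest

import dppsim


def _null_intervention(params):
    p = copy.deepcopy(params)
    p.intervention.delta_bmi = 0.0
    p.intervention.delta_hba1c = 0.0
    p.intervention.delta_sbp = 0.0
    p.intervention.delta_tc = 0.0
    p.intervention.cost = 0.0
    return p


class TestScenarioGating:
    def test_no_dementia_machinery_off(self, params, small_cohort):
        res = dppsim.run_arm(small_cohort,
                             dppsim.ScenarioConfig("no_dementia", "dpp", seed=1),
                             params)
        assert res.dementia_cost == 0.0
        assert res.dementia_diagnoses_per_1000 == 0.0
        assert res.counters["thin_evaluations"] == 0
        assert res.counters["caide_applications"] == 0

    def test_dementia_only_no_caide(self, params, small_cohort):
        res = dppsim.run_arm(small_cohort,
                             dppsim.ScenarioConfig("dementia_only", "dpp", seed=1),
                             params)
        assert res.counters["thin_evaluations"] > 0
        assert res.counters["caide_applications"] == 0

    def test_reduced_risk_both_active_in_dpp_arm_only(self, params, small_cohort):
        dpp = dppsim.run_arm(small_cohort,
                             dppsim.ScenarioConfig("reduced_dementia_risk", "dpp", seed=1),
                             params)
        ctrl = dppsim.run_arm(small_cohort,
                              dppsim.ScenarioConfig("reduced_dementia_risk", "control", seed=1),
                              params)
        assert dpp.counters["thin_evaluations"] > 0
        assert dpp.counters["caide_applications"] > 0
        assert ctrl.counters["caide_applications"] == 0

    def test_unknown_scenario_rejected(self, params, small_cohort):
        with pytest.raises(dppsim.ConfigError):
            dppsim.run_arm(small_cohort,
                           dppsim.ScenarioConfig("both", "dpp", seed=1), params)

    def test_empty_cohort_rejected(self, params):
        with pytest.raises(dppsim.InputError):
            dppsim.run_arm([], dppsim.ScenarioConfig("no_dementia", "dpp", seed=1),
                           params)


class TestDeterminism:
    def test_same_seed_bit_identical(self, params, small_cohort):
        cfg = dppsim.ScenarioConfig("dementia_only", "dpp", seed=9)
        a = dppsim.run_arm(small_cohort, cfg, params)
        b = dppsim.run_arm(small_cohort, cfg, params)
        for f in ("total_cost", "health_cost", "social_cost", "dementia_cost",
                  "cardiovascular_cost", "qalys", "life_years",
                  "diabetes_diagnoses_per_1000", "dementia_diagnoses_per_1000"):
            assert getattr(a, f) == getattr(b, f), f
        np.testing.assert_array_equal(a.discounted_cost_by_year,
                                      b.discounted_cost_by_year)

    def test_different_seed_differs(self, params, small_cohort):
        a = dppsim.run_arm(small_cohort,
                           dppsim.ScenarioConfig("dementia_only", "dpp", seed=9), params)
        b = dppsim.run_arm(small_cohort,
                           dppsim.ScenarioConfig("dementia_only", "dpp", seed=10), params)
        assert a.qalys != b.qalys


class TestIncrementalStructure:
    def test_null_intervention_all_zero_differences(self, params, small_cohort):
        inc = dppsim.compare_arms(small_cohort, "dementia_only",
                                  _null_intervention(params), seed=2)
        assert inc.delta_total_cost == 0.0
        assert inc.delta_qalys == 0.0
        assert inc.delta_dementia_per_1000 == 0.0
        assert inc.inb == 0.0

    def test_cost_only_intervention(self, params, small_cohort):
        """GBP 270 in cycle 0 (undiscounted), no effects: dCost=+270, INB=-270."""
        p = _null_intervention(params)
        p.intervention.cost = 270.0
        inc = dppsim.compare_arms(small_cohort, "no_dementia", p, seed=2)
        assert inc.delta_total_cost == pytest.approx(270.0)
        assert inc.delta_qalys == 0.0
        assert inc.inb == pytest.approx(-270.0)

    def test_inb_identity_on_stored_values(self, params, small_cohort):
        inc = dppsim.compare_arms(small_cohort, "reduced_dementia_risk", params, seed=2)
        assert inc.inb == pytest.approx(
            20000.0 * inc.delta_qalys - inc.delta_total_cost, rel=1e-12)

    def test_qalys_bounded_by_life_years(self, params, small_cohort):
        for arm in ("control", "dpp"):
            res = dppsim.run_arm(small_cohort,
                                 dppsim.ScenarioConfig("dementia_only", arm, seed=4),
                                 params)
            assert 0.0 < res.qalys <= res.life_years

    def test_intervention_reduces_diabetes_incidence(self, params, large_cohort):
        """Shared random numbers and a negative HbA1c offset cannot increase
        cumulative diabetes diagnoses."""
        inc = dppsim.compare_arms(large_cohort, "no_dementia", params, seed=6)
        assert inc.delta_diabetes_per_1000 <= 0.0

    def test_age_conditional_dementia_not_increased(self, params, large_cohort):
        """Dementia-only scenario: the intervention must not raise dementia
        incidence other than through longer survival, so the diagnosis rate
        per life-year lived cannot increase."""
        inc = dppsim.compare_arms(large_cohort, "dementia_only", params, seed=6)
        rate_ctrl = inc.control.dementia_diagnoses_per_1000 / inc.control.life_years
        rate_dpp = inc.dpp.dementia_diagnoses_per_1000 / inc.dpp.life_years
        assert rate_dpp <= rate_ctrl * 1.02


class TestSubgroups:
    def test_whole_cohort_band_matches_compare_arms(self, params, small_cohort):
        inc = dppsim.compare_arms(small_cohort, "dementia_only", params, seed=3)
        table = dppsim.run_subgroups(small_cohort, "dementia_only", params,
                                     {"all": lambda i: True}, seed=3)
        row = table.iloc[0]
        assert row["n"] == len(small_cohort)
        assert row["inb"] == pytest.approx(inc.inb)
        assert row["delta_qalys"] == pytest.approx(inc.delta_qalys)

    def test_empty_band_flagged_not_failed(self, params, small_cohort):
        table = dppsim.run_subgroups(small_cohort, "dementia_only", params,
                                     {"age 200+": dppsim.age_band(200, 300)}, seed=3)
        row = table.iloc[0]
        assert row["empty"] and row["n"] == 0 and np.isnan(row["inb"])

    def test_age_and_hba1c_band_layout(self, params, small_cohort):
        bands = {"40-50": dppsim.age_band(40, 50), "50-60": dppsim.age_band(50, 60),
                 "low": dppsim.hba1c_band(6.0, 6.1), "high": dppsim.hba1c_band(6.2, 6.4)}
        table = dppsim.run_subgroups(small_cohort, "no_dementia", params, bands, seed=3)
        assert list(table["band"]) == list(bands)
        assert (~table["empty"]).all()


class TestPSA:
    def _zero_se(self, params):
        p = copy.deepcopy(params)
        iv = p.intervention
        iv.se_bmi = iv.se_hba1c = iv.se_sbp = iv.se_tc = 0.0
        di = p.dementia_incidence
        di.se_hr_bmi = di.se_hr_bmi_sq = 0.0
        di.se_hr_antihypertensives = di.se_hr_stroke = di.se_hr_diabetes = 0.0
        ca = p.caide
        ca.se_or_obese = ca.se_or_hypertension = ca.se_or_hyperlipidemia = 0.0
        mp = p.mmse_progression
        mp.se_intercept = mp.se_pm1 = mp.se_pm2 = mp.se_pm3 = 0.0
        mp.se_age = mp.se_prev_rate = 0.0
        dm = p.dementia_mortality
        dm.se_60_84 = dm.se_85_plus = 0.0
        p.costs.dementia_cost_se_frac = 0.0
        p.utilities.utility_se_frac = 0.0
        return p

    def test_degenerate_psa_reproduces_deterministic_result(self, params, small_cohort):
        p = self._zero_se(params)
        det = dppsim.compare_arms(small_cohort, "dementia_only", p, seed=8)
        res = dppsim.run_psa(small_cohort, "dementia_only", p, n_samples=5, seed=8)
        assert np.allclose(res.samples["inb"], det.inb)
        assert set(res.ceac["probability"]) <= {0.0, 1.0}  # step function

    def test_ceac_at_lambda_zero(self, params, small_cohort):
        res = dppsim.run_psa(small_cohort, "dementia_only", params,
                             n_samples=20, lambda_grid=[0.0], seed=8)
        frac_saving = (res.samples["delta_total_cost"] < 0).mean()
        assert res.ceac["probability"].iloc[0] == pytest.approx(frac_saving)

    def test_ceac_monotone_when_qaly_gains_nonnegative(self, params, small_cohort):
        res = dppsim.run_psa(small_cohort, "dementia_only", params,
                             n_samples=20, seed=8)
        if (res.samples["delta_qalys"] >= 0).all():
            prob = res.ceac["probability"].to_numpy()
            assert (np.diff(prob) >= -1e-12).all()

    def test_psa_draws_respect_support(self, params):
        rng = np.random.default_rng(13)
        for _ in range(25):
            p = dppsim.draw_psa_sample(params, rng)
            assert p.dementia_incidence.hr_stroke > 0
            assert p.caide.or_obese > 0
            assert p.dementia_mortality.hr_60_84 > 0
            for band in ("mild", "moderate", "severe"):
                assert p.costs.dementia_health[band] >= 0
            for m in p.utilities.mmse_multipliers.values():
                assert 0 < m <= 1
            h = p.costs.dementia_health
            assert h["mild"] <= h["moderate"] <= h["severe"]

    def test_reproducible_for_fixed_seed(self, params, small_cohort):
        a = dppsim.run_psa(small_cohort, "dementia_only", params, n_samples=5, seed=3)
        b = dppsim.run_psa(small_cohort, "dementia_only", params, n_samples=5, seed=3)
        pd.testing.assert_frame_equal(a.samples, b.samples)


class TestConfigInterface:
    def test_yaml_round_trip_overrides(self, tmp_path):
        cfg = tmp_path / "cfg.yaml"
        cfg.write_text(
            "economics:\n  discount_rate: 0.015\n"
            "intervention:\n  cost: 300\n"
            "dementia:\n  caide_mode: recompute\n"
            "  incidence:\n    hr_stroke: 1.5\n")
        p = dppsim.ParameterSet.from_yaml(cfg)
        assert p.economics.discount_rate == 0.015
        assert p.intervention.cost == 300
        assert p.caide_mode == "recompute"
        assert p.dementia_incidence.hr_stroke == 1.5

    def test_unknown_key_rejected(self):
        with pytest.raises(dppsim.ConfigError):
            dppsim.ParameterSet.from_dict({"economics": {"discount": 0.01}})

    def test_digest_stable_and_sensitive(self, params):
        assert params.digest() == dppsim.ParameterSet.default().digest()
        p2 = dppsim.ParameterSet.default()
        p2.economics.discount_rate = 0.01
        assert p2.digest() != params.digest()
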