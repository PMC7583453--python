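"""Dementia incidence score, CAIDE risk reduction, MMSE onset/progression,
severity banding."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, strategies as st

import dppsim
from dppsim.dementia import mmse_from_gamma_draw, thin_relative_risk


class TestDiagnosisRisk:
    def test_zero_below_age_60(self, params, small_cohort):
        i = dataclasses.replace(small_cohort[0], age=55.0)
        assert dppsim.dementia_diagnosis_probability(i, params.dementia_incidence) == 0.0

    def test_stroke_and_diabetes_hr_product(self, params):
        """RR for stroke + diabetes vs neither: 1.781 x 1.332 = 2.372."""
        di = params.dementia_incidence
        rr_both = thin_relative_risk(di.bmi_reference, False, True, True, di)
        rr_none = thin_relative_risk(di.bmi_reference, False, False, False, di)
        assert float(rr_both / rr_none) == pytest.approx(2.372, abs=5e-4)

    def test_quadratic_bmi_term(self, params):
        """BMI 32 vs reference 28: 0.940^4 * 1.003^(32^2-28^2) = 1.602."""
        di = params.dementia_incidence
        rr = thin_relative_risk(32.0, False, False, False, di)
        assert float(rr) == pytest.approx(1.602, abs=1e-3)

    def test_antihypertensives_protective(self, params):
        di = params.dementia_incidence
        rr = thin_relative_risk(di.bmi_reference, True, False, False, di)
        assert float(rr) == pytest.approx(0.876)

    def test_probability_increases_with_age_band(self, params, small_cohort):
        di = params.dementia_incidence
        probs = []
        for age in (62, 67, 72, 77, 82, 92):
            i = dataclasses.replace(small_cohort[0], age=float(age),
                                    bmi=di.bmi_reference)
            probs.append(dppsim.dementia_diagnosis_probability(i, di))
        assert all(a < b for a, b in zip(probs, probs[1:]))


class TestCaideRiskReduction:
    def test_identical_profiles_unit_rr(self, params):
        rr = dppsim.caide_relative_risk((31.0, 145.0, 7.0), (31.0, 145.0, 7.0),
                                        2, params.caide)
        assert float(rr) == 1.0

    def test_obesity_reversal(self, params):
        """Control obese, treated non-obese: RR = 1/2.296 = 0.4355."""
        rr = dppsim.caide_relative_risk((31.0, 130.0, 5.0), (29.5, 130.0, 5.0),
                                        2, params.caide)
        assert float(rr) == pytest.approx(0.4355, abs=1e-4)

    def test_expires_after_horizon(self, params):
        rr = dppsim.caide_relative_risk((31.0, 145.0, 7.0), (29.0, 130.0, 5.0),
                                        21, params.caide)
        assert float(rr) == 1.0

    @given(bmi=st.floats(20, 45), sbp=st.floats(100, 180), tc=st.floats(3, 9),
           d_bmi=st.floats(0, 3), d_sbp=st.floats(0, 15), d_tc=st.floats(0, 1.5))
    def test_rr_at_most_one_when_treated_below_control(
            self, params, bmi, sbp, tc, d_bmi, d_sbp, d_tc):
        rr = dppsim.caide_relative_risk(
            (bmi, sbp, tc), (bmi - d_bmi, sbp - d_sbp, tc - d_tc), 1, params.caide)
        assert float(rr) <= 1.0 + 1e-12


class TestMMSEOnset:
    def test_mean_mmse_about_21(self, params):
        """shape*scale = 9 => long-run mean MMSE ~ 21 (clamping negligible)."""
        rng = np.random.default_rng(11)
        draws = dppsim.sample_mmse_at_diagnosis(params.mmse_onset, rng, size=100_000)
        se = 5.0 / np.sqrt(draws.size)
        assert abs(draws.mean() - 21.0) < 3 * se + 0.02  # small clamp bias allowance
        assert draws.min() >= 0.0 and draws.max() <= 30.0

    def test_degenerate_scale_gives_30(self):
        p = dppsim.MMSEOnsetParams(shape=3.24, scale=0.0)
        rng = np.random.default_rng(0)
        assert dppsim.sample_mmse_at_diagnosis(p, rng) == 30.0

    @given(st.floats(0, 100))
    def test_clamped_to_scale_range(self, g):
        assert 0.0 <= float(mmse_from_gamma_draw(g)) <= 30.0


class TestMMSEProgression:
    def test_null_coefficients_zero_rate(self):
        p = dppsim.MMSEProgressionParams(intercept=0, b_pm1=0, b_pm2=0,
                                         b_pm3=0, b_age=0, b_prev_rate=0)
        assert float(dppsim.annual_mmse_change(25, 80, -1.0, p)) == 0.0

    def test_hand_evaluated_linear_predictor_high_score(self, params):
        """prev 30, age 75, prev_rate 0 -> -2.0727 (all three spline terms on)."""
        rate = dppsim.annual_mmse_change(30.0, 75.0, 0.0, params.mmse_progression)
        assert float(rate) == pytest.approx(-2.0727, abs=1e-4)

    def test_hand_evaluated_linear_predictor_low_score(self, params):
        """prev 5, age 80, prev_rate -2 -> -1.4816 (PM2 = PM3 = 0)."""
        rate = dppsim.annual_mmse_change(5.0, 80.0, -2.0, params.mmse_progression)
        assert float(rate) == pytest.approx(-1.4816, abs=1e-4)

    def test_out_of_range_score_rejected(self, params):
        with pytest.raises(dppsim.InputError):
            dppsim.annual_mmse_change(31.0, 75.0, 0.0, params.mmse_progression)

    @given(prev=st.floats(0, 30), age=st.floats(60, 100),
           prev_rate=st.floats(-6, 2))
    def test_clamped_update_stays_in_range(self, params, prev, age, prev_rate):
        rate = float(dppsim.annual_mmse_change(prev, age, prev_rate,
                                               params.mmse_progression))
        assert 0.0 <= np.clip(prev + rate, 0.0, 30.0) <= 30.0


class TestSeverityBands:
    @pytest.mark.parametrize("mmse,cost,utility", [
        (30, "none", "none"),
        (27, "none", "none"),
        (26, "mild", "none"),      # literal band mismatch at 26, preserved
        (22, "mild", "21-25"),
        (21, "mild", "21-25"),
        (20, "moderate", "15-20"),
        (15, "moderate", "15-20"),
        (14, "moderate", "10-14"),
        (10, "moderate", "10-14"),
        (9, "severe", "0-9"),
        (0, "severe", "0-9"),
    ])
    def test_band_assignment(self, mmse, cost, utility):
        assert dppsim.severity_band(mmse) == (cost, utility)

    def test_out_of_range_rejected(self):
        with pytest.raises(dppsim.InputError):
            dppsim.severity_band(31)
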