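"""Incidence interpolation, non-hip derivation, stratum calibration, modifiers."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import osteoecon as oe
from osteoecon.risk import (
    NONHIP_SITES,
    PiecewiseIncidenceCurve,
    expected_history_rr,
    stratum_scaling_factor,
)


class TestExponentialFit:
    def test_two_anchor_fit_is_exact_exponential(self):
        curve = oe.fit_exponential_curve([(50, 0.001), (60, 0.002)])
        assert curve.probability(70) == pytest.approx(0.004, rel=1e-12)

    def test_flat_anchors_give_zero_slope(self):
        curve = oe.fit_exponential_curve([(50, 0.01), (60, 0.01), (70, 0.01)])
        assert curve.slope == pytest.approx(0.0, abs=1e-14)
        assert curve.probability(65) == pytest.approx(0.01, rel=1e-12)

    def test_noisy_anchors_match_grid_search_oracle(self):
        rng = np.random.default_rng(0)
        ages = np.array([50.0, 58.0, 66.0, 74.0, 82.0])
        probs = 0.001 * np.exp(0.06 * (ages - 50)) * np.exp(rng.normal(0, 0.1, 5))
        anchors = list(zip(ages, probs))
        curve = oe.fit_exponential_curve(anchors)

        # independent oracle: iteratively refined grid search minimising the
        # squared error on the log scale
        y = np.log(probs)

        def sse(a, b):
            return float(np.sum((y - (a + b * ages)) ** 2))

        a_lo, a_hi, b_lo, b_hi = -20.0, 0.0, -0.5, 0.5
        best = (0.0, 0.0)
        for _ in range(12):
            a_grid = np.linspace(a_lo, a_hi, 41)
            b_grid = np.linspace(b_lo, b_hi, 41)
            errs = [(sse(a, b), a, b) for a in a_grid for b in b_grid]
            _, a_best, b_best = min(errs)
            best = (a_best, b_best)
            a_span, b_span = (a_hi - a_lo) / 10, (b_hi - b_lo) / 10
            a_lo, a_hi = a_best - a_span, a_best + a_span
            b_lo, b_hi = b_best - b_span, b_best + b_span
        assert curve.intercept == pytest.approx(best[0], abs=1e-6)
        assert curve.slope == pytest.approx(best[1], abs=1e-6)

    def test_residuals_satisfy_normal_equations(self):
        anchors = [(50, 0.002), (60, 0.005), (70, 0.009), (80, 0.03)]
        curve = oe.fit_exponential_curve(anchors)
        ages = np.array([a for a, _ in anchors], dtype=float)
        resid = np.log([p for _, p in anchors]) - (curve.intercept + curve.slope * ages)
        assert abs(resid.sum()) < 1e-10
        assert abs((resid * ages).sum()) < 1e-8

    def test_invalid_anchors_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            oe.fit_exponential_curve([(50, 0.01)])
        with pytest.raises(ValueError, match="log"):
            oe.fit_exponential_curve([(50, 0.0), (60, 0.01)])
        with pytest.raises(ValueError, match="distinct"):
            oe.fit_exponential_curve([(50, 0.01), (50, 0.02)])


class TestNonHipExpansion:
    def _hip(self):
        return oe.fit_exponential_curve([(50, 0.001), (90, 0.02)], domain=(50, 100))

    def test_unit_ratios_reproduce_hip_curve(self):
        hip = self._hip()
        ratios = oe.HipRatioTable(bands=((50, 100, {s: 1.0 for s in NONHIP_SITES}),))
        curves = oe.expand_to_nonhip(hip, ratios)
        for site in NONHIP_SITES:
            for age in range(50, 101):
                assert curves[site].probability(age) == pytest.approx(
                    hip.probability(age), rel=1e-9)

    def test_constant_ratio_doubles_hip(self):
        hip = self._hip()
        ratios = oe.HipRatioTable(bands=((50, 100, {"vertebral": 2.0, "wrist": 1.0, "other": 1.0}),))
        vert = oe.expand_to_nonhip(hip, ratios)["vertebral"]
        for age in range(50, 101):
            assert vert.probability(age) == pytest.approx(2 * hip.probability(age), rel=1e-9)

    def test_piecewise_ratios_equal_per_age_multiplication_oracle(self):
        hip = self._hip()
        bands = ((50, 64, {s: 3.0 for s in NONHIP_SITES}),
                 (65, 100, {s: 1.5 for s in NONHIP_SITES}))
        curves = oe.expand_to_nonhip(hip, oe.HipRatioTable(bands=bands))
        for site in NONHIP_SITES:
            for age in range(50, 101):
                ratio = 3.0 if age <= 64 else 1.5
                oracle = min(1.0, hip.probability(age) * ratio)
                assert curves[site].probability(age) == pytest.approx(oracle, rel=1e-9)

    def test_missing_band_rejected(self):
        hip = self._hip()
        ratios = oe.HipRatioTable(bands=((50, 80, {s: 1.0 for s in NONHIP_SITES}),))
        with pytest.raises(ValueError, match="band"):
            oe.expand_to_nonhip(hip, ratios)


class TestStratumCalibration:
    def _prevalence(self, g, o, p, sex="women", age=70):
        return oe.StratumPrevalence(rows={(sex, age): {
            "general": g, "osteoporosis": o, "prevalent_fracture": p}})

    def _curve(self, p):
        return oe.fit_exponential_curve([(50, p), (105, p)], domain=(50, 105))

    def _modifiers(self, rr_op, rr_pf):
        return oe.RiskModifiers(stratum_rr={
            "general": {s: 1.0 for s in oe.SITES},
            "osteoporosis": {s: rr_op for s in oe.SITES},
            "prevalent_fracture": {s: rr_pf for s in oe.SITES}})

    def test_pure_general_population_is_identity(self):
        out = oe.calibrate_stratum_incidence(
            self._curve(0.015), self._prevalence(1.0, 0.0, 0.0),
            self._modifiers(2.0, 2.5), 70, "women", "hip")
        assert out["general"] == pytest.approx(0.015, rel=1e-12)

    def test_two_stratum_closed_form(self):
        out = oe.calibrate_stratum_incidence(
            self._curve(0.015), self._prevalence(0.5, 0.5, 0.0),
            self._modifiers(2.0, 2.5), 70, "women", "hip")
        assert out["general"] == pytest.approx(0.01, rel=1e-12)
        assert out["osteoporosis"] == pytest.approx(0.02, rel=1e-12)

    def test_reference_weights_recompose_population_curve(self, population_tables):
        _, prevalence = population_tables
        modifiers = self._modifiers(2.0, 2.5)
        curve = self._curve(0.02)
        out = oe.calibrate_stratum_incidence(curve, prevalence, modifiers, 70, "women", "hip")
        w = prevalence.fractions("women", 70)
        mixture = (w["general"] * out["general"]
                   + w["osteoporosis"] * out["osteoporosis"]
                   + w["prevalent_fracture"] * out["prevalent_fracture"])
        assert abs(mixture - curve.probability(70)) < 1e-12

    def test_history_split_enters_mixture_but_not_baseline(self, population_tables):
        _, prevalence = population_tables
        modifiers = self._modifiers(2.0, 1.0)
        curve = self._curve(0.02)
        split = {"hip": 0.5, "vertebral": 0.5}
        out = oe.calibrate_stratum_incidence(
            curve, prevalence, modifiers, 70, "women", "hip", pf_history_split=split)
        w = prevalence.fractions("women", 70)
        eff_pf = expected_history_rr("hip", split, modifiers.prior_fx_rr)
        assert eff_pf == pytest.approx(0.5 * 2.3 + 0.5)
        mixture = (w["general"] * out["general"]
                   + w["osteoporosis"] * out["osteoporosis"]
                   + w["prevalent_fracture"] * out["prevalent_fracture"] * eff_pf)
        assert abs(mixture - curve.probability(70)) < 1e-12
        # the baseline excludes the history elevation (applied by the engine)
        assert out["prevalent_fracture"] == pytest.approx(out["general"], rel=1e-12)

    def test_zero_weights_rejected(self):
        prevalence = self._prevalence(0.0, 0.0, 0.0)
        with pytest.raises(ValueError):
            oe.calibrate_stratum_incidence(
                self._curve(0.015), prevalence, self._modifiers(2.0, 2.5), 70, "women", "hip")

    def test_scaling_factor_consistent_with_calibration(self, population_tables):
        _, prevalence = population_tables
        modifiers = self._modifiers(2.0, 2.0)
        split = {"hip": 0.5, "vertebral": 0.5}
        curve = self._curve(0.02)
        out = oe.calibrate_stratum_incidence(
            curve, prevalence, modifiers, 60, "women", "vertebral", pf_history_split=split)
        for stratum in oe.STRATA:
            factor = stratum_scaling_factor(
                prevalence, modifiers, 60, "women", "vertebral", stratum, split)
            assert out[stratum] == pytest.approx(curve.probability(60) * factor, rel=1e-12)


class TestAdjustedProbability:
    def test_prior_same_site_fracture_elevates_risk(self):
        p = oe.adjusted_fracture_probability(
            0.01, "hip", frozenset({"hip"}), "control", oe.RiskModifiers())
        assert p == pytest.approx(0.023)

    def test_supplementation_reduces_hip_risk_by_18_percent(self):
        p = oe.adjusted_fracture_probability(
            0.01, "hip", frozenset(), "intervention", oe.RiskModifiers())
        assert p == pytest.approx(0.0082)

    def test_probability_capped_at_one(self):
        p = oe.adjusted_fracture_probability(
            0.6, "vertebral", frozenset({"vertebral"}), "control", oe.RiskModifiers())
        assert p == 1.0  # 0.6 * 4.4 capped

    def test_other_site_history_does_not_elevate(self):
        p = oe.adjusted_fracture_probability(
            0.01, "hip", frozenset({"wrist"}), "control", oe.RiskModifiers())
        assert p == pytest.approx(0.01)

    @given(
        base=st.floats(min_value=0.0, max_value=1.0),
        site=st.sampled_from(oe.SITES),
        history=st.sets(st.sampled_from(oe.SITES)).map(frozenset),
    )
    @settings(max_examples=200, derandomize=True)
    def test_bounds_and_arm_ordering(self, base, site, history):
        modifiers = oe.RiskModifiers()
        p_control = oe.adjusted_fracture_probability(base, site, history, "control", modifiers)
        p_int = oe.adjusted_fracture_probability(base, site, history, "intervention", modifiers)
        assert 0.0 <= p_int <= p_control <= 1.0
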