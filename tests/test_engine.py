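"""Markov cohort engine: cycle mechanics, conservation, limiting cases."""

import numpy as np
import pytest

import osteoecon as oe
from osteoecon.engine import cycle_step
from osteoecon.pipeline import run_cohort_pair

from conftest import flat_inputs


def _cohort(size=1000, sex="women", age=70, stratum="general"):
    return oe.Cohort(sex=sex, baseline_age=age, stratum=stratum, size=size)


class TestCycleStep:
    def test_no_risk_no_mortality_leaves_occupancy_unchanged(self):
        inputs = flat_inputs()
        occ = {(frozenset(), 0): 500.0}
        nxt, dead, flows = cycle_step(occ, 0.0, 60, inputs, "control")
        assert nxt == occ
        assert dead == 0.0
        assert flows.deaths == 0.0
        assert all(v == 0.0 for v in flows.fractures.values())

    def test_hand_enumerated_two_by_two_outcome_tree(self):
        # p_hip = 0.1, qx = 0.02: dying fraction = 0.1*min(1, 5.5*0.02) + 0.9*0.02
        inputs = flat_inputs(p_site={"hip": 0.1}, qx=0.02)
        occ = {(frozenset(), 0): 1.0}
        _, dead, flows = cycle_step(occ, 0.0, 60, inputs, "control")
        assert dead == pytest.approx(0.029, rel=1e-12)
        assert flows.fractures["hip"] == pytest.approx(0.1, rel=1e-12)
        assert flows.fracture_survivors["hip"] == pytest.approx(0.1 * (1 - 0.11), rel=1e-12)

    def test_certain_death_empties_all_states(self):
        inputs = flat_inputs(p_site={"hip": 0.05, "wrist": 0.1}, qx=1.0)
        occ = {(frozenset(), 0): 300.0, (frozenset({"hip"}), 0): 200.0}
        nxt, dead, flows = cycle_step(occ, 0.0, 60, inputs, "control")
        assert sum(nxt.values()) == pytest.approx(0.0, abs=1e-12)
        assert dead == pytest.approx(500.0, rel=1e-12)
        assert flows.person_years == pytest.approx(250.0, rel=1e-12)

    def test_negative_occupancy_rejected(self):
        inputs = flat_inputs()
        with pytest.raises(ValueError, match="negative or non-finite"):
            cycle_step({(frozenset(), 0): -1.0}, 0.0, 60, inputs, "control")

    def test_total_fracture_probability_capped_with_proportional_shares(self):
        inputs = flat_inputs(p_site={"hip": 0.8, "vertebral": 0.8})
        occ = {(frozenset(), 0): 1.0}
        _, _, flows = cycle_step(occ, 0.0, 60, inputs, "control")
        total = flows.fractures["hip"] + flows.fractures["vertebral"]
        assert total == pytest.approx(0.999, rel=1e-12)
        assert flows.fractures["hip"] == pytest.approx(flows.fractures["vertebral"])


class TestRunCohort:
    def test_empty_cohort_produces_zero_trace(self):
        trace = oe.run_cohort(_cohort(size=0), "control", flat_inputs(qx=0.1), 105)
        assert trace.occupancy.sum() == 0.0
        assert trace.fractures.sum() == 0.0

    def test_geometric_decay_under_constant_mortality(self):
        trace = oe.run_cohort(_cohort(size=1000), "control", flat_inputs(qx=0.1), 105)
        assert trace.alive_start[:3] == pytest.approx([1000.0, 900.0, 810.0], rel=1e-12)

    def test_person_conservation_for_all_reference_cohorts(self, reference_scenario):
        s = reference_scenario
        for cohort in s.cohorts():
            for arm in ("control", "intervention"):
                trace = oe.run_cohort(cohort, arm, s.engine_inputs(cohort), s.max_age)
                assert trace.conservation_error() < 1e-9

    def test_null_efficacy_makes_arms_identical(self, reference_scenario):
        s = reference_scenario
        cohort = _cohort(size=5000)
        inputs = s.engine_inputs(cohort)
        null = oe.RiskModifiers(
            prior_fx_rr=inputs.modifiers.prior_fx_rr,
            stratum_rr=inputs.modifiers.stratum_rr,
            efficacy_rr={site: 1.0 for site in oe.SITES},
        )
        inputs.modifiers = null
        control = oe.run_cohort(cohort, "control", inputs, s.max_age)
        intervention = oe.run_cohort(cohort, "intervention", inputs, s.max_age)
        np.testing.assert_array_equal(control.occupancy, intervention.occupancy)
        np.testing.assert_array_equal(control.fractures, intervention.fractures)

    def test_intervention_avoids_fractures(self, reference_scenario):
        s = reference_scenario
        cohort = _cohort(size=10000)
        control, intervention = run_cohort_pair(s, cohort)
        assert intervention.total_fractures()["total"] <= control.total_fractures()["total"]

    @pytest.mark.parametrize("site", ["hip", "vertebral"])
    def test_cumulative_fractures_monotone_in_efficacy_rr(self, reference_scenario, site):
        s = reference_scenario
        cohort = _cohort(size=10000)
        totals = []
        for rr in (0.6, 0.8, 1.0):
            inputs = s.engine_inputs(cohort)
            eff = dict(inputs.modifiers.efficacy_rr)
            eff[site] = rr
            inputs.modifiers = oe.RiskModifiers(
                prior_fx_rr=inputs.modifiers.prior_fx_rr,
                stratum_rr=inputs.modifiers.stratum_rr,
                efficacy_rr=eff,
            )
            trace = oe.run_cohort(cohort, "intervention", inputs, s.max_age)
            totals.append(trace.total_fractures()["total"])
        assert totals[0] <= totals[1] <= totals[2]

    def test_prevalent_fracture_cohort_starts_with_history(self, reference_scenario):
        s = reference_scenario
        cohort = _cohort(size=1000, stratum="prevalent_fracture")
        trace = oe.run_cohort(cohort, "control", s.engine_inputs(cohort), s.max_age)
        start = dict(zip(trace.state_labels, trace.occupancy[0]))
        assert start.get("hip", 0.0) == pytest.approx(500.0)
        assert start.get("vertebral", 0.0) == pytest.approx(500.0)
        assert start.get("no_fx", 0.0) == 0.0

    def test_zero_incidence_life_expectancy_matches_life_table_closed_form(
        self, reference_scenario
    ):
        lt = reference_scenario.life_tables["women"]
        inputs = flat_inputs()
        inputs.life_table = lt
        cohort = _cohort(size=1.0)
        trace = oe.run_cohort(oe.Cohort("women", 70, "general", 1), "control", inputs, lt.max_age)
        undisc, _ = oe.life_years(trace, 0.0)
        assert abs(undisc - lt.life_expectancy(70)) < 1e-9

    def test_baseline_age_must_be_below_horizon(self):
        with pytest.raises(ValueError, match="max_age"):
            oe.run_cohort(_cohort(age=80), "control", flat_inputs(), 80)


class TestLifeYears:
    def test_death_in_first_cycle_credits_half_year(self):
        trace = oe.run_cohort(_cohort(size=1), "control", flat_inputs(qx=1.0), 105)
        undisc, disc = oe.life_years(trace, 0.03)
        assert undisc == pytest.approx(0.5, rel=1e-12)
        assert disc == pytest.approx(0.5, rel=1e-12)  # t = 0 is undiscounted

    def test_zero_rate_equates_both_totals(self):
        trace = oe.run_cohort(_cohort(size=100), "control", flat_inputs(qx=0.2), 105)
        undisc, disc = oe.life_years(trace, 0.0)
        assert undisc == pytest.approx(disc, rel=1e-15)

    def test_two_cycle_toy_matches_hand_summation(self):
        # 1000 persons, qx = 0.5 each cycle, 3% discounting, then a terminal
        # cycle in which the 250 remaining all die:
        # cycle 0: 500 survive (1 y) + 500 die (0.5 y) = 750 PY at factor 1
        # cycle 1: 250 survive (1 y) + 250 die (0.5 y) = 375 PY at 1/1.03
        # cycle 2: 250 die (0.5 y) = 125 PY at 1/1.03^2
        inputs = flat_inputs()
        qx = {70: 0.5, 71: 0.5, 72: 1.0}
        inputs.life_table = oe.LifeTable(sex="women", max_age=72, qx=qx)
        trace = oe.run_cohort(_cohort(size=1000), "control", inputs, 72)
        _, disc = oe.life_years(trace, 0.03)
        expected = 750.0 + 375.0 / 1.03 + 125.0 / 1.03**2
        assert disc == pytest.approx(expected, abs=1e-12)

    def test_negative_rate_rejected(self):
        trace = oe.run_cohort(_cohort(size=10), "control", flat_inputs(qx=0.5), 105)
        with pytest.raises(ValueError, match="non-negative"):
            oe.life_years(trace, -0.01)


class TestExcessMortality:
    def test_multiplier_applies_only_to_hip_and_vertebral(self):
        qx = 0.02
        for site, expect_excess in [("hip", True), ("vertebral", True),
                                    ("wrist", False), ("other", False)]:
            inputs = flat_inputs(p_site={site: 0.1}, qx=qx)
            _, dead, _ = cycle_step({(frozenset(), 0): 1.0}, 0.0, 60, inputs, "control")
            q_fx = min(1.0, 5.5 * qx) if expect_excess else qx
            assert dead == pytest.approx(0.1 * q_fx + 0.9 * qx, rel=1e-12)

    def test_lingering_excess_duration(self):
        excess = oe.ExcessMortality(multiplier=5.5, duration=1)
        inputs = flat_inputs(p_site={"hip": 1.0}, qx=0.01, excess=excess)
        occ, dead, _ = cycle_step({(frozenset(), 0): 1.0}, 0.0, 60, inputs, "control")
        # hip-fracture survivors carry one more cycle of excess risk
        assert occ[(frozenset({"hip"}), 1)] > 0
        follow = flat_inputs(qx=0.01, excess=excess)
        occ2 = {(frozenset({"hip"}), 1): 1.0}
        nxt, deaths, _ = cycle_step(occ2, 0.0, 61, follow, "control")
        assert deaths == pytest.approx(min(1.0, 5.5 * 0.01), rel=1e-12)
        # the counter decrements: survivors are back on background mortality
        assert set(nxt) == {(frozenset({"hip"}), 0)}
        _, deaths3, _ = cycle_step(nxt, 0.0, 62, follow, "control")
        assert deaths3 / sum(nxt.values()) == pytest.approx(0.01, rel=1e-12)

    def test_attributable_fraction_scales_excess(self):
        excess = oe.ExcessMortality(multiplier=5.5, attributable_fraction=0.5)
        assert excess.adjusted_qx(0.02) == pytest.approx(0.02 * (1 + 0.5 * 4.5))
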