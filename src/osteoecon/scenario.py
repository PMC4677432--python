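"""Scenario assembly: the complete, reproducible input bundle for one run.

A scenario bundles the two life tables, the cohort projection and stratum
prevalences, the hip-incidence anchors and site-ratio bands per sex, the cost
schedule and all risk modifiers.  The cohort tables default to the packaged
reference values; every externally sourced input (mortality, hip incidence,
fracture costs) is a parametric synthetic stand-in, lightly jittered by the
scenario seed so that distinct seeds give distinct but structurally identical
study conditions.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from . import demography, risk
from .demography import (
    BASELINE_AGES,
    SEXES,
    STRATA,
    Cohort,
    LifeTable,
    PopulationProjection,
    StratumPrevalence,
    build_cohorts,
    generate_hip_incidence_anchors,
    generate_life_table,
    load_population_tables,
)
from .economics import CostSchedule
from .engine import EngineInputs, ExcessMortality
from .risk import (
    NONHIP_SITES,
    SITES,
    HipRatioTable,
    IncidenceCurve,
    PiecewiseIncidenceCurve,
    RiskModifiers,
    expand_to_nonhip,
    fit_exponential_curve,
    make_site_base_curves,
)

#: fully-resolved default configuration = the reference study conditions
DEFAULT_CONFIG: Dict = {
    "demography": {
        "max_age": 105,
        "population": "packaged",
        "mortality": {
            "women": {"makeham_a": 0.0005, "gompertz_b": 0.002, "gompertz_c": 0.10},
            "men": {"makeham_a": 0.0012, "gompertz_b": 0.0035, "gompertz_c": 0.098},
        },
        "hip_incidence": {
            "women": {"rate_at_50": 0.0005, "doubling_time": 6.0},
            "men": {"rate_at_50": 0.0003, "doubling_time": 7.0},
        },
        "anchor_ages": [50, 60, 70, 80, 90],
        "anchor_jitter_sd": 0.03,
    },
    "risk": {
        "prior_fracture_rr": {"hip": 2.3, "vertebral": 4.4, "wrist": 3.3, "other": 1.9},
        "efficacy_rr": {"hip": 0.82, "vertebral": 0.87, "wrist": 0.80, "other": 0.80},
        "stratum_rr": {
            "osteoporosis": {"hip": 2.0, "vertebral": 2.0, "wrist": 2.0, "other": 2.0},
            "prevalent_fracture": {"hip": 2.0, "vertebral": 2.0, "wrist": 2.0, "other": 2.0},
        },
        "prevalent_fracture_split": {"hip": 0.5, "vertebral": 0.5},
        "ratio_bands": {
            "women": [
                {"from_age": 50, "to_age": 64, "vertebral": 4.0, "wrist": 5.0, "other": 6.0},
                {"from_age": 65, "to_age": 79, "vertebral": 1.5, "wrist": 1.5, "other": 2.0},
                {"from_age": 80, "to_age": 105, "vertebral": 0.8, "wrist": 0.4, "other": 1.0},
            ],
            "men": [
                {"from_age": 50, "to_age": 64, "vertebral": 3.0, "wrist": 2.0, "other": 4.0},
                {"from_age": 65, "to_age": 79, "vertebral": 1.2, "wrist": 0.8, "other": 1.5},
                {"from_age": 80, "to_age": 105, "vertebral": 0.7, "wrist": 0.3, "other": 1.0},
            ],
        },
    },
    "economics": {
        "hip_cost_anchors": [[50, 8000.0], [60, 8800.0], [70, 9800.0], [80, 11000.0], [90, 12500.0]],
        "cost_curve_family": "power",
        "hip_extra_first_year": 6000.0,
        "nonhip_relative": {"vertebral": 0.6, "wrist": 0.2, "other": 0.3},
        "supplement_price": 250.0,
        "supplement_prices": [150.0, 250.0, 350.0],
        "discount_rate_costs": 0.03,
        "discount_rate_effects": 0.03,
        "long_term_hip_annual": 0.0,
        "fold_hip_extra_into_acute": False,
    },
    "run": {
        "seed": 1,
        "arms": ["control", "intervention"],
        "cohorts": "all",
        "excess_mortality_multiplier": 5.5,
        "excess_mortality_duration": 0,
        "excess_attributable_fraction": 1.0,
        "headline_discounted_lyg": True,
    },
}


def _jitter(values: List[float], rng: np.random.Generator, sd: float) -> List[float]:
    if sd <= 0:
        return list(values)
    return [v * float(np.exp(rng.normal(0.0, sd))) for v in values]


@dataclass
class Scenario:
    """A complete, validated input bundle for the cohort model."""

    config: Dict
    seed: int
    life_tables: Dict[str, LifeTable]
    projection: PopulationProjection
    prevalence: StratumPrevalence
    hip_anchors: Dict[str, List[Tuple[int, float]]]
    cost_anchors: List[Tuple[float, float]]
    ratio_tables: Dict[str, HipRatioTable]
    modifiers: RiskModifiers
    schedule: CostSchedule
    max_age: int
    prices: List[float]
    pf_split: Dict[str, float]
    excess: ExcessMortality
    headline_discounted: bool
    _curves: Dict[str, Dict[str, object]] = field(default_factory=dict, repr=False)

    def population_curves(self, sex: str) -> Dict[str, object]:
        """Population-average incidence curve per site (hip fitted, non-hip derived)."""
        if sex not in self._curves:
            hip = fit_exponential_curve(
                self.hip_anchors[sex], sex=sex, site="hip", domain=(50, self.max_age)
            )
            curves: Dict[str, object] = {"hip": hip}
            curves.update(expand_to_nonhip(hip, self.ratio_tables[sex]))
            self._curves[sex] = curves
        return self._curves[sex]

    def cohorts(self) -> List[Cohort]:
        return build_cohorts(self.projection, self.prevalence)

    def start_history(self, stratum: str) -> Dict[frozenset, float]:
        if stratum == "prevalent_fracture":
            return {frozenset({site}): frac for site, frac in self.pf_split.items() if frac > 0}
        return {frozenset(): 1.0}

    def engine_inputs(self, cohort: Cohort) -> EngineInputs:
        """Inputs for the transition engine: stratum-calibrated curves, modifiers, mortality."""
        curves = self.population_curves(cohort.sex)
        site_base = make_site_base_curves(
            curves,
            self.prevalence,
            self.modifiers,
            cohort.baseline_age,
            cohort.sex,
            cohort.stratum,
            pf_history_split=self.pf_split,
        )
        return EngineInputs(
            site_base=site_base,
            modifiers=self.modifiers,
            life_table=self.life_tables[cohort.sex],
            excess=self.excess,
            start_history=self.start_history(cohort.stratum),
        )

    def validate(self) -> None:
        """Run every domain-type invariant over the bundle; raises on violation."""
        for sex in SEXES:
            lt = self.life_tables[sex]
            surv = list(lt.survival(50).values())
            if any(b > a + 1e-12 for a, b in zip(surv, surv[1:])):
                raise ValueError("life-table survival curve must be non-increasing")
            for age, p in self.hip_anchors[sex]:
                if not (0.0 < p <= 1.0):
                    raise ValueError(f"hip anchor probability at age {age} outside (0, 1]")
            curves = self.population_curves(sex)
            for site in SITES:
                for age in range(50, self.max_age + 1):
                    p = curves[site].probability(age)
                    if not (0.0 <= p <= 1.0):
                        raise ValueError(f"{sex} {site} incidence at {age} outside [0, 1]")
        build_cohorts(self.projection, self.prevalence)  # raises on bad prevalence
        if abs(sum(self.pf_split.values()) - 1.0) > 1e-9:
            raise ValueError("prevalent-fracture history split must sum to 1")
        for age, cost in self.cost_anchors:
            if cost <= 0:
                raise ValueError(f"cost anchor at age {age} must be positive")


def build_scenario(config: Dict) -> Scenario:
    """Materialise a Scenario from a fully-resolved configuration mapping."""
    cfg = copy.deepcopy(config)
    demo, riskc, econ, runc = cfg["demography"], cfg["risk"], cfg["economics"], cfg["run"]
    seed = int(runc["seed"])
    max_age = int(demo["max_age"])

    life_tables = {
        sex: generate_life_table(
            makeham_a=demo["mortality"][sex]["makeham_a"],
            gompertz_b=demo["mortality"][sex]["gompertz_b"],
            gompertz_c=demo["mortality"][sex]["gompertz_c"],
            max_age=max_age,
            sex=sex,
        )
        for sex in SEXES
    }

    if demo["population"] == "packaged":
        projection, prevalence = load_population_tables()
    else:
        entries, rows = {}, {}
        for sex in SEXES:
            for rec in demo["population"][sex]:
                key = (sex, int(rec["age"]))
                entries[key] = int(rec["total"])
                rows[key] = {
                    "general": float(rec["general_pct"]),
                    "osteoporosis": float(rec["osteoporosis_pct"]),
                    "prevalent_fracture": float(rec["prevalent_fx_pct"]),
                }
        projection = PopulationProjection(entries=entries)
        prevalence = StratumPrevalence(rows=rows)

    sd = float(demo["anchor_jitter_sd"])
    hip_anchors: Dict[str, List[Tuple[int, float]]] = {}
    for i, sex in enumerate(SEXES):
        anchors = generate_hip_incidence_anchors(
            rate_at_50=demo["hip_incidence"][sex]["rate_at_50"],
            doubling_time=demo["hip_incidence"][sex]["doubling_time"],
            anchor_ages=demo["anchor_ages"],
        )
        rng = np.random.default_rng(np.random.SeedSequence([seed, 10 + i]))
        probs = _jitter([p for _, p in anchors], rng, sd)
        hip_anchors[sex] = [(a, min(p, 0.999)) for (a, _), p in zip(anchors, probs)]

    rng_cost = np.random.default_rng(np.random.SeedSequence([seed, 20]))
    base_costs = [(float(a), float(c)) for a, c in econ["hip_cost_anchors"]]
    cost_anchors = [
        (a, c) for (a, _), c in zip(base_costs, _jitter([c for _, c in base_costs], rng_cost, sd))
    ]

    ratio_tables = {
        sex: HipRatioTable(
            bands=tuple(
                (
                    int(b["from_age"]),
                    int(b["to_age"]),
                    {s: float(b[s]) for s in NONHIP_SITES},
                )
                for b in riskc["ratio_bands"][sex]
            )
        )
        for sex in SEXES
    }

    stratum_rr = {"general": {s: 1.0 for s in SITES}}
    for stratum in ("osteoporosis", "prevalent_fracture"):
        stratum_rr[stratum] = {s: float(riskc["stratum_rr"][stratum][s]) for s in SITES}
    modifiers = RiskModifiers(
        prior_fx_rr={s: float(riskc["prior_fracture_rr"][s]) for s in SITES},
        stratum_rr=stratum_rr,
        efficacy_rr={s: float(riskc["efficacy_rr"][s]) for s in SITES},
    )

    schedule = CostSchedule(
        hip_cost_anchors=tuple(cost_anchors),
        hip_extra_first_year=float(econ["hip_extra_first_year"]),
        nonhip_relative={s: float(econ["nonhip_relative"][s]) for s in NONHIP_SITES},
        supplement_annual_price=float(econ["supplement_price"]),
        discount_rate_costs=float(econ["discount_rate_costs"]),
        discount_rate_effects=float(econ["discount_rate_effects"]),
        cost_curve_family=str(econ["cost_curve_family"]),
        long_term_hip_annual=float(econ["long_term_hip_annual"]),
        fold_hip_extra_into_acute=bool(econ["fold_hip_extra_into_acute"]),
    )

    excess = ExcessMortality(
        multiplier=float(runc["excess_mortality_multiplier"]),
        duration=int(runc["excess_mortality_duration"]),
        attributable_fraction=float(runc["excess_attributable_fraction"]),
    )

    scenario = Scenario(
        config=cfg,
        seed=seed,
        life_tables=life_tables,
        projection=projection,
        prevalence=prevalence,
        hip_anchors=hip_anchors,
        cost_anchors=cost_anchors,
        ratio_tables=ratio_tables,
        modifiers=modifiers,
        schedule=schedule,
        max_age=max_age,
        prices=[float(p) for p in econ["supplement_prices"]],
        pf_split={k: float(v) for k, v in riskc["prevalent_fracture_split"].items()},
        excess=excess,
        headline_discounted=bool(runc["headline_discounted_lyg"]),
    )
    scenario.validate()
    return scenario


def make_reference_scenario(seed: int = 1) -> Scenario:
    """The reference study conditions: packaged cohort tables plus seeded synthetic inputs."""
    cfg = copy.deepcopy(DEFAULT_CONFIG)
    cfg["run"]["seed"] = int(seed)
    return build_scenario(cfg)
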