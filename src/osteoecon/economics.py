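"""Direct medical costs: fracture costs, supplement costs, discounting.

The payer perspective covers acute hip hospitalisation (age-dependent, fitted
through cost anchors with a power or quadratic polynomial regression), extra
costs in the year following a hip fracture for fracture survivors, non-hip
fracture costs expressed as fractions of the acute hip cost (no long-term
non-hip costs), and the annual supplement price in the intervention arm.
All flows are discounted at a constant annual rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd

from .engine import CohortTrace
from .risk import NONHIP_SITES, SITES

COST_FAMILIES = ("power", "polynomial")


@dataclass(frozen=True)
class CostCurve:
    """Age -> cost function fitted through anchors; evaluation clamps at >= 0."""

    family: str
    coefficients: Tuple[float, ...]

    def cost(self, age: float) -> float:
        if self.family == "power":
            log_k, exponent = self.coefficients
            return max(0.0, float(np.exp(log_k) * age ** exponent))
        c0, c1, c2 = self.coefficients
        return max(0.0, float(c0 + c1 * age + c2 * age * age))


def fit_cost_curve(anchors: Sequence[Tuple[float, float]], family: str = "power") -> CostCurve:
    """Fit an age-cost curve: power law (log-log least squares) or quadratic."""
    if family not in COST_FAMILIES:
        raise ValueError(f"unknown cost curve family {family!r}")
    ages = np.asarray([a for a, _ in anchors], dtype=float)
    costs = np.asarray([c for _, c in anchors], dtype=float)
    if len(np.unique(ages)) != len(ages):
        raise ValueError("anchor ages must be distinct")
    if family == "power":
        if len(anchors) < 2:
            raise ValueError("power fit needs at least 2 anchors")
        if np.any(costs <= 0):
            raise ValueError("power fit requires strictly positive costs")
        design = np.column_stack([np.ones_like(ages), np.log(ages)])
        coef, *_ = np.linalg.lstsq(design, np.log(costs), rcond=None)
        return CostCurve(family="power", coefficients=(float(coef[0]), float(coef[1])))
    if len(anchors) < 3:
        raise ValueError("polynomial fit needs at least 3 anchors")
    design = np.column_stack([np.ones_like(ages), ages, ages * ages])
    coef, *_ = np.linalg.lstsq(design, costs, rcond=None)
    return CostCurve(family="polynomial", coefficients=tuple(float(c) for c in coef))


def discount(amount: float, cycle: int, rate: float) -> float:
    """Present value of ``amount`` occurring ``cycle`` years after baseline."""
    if rate < 0:
        raise ValueError("discount rate must be non-negative")
    if cycle < 0:
        raise ValueError("cycle must be non-negative")
    return amount / (1.0 + rate) ** cycle


@dataclass(frozen=True)
class CostSchedule:
    """All cost parameters of one scenario (euros, single currency-year)."""

    hip_cost_anchors: Tuple[Tuple[float, float], ...]
    hip_extra_first_year: float = 6000.0
    nonhip_relative: Dict[str, float] = field(
        default_factory=lambda: {"vertebral": 0.6, "wrist": 0.2, "other": 0.3}
    )
    supplement_annual_price: float = 250.0
    discount_rate_costs: float = 0.03
    discount_rate_effects: float = 0.03
    cost_curve_family: str = "power"
    long_term_hip_annual: float = 0.0
    fold_hip_extra_into_acute: bool = False

    def __post_init__(self) -> None:
        if self.hip_extra_first_year < 0 or self.supplement_annual_price < 0:
            raise ValueError("costs must be non-negative")
        if self.discount_rate_costs < 0 or self.discount_rate_effects < 0:
            raise ValueError("discount rates must be non-negative")
        for site in NONHIP_SITES:
            if self.nonhip_relative.get(site, -1.0) < 0:
                raise ValueError(f"nonhip_relative[{site}] must be a non-negative fraction")
        if self.cost_curve_family not in COST_FAMILIES:
            raise ValueError(f"unknown cost curve family {self.cost_curve_family!r}")

    def hip_cost_curve(self) -> CostCurve:
        return fit_cost_curve(self.hip_cost_anchors, family=self.cost_curve_family)

    def site_cost(self, site: str, age: float, hip_curve: CostCurve) -> float:
        acute_hip = hip_curve.cost(age)
        if site == "hip":
            extra = self.hip_extra_first_year if self.fold_hip_extra_into_acute else 0.0
            return acute_hip + extra
        return acute_hip * self.nonhip_relative[site]


@dataclass
class ArmCosts:
    """Total discounted cost of one arm plus its per-cycle breakdown."""

    arm: str
    total: float
    breakdown: pd.DataFrame

    def component_total(self, name: str) -> float:
        return float(self.breakdown[name].sum())


def arm_costs(trace: CohortTrace, schedule: CostSchedule, arm: str) -> ArmCosts:
    """Assemble the discounted cost stream of one arm from a cohort trace.

    Per cycle: acute fracture costs for every incident fracture at that age;
    hip first-year extra costs at t+1 for hip fracturers who survived cycle t;
    the supplement price times person-years alive (intervention arm only).
    Non-hip fractures carry no cost beyond the event cycle.
    """
    if arm not in ("intervention", "control"):
        raise ValueError(f"unknown arm {arm!r}")
    hip_curve = schedule.hip_cost_curve()
    rate = schedule.discount_rate_costs
    T = trace.n_cycles
    rows: List[Dict[str, float]] = []
    site_idx = {s: i for i, s in enumerate(SITES)}

    hip_in_history = np.zeros(T)
    if schedule.long_term_hip_annual > 0:
        hip_cols = [
            i for i, lbl in enumerate(trace.state_labels[:-1]) if "hip" in lbl.split("|")[0].split("+")
        ]
        hip_in_history = trace.occupancy[:-1, hip_cols].sum(axis=1)

    for t in range(T):
        age = int(trace.ages[t])
        acute = {
            s: trace.fractures[t, site_idx[s]] * schedule.site_cost(s, age, hip_curve)
            for s in SITES
        }
        hip_extra = 0.0
        if not schedule.fold_hip_extra_into_acute and t > 0:
            hip_extra = trace.fracture_survivors[t - 1, site_idx["hip"]] * schedule.hip_extra_first_year
        long_term = hip_in_history[t] * schedule.long_term_hip_annual
        supplement = (
            schedule.supplement_annual_price * trace.person_years[t]
            if arm == "intervention"
            else 0.0
        )
        undiscounted = sum(acute.values()) + hip_extra + long_term + supplement
        rows.append(
            {
                "cycle": t,
                "age": age,
                **{f"acute_{s}": acute[s] for s in SITES},
                "hip_extra": hip_extra,
                "long_term_hip": long_term,
                "supplement": supplement,
                "undiscounted": undiscounted,
                "discounted": discount(undiscounted, t, rate),
            }
        )
    breakdown = pd.DataFrame(rows)
    return ArmCosts(arm=arm, total=float(breakdown["discounted"].sum()), breakdown=breakdown)


def discounted_person_years(trace: CohortTrace, rate: float) -> float:
    """Person-years alive discounted at the cost rate (supplement-cost driver)."""
    t = np.arange(trace.n_cycles)
    return float((trace.person_years / (1.0 + rate) ** t).sum())
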