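"""Arm comparison: fractures avoided, life-years gained, incremental cost, ICERs.

The two headline ratios are cost per fracture avoided and cost per life-year
gained (LYG).  Ratios with non-positive denominators are reported as typed
outcomes (no effect / dominated), never as sentinel numbers; a negative
incremental cost with positive effect is flagged cost-saving.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import pandas as pd

from .economics import ArmCosts, discounted_person_years
from .engine import CohortTrace, life_years
from .risk import SITES


@dataclass(frozen=True)
class Ratio:
    """An incremental cost-effectiveness ratio or a typed reason it is undefined.

    ``status`` is "ok", "cost_saving" (value <= 0 with positive effect),
    "no_effect" (zero denominator) or "dominated" (negative denominator:
    the intervention is worse on this outcome).
    """

    value: Optional[float]
    status: str

    @property
    def defined(self) -> bool:
        return self.value is not None

    def __format__(self, spec: str) -> str:
        if self.value is None:
            return self.status
        return format(self.value, spec)


def _ratio(incremental_cost: float, effect: float) -> Ratio:
    if effect > 0:
        status = "cost_saving" if incremental_cost <= 0 else "ok"
        return Ratio(value=incremental_cost / effect, status=status)
    if effect == 0:
        return Ratio(value=None, status="no_effect")
    return Ratio(value=None, status="dominated")


@dataclass
class ComparisonResult:
    """Incremental outcomes of intervention vs control for one cohort."""

    cohort_id: str
    fractures_avoided: Dict[str, float]
    lyg_undiscounted: float
    lyg_discounted: float
    incremental_cost: float
    cost_per_fracture_avoided: Ratio
    cost_per_lyg: Ratio
    supplement_price: float
    headline_discounted: bool = True

    @property
    def lyg(self) -> float:
        return self.lyg_discounted if self.headline_discounted else self.lyg_undiscounted

    def as_row(self) -> Dict[str, object]:
        return {
            "cohort": self.cohort_id,
            "price": self.supplement_price,
            **{f"avoided_{s}": self.fractures_avoided[s] for s in SITES},
            "avoided_total": self.fractures_avoided["total"],
            "lyg_undiscounted": self.lyg_undiscounted,
            "lyg_discounted": self.lyg_discounted,
            "incremental_cost": self.incremental_cost,
            "cost_per_fracture_avoided": (
                self.cost_per_fracture_avoided.value
                if self.cost_per_fracture_avoided.defined
                else self.cost_per_fracture_avoided.status
            ),
            "cost_per_lyg": (
                self.cost_per_lyg.value if self.cost_per_lyg.defined else self.cost_per_lyg.status
            ),
        }


def compare(
    intervention: CohortTrace,
    intervention_costs: ArmCosts,
    control: CohortTrace,
    control_costs: ArmCosts,
    effect_discount_rate: float,
    headline_discounted: bool = True,
) -> ComparisonResult:
    """Incremental comparison of the two arms of one cohort."""
    if control.cohort != intervention.cohort:
        raise ValueError("arms were run on different cohorts")
    fx_c = control.total_fractures()
    fx_i = intervention.total_fractures()
    avoided = {k: fx_c[k] - fx_i[k] for k in fx_c}
    ly_c = life_years(control, effect_discount_rate)
    ly_i = life_years(intervention, effect_discount_rate)
    lyg_undisc = ly_i[0] - ly_c[0]
    lyg_disc = ly_i[1] - ly_c[1]
    inc_cost = intervention_costs.total - control_costs.total
    lyg_headline = lyg_disc if headline_discounted else lyg_undisc
    return ComparisonResult(
        cohort_id=intervention.cohort.cohort_id if intervention.cohort else "",
        fractures_avoided=avoided,
        lyg_undiscounted=lyg_undisc,
        lyg_discounted=lyg_disc,
        incremental_cost=inc_cost,
        cost_per_fracture_avoided=_ratio(inc_cost, avoided["total"]),
        cost_per_lyg=_ratio(inc_cost, lyg_headline),
        supplement_price=0.0,
        headline_discounted=headline_discounted,
    )


def price_sweep(
    intervention: CohortTrace,
    control: CohortTrace,
    schedule,
    prices: Sequence[float],
    arm_costs_fn,
    headline_discounted: bool = True,
) -> List[ComparisonResult]:
    """Re-price the supplement over a list of annual prices on fixed traces.

    The traces are computed once per arm; only the supplement cost term varies,
    so the cost-per-LYG is affine in the price with slope equal to the
    discounted intervention-arm person-years divided by the LYG.
    """
    if len(prices) == 0:
        raise ValueError("at least one price is required")
    if any(p < 0 for p in prices):
        raise ValueError("supplement prices must be non-negative")
    from dataclasses import replace

    results = []
    control_cost = arm_costs_fn(control, schedule, "control")
    for price in prices:
        sched_p = replace(schedule, supplement_annual_price=float(price))
        int_cost = arm_costs_fn(intervention, sched_p, "intervention")
        res = compare(
            intervention,
            int_cost,
            control,
            control_cost,
            effect_discount_rate=schedule.discount_rate_effects,
            headline_discounted=headline_discounted,
        )
        res.supplement_price = float(price)
        results.append(res)
    return results


def cost_per_lyg_price_slope(intervention: CohortTrace, schedule, lyg: float) -> float:
    """Analytic d(cost per LYG)/d(price): discounted person-years over LYG."""
    if lyg <= 0:
        raise ValueError("slope defined only for positive LYG")
    return discounted_person_years(intervention, schedule.discount_rate_costs) / lyg


@dataclass
class AggregateResult:
    """Population totals of fractures avoided and LYG, per sex and overall."""

    by_sex: Dict[str, Dict[str, float]]
    overall: Dict[str, float]
    table: pd.DataFrame = field(repr=False, default=None)


def aggregate(results: Sequence[ComparisonResult]) -> AggregateResult:
    """Sum per-cohort incremental outcomes into population totals.

    Reproducing any particular national headline requires the original national
    life tables, incidence and cost inputs; with synthetic stand-ins the totals
    are internally consistent but scenario-specific.
    """
    seen = set()
    for r in results:
        if r.cohort_id in seen:
            raise ValueError(f"duplicate cohort id {r.cohort_id!r}")
        seen.add(r.cohort_id)
    rows = [r.as_row() for r in results]
    table = pd.DataFrame(rows)
    by_sex: Dict[str, Dict[str, float]] = {}
    for r in results:
        sex = r.cohort_id.split(":")[0]
        acc = by_sex.setdefault(
            sex,
            {"fractures_avoided": 0.0, "lyg": 0.0, "lyg_undiscounted": 0.0, "incremental_cost": 0.0},
        )
        acc["fractures_avoided"] += r.fractures_avoided["total"]
        acc["lyg"] += r.lyg
        acc["lyg_undiscounted"] += r.lyg_undiscounted
        acc["incremental_cost"] += r.incremental_cost
    overall = {
        key: sum(acc[key] for acc in by_sex.values())
        for key in ("fractures_avoided", "lyg", "lyg_undiscounted", "incremental_cost")
    }
    return AggregateResult(by_sex=by_sex, overall=overall, table=table)
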