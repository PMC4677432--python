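"""Individual-level Monte-Carlo cross-check of the deterministic cohort engine.

Simulates n individuals through the identical annual-cycle contract — at most
one index fracture per person-year with proportional site allocation and the
same capped total, fracture before mortality, excess mortality after hip or
vertebral fracture, half-year credit in the death year, identical cost rules —
but with its own transition code, so it serves as an independent oracle.
Random draws use a counter-based Philox stream keyed on (seed, cycle) and
indexed by individual, making results independent of iteration order.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional

import numpy as np

from .demography import Cohort
from .economics import CostSchedule
from .engine import EXCESS_MORTALITY_SITES, TOTAL_FRACTURE_CAP, EngineInputs
from .risk import SITES


@dataclass(frozen=True)
class MicrosimEstimate:
    """A Monte-Carlo point estimate with its standard error."""

    label: str
    estimate: float
    se: float
    n: int

    def __post_init__(self) -> None:
        if self.se < 0:
            raise ValueError("standard error must be non-negative")
        if self.n < 1:
            raise ValueError("replicate count must be at least 1")

    def z(self, reference: float) -> float:
        """Standardised deviation of a reference value from the estimate.

        A zero standard error (degenerate metric, e.g. lifetime deaths) falls
        back to an absolute float-tolerance comparison.
        """
        if self.se == 0:
            close = abs(reference - self.estimate) <= 1e-9 * max(1.0, abs(self.estimate))
            return 0.0 if close else np.inf
        return (reference - self.estimate) / self.se


def _cycle_rng(seed: int, cycle: int) -> np.random.Generator:
    key = np.array([np.uint64(seed), np.uint64(cycle)], dtype=np.uint64)
    return np.random.Generator(np.random.Philox(key=key))


def simulate(
    cohort: Cohort,
    arm: str,
    inputs: EngineInputs,
    max_age: int,
    n_individuals: int,
    seed: int,
    schedule: Optional[CostSchedule] = None,
) -> Dict[str, MicrosimEstimate]:
    """Monte-Carlo estimates of fractures, deaths, life-years and costs.

    Estimates are scaled to the cohort head count; standard errors scale
    accordingly.  The starting-history split of a prevalent-fracture cohort is
    assigned deterministically by individual index.
    """
    if n_individuals < 1:
        raise ValueError("n_individuals must be at least 1")
    if arm not in ("intervention", "control"):
        raise ValueError(f"unknown arm {arm!r}")
    if inputs.life_table.max_age < max_age:
        raise ValueError("life table does not cover the projection horizon")
    if inputs.life_table.sex != cohort.sex:
        raise ValueError("parameter bundle mismatch: life table sex differs from cohort sex")

    n = int(n_individuals)
    site_idx = {s: i for i, s in enumerate(SITES)}
    excess_idx = [site_idx[s] for s in EXCESS_MORTALITY_SITES]

    alive = np.ones(n, dtype=bool)
    history = np.zeros((n, len(SITES)), dtype=bool)
    exc_left = np.zeros(n, dtype=np.int64)
    items = list(inputs.start_history.items())
    bounds = np.round(np.cumsum([frac for _, frac in items]) * n).astype(int)
    bounds[-1] = n  # rounding remainder joins the last starting-history class
    lo = 0
    for (h, _), hi in zip(items, bounds):
        for site in h:
            history[lo:hi, site_idx[site]] = True
        lo = hi

    fx_counts = np.zeros((n, len(SITES)))
    died = np.zeros(n, dtype=bool)
    ly = np.zeros(n)
    ly_disc = np.zeros(n)
    cost = np.zeros(n)

    hip_curve = schedule.hip_cost_curve() if schedule is not None else None
    pending_hip_extra = np.zeros(n, dtype=bool)

    eff_rate = schedule.discount_rate_effects if schedule is not None else 0.0
    cost_rate = schedule.discount_rate_costs if schedule is not None else 0.0
    mult = 1.0 + inputs.excess.attributable_fraction * (inputs.excess.multiplier - 1.0)

    ages = range(cohort.baseline_age, max_age + 1)
    for t, age in enumerate(ages):
        if not alive.any():
            break
        rng = _cycle_rng(seed, t)
        u_frac = rng.random(n)
        u_death = rng.random(n)
        d_eff = (1.0 + eff_rate) ** (-t)
        d_cost = (1.0 + cost_rate) ** (-t)

        # hip first-year extra cost for last cycle's surviving hip fracturers
        if schedule is not None and not schedule.fold_hip_extra_into_acute:
            who = pending_hip_extra & alive
            cost[who] += schedule.hip_extra_first_year * d_cost
        pending_next = np.zeros(n, dtype=bool)

        if schedule is not None and schedule.long_term_hip_annual > 0:
            who = alive & history[:, site_idx["hip"]]
            cost[who] += schedule.long_term_hip_annual * d_cost

        base = np.array([inputs.site_base[s](age) for s in SITES])
        p = np.tile(base, (n, 1))
        for s in SITES:
            j = site_idx[s]
            prior = history[:, j]
            p[prior, j] *= inputs.modifiers.prior_fx_rr[s]
            if arm == "intervention":
                p[:, j] *= inputs.modifiers.efficacy_rr[s]
        p = np.minimum(p, 1.0)
        total = p.sum(axis=1)
        p_any = np.minimum(total, TOTAL_FRACTURE_CAP)
        with np.errstate(invalid="ignore", divide="ignore"):
            shares = np.where(total[:, None] > 0, p * (p_any / np.where(total > 0, total, 1.0))[:, None], 0.0)
        cum = np.cumsum(shares, axis=1)

        fractured = alive & (u_frac < p_any)
        site_of = np.full(n, -1, dtype=np.int64)
        if fractured.any():
            site_of[fractured] = (u_frac[fractured, None] < cum[fractured]).argmax(axis=1)

        qx = inputs.life_table.qx[age]
        qx_exc = min(1.0, qx * mult)
        fx_excess = fractured & np.isin(site_of, excess_idx)
        lingering = alive & (exc_left > 0)
        q_ind = np.where(fx_excess | lingering, qx_exc, qx)
        dies = alive & (u_death < q_ind)

        for s in SITES:
            j = site_idx[s]
            hit = fractured & (site_of == j)
            fx_counts[hit, j] += 1.0
            if schedule is not None:
                cost[hit] += schedule.site_cost(s, age, hip_curve) * d_cost

        ly_credit = np.where(dies, 0.5, 1.0)
        ly[alive] += ly_credit[alive]
        ly_disc[alive] += (ly_credit * d_eff)[alive]
        if schedule is not None and arm == "intervention":
            cost[alive] += schedule.supplement_annual_price * (ly_credit * d_cost)[alive]

        survivors = alive & ~dies
        hit_hip = fractured & (site_of == site_idx["hip"]) & survivors
        pending_next[hit_hip] = True
        for s in SITES:
            j = site_idx[s]
            history[survivors & fractured & (site_of == j), j] = True
        exc_next = np.maximum(exc_left - 1, 0)
        exc_next[fx_excess] = inputs.excess.duration
        exc_left = np.where(survivors, exc_next, 0)

        died |= dies & alive
        alive = survivors
        pending_hip_extra = pending_next

    scale = cohort.size / n

    def estimate(label: str, per_individual: np.ndarray) -> MicrosimEstimate:
        mean = float(per_individual.mean())
        se = float(per_individual.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
        return MicrosimEstimate(label=label, estimate=mean * cohort.size, se=se * cohort.size, n=n)

    out = {f"fractures_{s}": estimate(f"fractures_{s}", fx_counts[:, site_idx[s]]) for s in SITES}
    out["fractures_total"] = estimate("fractures_total", fx_counts.sum(axis=1))
    out["deaths"] = estimate("deaths", died.astype(float))
    out["life_years"] = estimate("life_years", ly)
    out["life_years_discounted"] = estimate("life_years_discounted", ly_disc)
    if schedule is not None:
        out["cost"] = estimate("cost", cost)
    # per-individual estimates are scaled by cohort size / n; SEs likewise
    return out
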