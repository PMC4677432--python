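"""Deterministic Markov cohort engine.

Each cohort is propagated in annual cycles as expected values (fractional
persons).  Alive states are the 16 subsets of fracture history over the four
sites, plus one absorbing Dead state.  Within a cycle, fracture comes first
(at most one index fracture per person-year, total probability capped, site
shares proportional), then mortality conditional on fracture status: persons
sustaining a hip or clinical vertebral fracture that year die with an
excess-multiplied background probability; everyone else with the background
probability.  Persons dying within a cycle are credited half a person-year.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Callable, Dict, FrozenSet, List, Optional, Tuple

import numpy as np
import pandas as pd

from .demography import Cohort, LifeTable
from .risk import SITES, RiskModifiers, adjusted_fracture_probability

#: total annual index-fracture probability is capped here to keep shares well defined
TOTAL_FRACTURE_CAP = 0.999

#: sites whose fracture carries excess mortality
EXCESS_MORTALITY_SITES = ("hip", "vertebral")

#: all 16 alive history classes, in a fixed deterministic order
ALIVE_CLASSES: Tuple[FrozenSet[str], ...] = tuple(
    frozenset(c)
    for r in range(len(SITES) + 1)
    for c in itertools.combinations(SITES, r)
)

DEAD = "dead"


@dataclass(frozen=True)
class ExcessMortality:
    """Excess mortality after hip/vertebral fracture.

    The background death probability is multiplied by
    ``1 + attributable_fraction * (multiplier - 1)`` in the fracture cycle and,
    optionally, for ``duration`` further cycles.
    """

    multiplier: float = 5.5
    duration: int = 0
    attributable_fraction: float = 1.0

    def adjusted_qx(self, qx: float) -> float:
        return min(1.0, qx * (1.0 + self.attributable_fraction * (self.multiplier - 1.0)))


StateKey = Tuple[FrozenSet[str], int]  # (history, remaining excess-mortality cycles)


@dataclass
class EngineInputs:
    """Everything cycle_step needs besides the occupancy itself."""

    site_base: Dict[str, Callable[[int], float]]
    modifiers: RiskModifiers
    life_table: LifeTable
    excess: ExcessMortality = field(default_factory=ExcessMortality)
    start_history: Dict[FrozenSet[str], float] = field(
        default_factory=lambda: {frozenset(): 1.0}
    )


@dataclass
class CycleFlows:
    fractures: Dict[str, float]
    fracture_survivors: Dict[str, float]
    deaths: float
    person_years: float


def cycle_step(
    occupancy: Dict[StateKey, float],
    dead: float,
    age: int,
    inputs: EngineInputs,
    arm: str,
) -> Tuple[Dict[StateKey, float], float, CycleFlows]:
    """Advance one annual cycle; returns (next occupancy, next dead, flows)."""
    for key, m in occupancy.items():
        if not np.isfinite(m) or m < 0:
            raise ValueError(f"occupancy for state {key} is negative or non-finite: {m}")
    qx = inputs.life_table.qx[age]
    qx_excess = inputs.excess.adjusted_qx(qx)

    nxt: Dict[StateKey, float] = {}
    fractures = {s: 0.0 for s in SITES}
    survivors = {s: 0.0 for s in SITES}
    deaths = 0.0
    person_years = 0.0

    for (history, exc_left), m in occupancy.items():
        if m == 0.0:
            continue
        p_site = {
            s: adjusted_fracture_probability(
                inputs.site_base[s](age), s, history, arm, inputs.modifiers
            )
            for s in SITES
        }
        total = sum(p_site.values())
        p_any = min(total, TOTAL_FRACTURE_CAP)
        shares = {s: (p_any * p_site[s] / total if total > 0 else 0.0) for s in SITES}

        # no-fracture branch: lingering excess mortality if still within duration
        q_nofx = qx_excess if exc_left > 0 else qx
        m_nofx = m * (1.0 - p_any)
        deaths += m_nofx * q_nofx
        person_years += m_nofx * ((1.0 - q_nofx) + 0.5 * q_nofx)
        key_nofx = (history, max(exc_left - 1, 0))
        nxt[key_nofx] = nxt.get(key_nofx, 0.0) + m_nofx * (1.0 - q_nofx)

        for s in SITES:
            m_s = m * shares[s]
            if m_s == 0.0:
                continue
            fractures[s] += m_s
            if s in EXCESS_MORTALITY_SITES:
                q_s = qx_excess
                exc_next = inputs.excess.duration
            else:
                q_s = qx_excess if exc_left > 0 else qx
                exc_next = max(exc_left - 1, 0)
            deaths += m_s * q_s
            person_years += m_s * ((1.0 - q_s) + 0.5 * q_s)
            surv = m_s * (1.0 - q_s)
            survivors[s] += surv
            key_s = (history | {s}, exc_next)
            nxt[key_s] = nxt.get(key_s, 0.0) + surv

    return nxt, dead + deaths, CycleFlows(fractures, survivors, deaths, person_years)


@dataclass
class CohortTrace:
    """Cycle-by-cycle occupancy and event flows of one cohort/arm run.

    ``occupancy`` has one row per cycle start (T + 1 rows, the last after the
    terminal cycle) over the alive classes, with Dead in the final column.
    ``fractures``/``fracture_survivors`` are (T, 4) arrays over SITES.
    """

    cohort: Optional[Cohort]
    arm: str
    ages: np.ndarray
    state_labels: List[str]
    occupancy: np.ndarray
    fractures: np.ndarray
    fracture_survivors: np.ndarray
    deaths: np.ndarray
    person_years: np.ndarray

    @property
    def n_cycles(self) -> int:
        return len(self.ages)

    @property
    def alive_start(self) -> np.ndarray:
        """Persons alive at the start of each cycle."""
        return self.occupancy[:-1, :-1].sum(axis=1)

    @property
    def initial_size(self) -> float:
        return float(self.occupancy[0].sum())

    def total_fractures(self) -> Dict[str, float]:
        out = {s: float(self.fractures[:, i].sum()) for i, s in enumerate(SITES)}
        out["total"] = float(self.fractures.sum())
        return out

    def total_deaths(self) -> float:
        return float(self.deaths.sum())

    def conservation_error(self) -> float:
        """Max relative deviation of (alive + dead) from the initial size."""
        totals = self.occupancy.sum(axis=1)
        scale = max(self.initial_size, 1.0)
        return float(np.max(np.abs(totals - self.initial_size)) / scale)

    def occupancy_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.occupancy, columns=self.state_labels)
        frame.insert(0, "cycle", np.arange(len(frame)))
        return frame

    def flows_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.fractures, columns=[f"fx_{s}" for s in SITES])
        for i, s in enumerate(SITES):
            frame[f"fx_{s}_survivors"] = self.fracture_survivors[:, i]
        frame["deaths"] = self.deaths
        frame["person_years"] = self.person_years
        frame.insert(0, "age", self.ages)
        frame.insert(0, "cycle", np.arange(len(frame)))
        return frame


def _state_label(history: FrozenSet[str], exc: int) -> str:
    name = "+".join(sorted(history)) if history else "no_fx"
    return name if exc == 0 else f"{name}|exc{exc}"


def run_cohort(cohort: Cohort, arm: str, inputs: EngineInputs, max_age: int) -> CohortTrace:
    """Project a cohort from its baseline age to the terminal age, one cycle per year."""
    if cohort.baseline_age >= max_age:
        raise ValueError("cohort baseline age must be below max_age")
    if inputs.life_table.max_age < max_age:
        raise ValueError("life table does not cover the projection horizon")
    for site in SITES:
        inputs.site_base[site](max_age)  # raises if curve coverage is missing

    ages = np.arange(cohort.baseline_age, max_age + 1)
    occupancy: Dict[StateKey, float] = {}
    for history, frac in inputs.start_history.items():
        occupancy[(frozenset(history), 0)] = cohort.size * frac
    dead = 0.0

    keys_seen = sorted(occupancy, key=lambda k: (sorted(k[0]), k[1]))
    occ_rows: List[Dict[StateKey, float]] = [dict(occupancy)]
    dead_rows = [dead]
    fractures = np.zeros((len(ages), len(SITES)))
    survivors = np.zeros((len(ages), len(SITES)))
    deaths = np.zeros(len(ages))
    person_years = np.zeros(len(ages))

    for t, age in enumerate(ages):
        occupancy, dead, flows = cycle_step(occupancy, dead, int(age), inputs, arm)
        occ_rows.append(dict(occupancy))
        dead_rows.append(dead)
        for i, s in enumerate(SITES):
            fractures[t, i] = flows.fractures[s]
            survivors[t, i] = flows.fracture_survivors[s]
        deaths[t] = flows.deaths
        person_years[t] = flows.person_years
        for key in occupancy:
            if key not in keys_seen:
                keys_seen.append(key)

    keys_seen = sorted(keys_seen, key=lambda k: (len(k[0]), sorted(k[0]), k[1]))
    occ = np.zeros((len(occ_rows), len(keys_seen) + 1))
    for r, row in enumerate(occ_rows):
        for c, key in enumerate(keys_seen):
            occ[r, c] = row.get(key, 0.0)
        occ[r, -1] = dead_rows[r]
    labels = [_state_label(h, e) for h, e in keys_seen] + [DEAD]

    return CohortTrace(
        cohort=cohort,
        arm=arm,
        ages=ages,
        state_labels=labels,
        occupancy=occ,
        fractures=fractures,
        fracture_survivors=survivors,
        deaths=deaths,
        person_years=person_years,
    )


def life_years(trace: CohortTrace, discount_rate: float) -> Tuple[float, float]:
    """(undiscounted, discounted) person-years alive over the projection.

    Persons alive through cycle t credit one year, persons dying within it
    half a year; cycle t is discounted by (1 + rate)^-t with t = 0 at baseline.
    """
    if discount_rate < 0:
        raise ValueError("discount rate must be non-negative")
    t = np.arange(trace.n_cycles)
    undiscounted = float(trace.person_years.sum())
    discounted = float((trace.person_years / (1.0 + discount_rate) ** t).sum())
    return undiscounted, discounted
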