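"""Demographic inputs: life tables, population cohorts and risk-stratum prevalence.

The model operates on closed national birth cohorts (no migration) observed at
baseline ages 50, 60, 70 and 80 for each sex.  Each cohort is split into three
baseline-risk strata: the general population, the population with densitometric
osteoporosis (BMD T-score <= -2.5) and the population with a prevalent hip or
vertebral fracture.  Background mortality enters as an age-indexed annual death
probability per sex; the synthetic stand-in for official national life tables
is a Gompertz-Makeham hazard with age origin 50.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from typing import Dict, List, Sequence, Tuple

import pandas as pd

SEXES = ("women", "men")
STRATA = ("general", "osteoporosis", "prevalent_fracture")
BASELINE_AGES = (50, 60, 70, 80)

#: tolerance on the sum of independently rounded printed prevalence fractions
PREVALENCE_SUM_TOL = 0.005


def round_half_away(x: float) -> int:
    """Round to the nearest integer, halves away from zero."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass(frozen=True)
class LifeTable:
    """Annual background death probabilities ``qx`` for one sex, ages 50..max_age.

    The terminal age is absorbing: ``qx(max_age) = 1`` so no survivor outlives
    the table.
    """

    sex: str
    max_age: int
    qx: Dict[int, float]

    def __post_init__(self) -> None:
        ages = sorted(self.qx)
        if ages != list(range(ages[0], self.max_age + 1)):
            raise ValueError("life table ages must form a contiguous range up to max_age")
        for age, q in self.qx.items():
            if not (0.0 <= q <= 1.0):
                raise ValueError(f"qx({age}) = {q} outside [0, 1]")
        if self.qx[self.max_age] != 1.0:
            raise ValueError("terminal age must be absorbing: qx(max_age) must equal 1")

    @property
    def min_age(self) -> int:
        return min(self.qx)

    def survival(self, from_age: int) -> Dict[int, float]:
        """Probability of being alive at the start of each age, given alive at from_age."""
        s = 1.0
        out = {from_age: 1.0}
        for age in range(from_age, self.max_age + 1):
            s *= 1.0 - self.qx[age]
            out[age + 1] = s
        return out

    def life_expectancy(self, from_age: int) -> float:
        """Expected remaining person-years with half-year credit in the death year.

        E = sum_t S_t * [(1 - q_t) + 0.5 * q_t] where S_t is survival to the
        start of year t.
        """
        s = 1.0
        total = 0.0
        for age in range(from_age, self.max_age + 1):
            q = self.qx[age]
            total += s * ((1.0 - q) + 0.5 * q)
            s *= 1.0 - q
        return total


def generate_life_table(
    makeham_a: float,
    gompertz_b: float,
    gompertz_c: float,
    max_age: int = 105,
    sex: str = "women",
) -> LifeTable:
    """Build a synthetic life table from a Gompertz-Makeham hazard.

    The hazard at integer age x (>= 50) is ``a + b * exp(c * (x - 50))``, and the
    annual death probability is ``1 - exp(-hazard)``.  The terminal age absorbs
    all survivors (qx = 1).
    """
    for name, value in (("makeham_a", makeham_a), ("gompertz_b", gompertz_b), ("gompertz_c", gompertz_c)):
        if value < 0:
            raise ValueError(f"{name} must be non-negative, got {value}")
    if max_age <= 50:
        raise ValueError("max_age must exceed 50")
    qx = {}
    for age in range(50, max_age):
        hazard = makeham_a + gompertz_b * math.exp(gompertz_c * (age - 50))
        qx[age] = 1.0 - math.exp(-hazard)
    qx[max_age] = 1.0
    return LifeTable(sex=sex, max_age=max_age, qx=qx)


@dataclass(frozen=True)
class PopulationProjection:
    """Head counts per (sex, baseline age) cohort."""

    entries: Dict[Tuple[str, int], int]

    def __post_init__(self) -> None:
        for key, n in self.entries.items():
            if n < 0 or n != int(n):
                raise ValueError(f"cohort size for {key} must be a non-negative integer")

    def total(self, sex: str, age: int) -> int:
        return self.entries[(sex, age)]


@dataclass(frozen=True)
class StratumPrevalence:
    """Baseline-risk stratum fractions per (sex, age): general / osteoporosis / prevalent fracture."""

    rows: Dict[Tuple[str, int], Dict[str, float]]

    def __post_init__(self) -> None:
        for key, row in self.rows.items():
            missing = set(STRATA) - set(row)
            if missing:
                raise ValueError(f"prevalence row {key} missing strata {sorted(missing)}")
            for stratum, frac in row.items():
                if not (0.0 <= frac <= 1.0):
                    raise ValueError(f"prevalence {stratum} for {key} = {frac} outside [0, 1]")
            if sum(row.values()) > 1.0 + PREVALENCE_SUM_TOL:
                raise ValueError(
                    f"prevalence fractions for {key} sum to {sum(row.values()):.4f} > 1 + {PREVALENCE_SUM_TOL}"
                )

    def fractions(self, sex: str, age: int) -> Dict[str, float]:
        return dict(self.rows[(sex, age)])


@dataclass(frozen=True)
class Cohort:
    """One sex x baseline-age x risk-stratum population slice."""

    sex: str
    baseline_age: int
    stratum: str
    size: int

    def __post_init__(self) -> None:
        if self.size < 0:
            raise ValueError("cohort size must be non-negative")
        if self.stratum not in STRATA:
            raise ValueError(f"unknown stratum {self.stratum!r}")
        if self.sex not in SEXES:
            raise ValueError(f"unknown sex {self.sex!r}")

    @property
    def cohort_id(self) -> str:
        return f"{self.sex}:{self.baseline_age}:{self.stratum}"


def build_cohorts(projection: PopulationProjection, prevalence: StratumPrevalence) -> List[Cohort]:
    """Stratify every projected cohort by its printed baseline-risk prevalences.

    Each stratum size is the nearest integer (half away from zero) of
    total x printed fraction; the general stratum uses its own printed fraction
    rather than the complement of the others, so the three strata may miss the
    printed total by a person or two of rounding slack.
    """
    cohorts: List[Cohort] = []
    for (sex, age), total in sorted(projection.entries.items()):
        if (sex, age) not in prevalence.rows:
            raise ValueError(f"no prevalence row for cohort ({sex}, {age})")
        fracs = prevalence.fractions(sex, age)
        for stratum in STRATA:
            size = round_half_away(total * fracs[stratum])
            cohorts.append(Cohort(sex=sex, baseline_age=age, stratum=stratum, size=size))
    return cohorts


def generate_hip_incidence_anchors(
    rate_at_50: float, doubling_time: float, anchor_ages: Sequence[int]
) -> List[Tuple[int, float]]:
    """Synthetic age anchors for annual hip-fracture probability.

    Exponential in age: the probability doubles every ``doubling_time`` years
    starting from ``rate_at_50`` at age 50, capped at 1.
    """
    if not (0.0 < rate_at_50 < 1.0):
        raise ValueError("rate_at_50 must lie in (0, 1)")
    if doubling_time <= 0:
        raise ValueError("doubling_time must be positive")
    if len(anchor_ages) == 0:
        raise ValueError("anchor_ages must not be empty")
    return [
        (int(age), min(1.0, rate_at_50 * 2.0 ** ((age - 50) / doubling_time)))
        for age in anchor_ages
    ]


def load_population_tables() -> Tuple[PopulationProjection, StratumPrevalence]:
    """Load the packaged reference cohort tables (Belgian 2015 birth cohorts)."""
    entries: Dict[Tuple[str, int], int] = {}
    rows: Dict[Tuple[str, int], Dict[str, float]] = {}
    for sex in SEXES:
        with resources.files("osteoecon.data").joinpath(f"cohorts_{sex}.tsv").open() as fh:
            table = pd.read_csv(fh, sep="\t")
        for _, rec in table.iterrows():
            key = (sex, int(rec["age"]))
            entries[key] = int(rec["total"])
            rows[key] = {
                "general": float(rec["general_pct"]),
                "osteoporosis": float(rec["osteoporosis_pct"]),
                "prevalent_fracture": float(rec["prevalent_fx_pct"]),
            }
    return PopulationProjection(entries=entries), StratumPrevalence(rows=rows)
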