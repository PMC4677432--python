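"""Age-, site-, stratum- and history-specific annual fracture probabilities.

Four index fracture sites are modelled: hip, clinical vertebral, wrist
(forearm) and "other".  Hip incidence is anchored on observed age points and
interpolated with an exponential (log-linear in age) regression; non-hip
incidence is derived from hip via banded site-to-hip ratios, the standard
device when only hip admissions are registered.  Risk modifiers act
multiplicatively on the annual probability: a same-site prior-fracture
relative risk, a baseline-stratum relative risk, and the supplementation
efficacy relative risk in the intervention arm.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, FrozenSet, List, Optional, Sequence, Tuple

import numpy as np

SITES = ("hip", "vertebral", "wrist", "other")
NONHIP_SITES = ("vertebral", "wrist", "other")

#: same-site relative risk of re-fracture after a prior fracture
DEFAULT_PRIOR_FX_RR = {"hip": 2.3, "vertebral": 4.4, "wrist": 3.3, "other": 1.9}
#: supplementation efficacy: 18% hip, 13% vertebral, 20% non-hip non-vertebral
DEFAULT_EFFICACY_RR = {"hip": 0.82, "vertebral": 0.87, "wrist": 0.80, "other": 0.80}


@dataclass(frozen=True)
class IncidenceCurve:
    """Log-linear-in-age annual first-event fracture probability for one site.

    ``probability(age) = min(exp(intercept + slope * age), 1)`` on the closed
    age domain.
    """

    sex: str
    site: str
    intercept: float
    slope: float
    domain: Tuple[int, int] = (50, 105)

    def probability(self, age: float) -> float:
        lo, hi = self.domain
        if not (lo <= age <= hi):
            raise ValueError(f"age {age} outside curve domain [{lo}, {hi}]")
        return min(1.0, float(np.exp(self.intercept + self.slope * age)))


def fit_exponential_curve(
    anchors: Sequence[Tuple[float, float]],
    sex: str = "women",
    site: str = "hip",
    domain: Tuple[int, int] = (50, 105),
) -> IncidenceCurve:
    """Exponential regression through (age, probability) anchors.

    Ordinary least squares of log(probability) on age; with two anchors the
    curve passes through them exactly.
    """
    if len(anchors) < 2:
        raise ValueError("exponential regression needs at least 2 anchors")
    ages = np.asarray([a for a, _ in anchors], dtype=float)
    probs = np.asarray([p for _, p in anchors], dtype=float)
    if np.any(probs <= 0) or np.any(probs >= 1):
        raise ValueError("anchor probabilities must lie in (0, 1) for the log transform")
    if len(np.unique(ages)) != len(ages):
        raise ValueError("anchor ages must be distinct")
    design = np.column_stack([np.ones_like(ages), ages])
    coef, *_ = np.linalg.lstsq(design, np.log(probs), rcond=None)
    return IncidenceCurve(sex=sex, site=site, intercept=float(coef[0]), slope=float(coef[1]), domain=domain)


@dataclass(frozen=True)
class HipRatioTable:
    """Banded ratios of non-hip site incidence to hip incidence.

    ``bands`` is a list of (age_lo, age_hi, {site: ratio}) with inclusive
    edges; every model age must fall in exactly one band.
    """

    bands: Tuple[Tuple[int, int, Dict[str, float]], ...]

    def __post_init__(self) -> None:
        for lo, hi, ratios in self.bands:
            if lo > hi:
                raise ValueError(f"band [{lo}, {hi}] is empty")
            for site, r in ratios.items():
                if site not in NONHIP_SITES:
                    raise ValueError(f"ratio given for unknown non-hip site {site!r}")
                if r < 0:
                    raise ValueError(f"ratio for {site} in band [{lo}, {hi}] is negative")

    def ratio(self, age: float, site: str) -> float:
        for lo, hi, ratios in self.bands:
            if lo <= age <= hi:
                return ratios[site]
        raise ValueError(f"no ratio band covers age {age}")


@dataclass(frozen=True)
class PiecewiseIncidenceCurve:
    """Incidence curve that is log-linear within each ratio band."""

    sex: str
    site: str
    segments: Tuple[Tuple[int, int, IncidenceCurve], ...]

    def probability(self, age: float) -> float:
        for lo, hi, curve in self.segments:
            if lo <= age <= hi:
                return curve.probability(age)
        raise ValueError(f"age {age} outside piecewise curve domain")

    @property
    def domain(self) -> Tuple[int, int]:
        return (self.segments[0][0], self.segments[-1][1])


def expand_to_nonhip(
    hip_curve: IncidenceCurve, ratios: HipRatioTable
) -> Dict[str, PiecewiseIncidenceCurve]:
    """Derive vertebral, wrist and "other" curves from hip via banded ratios.

    Within each band the derived points hip(age) x ratio are refit log-linearly;
    because the ratio is constant on the band the refit is exact and the result
    equals direct per-age multiplication (up to the cap at 1).
    """
    lo_dom, hi_dom = hip_curve.domain
    out: Dict[str, PiecewiseIncidenceCurve] = {}
    for site in NONHIP_SITES:
        segments: List[Tuple[int, int, IncidenceCurve]] = []
        for lo, hi, band_ratios in ratios.bands:
            seg_lo, seg_hi = max(lo, lo_dom), min(hi, hi_dom)
            if seg_lo > seg_hi:
                continue
            pts = []
            for age in range(seg_lo, seg_hi + 1):
                p = min(1.0, hip_curve.probability(age) * band_ratios[site])
                pts.append((age, p))
            if len(pts) == 1:  # single-age band: flat segment through the point
                age0, p0 = pts[0]
                curve = IncidenceCurve(
                    sex=hip_curve.sex, site=site,
                    intercept=float(np.log(max(p0, 1e-300))), slope=0.0,
                    domain=(seg_lo, seg_hi),
                )
            else:
                usable = [(a, p) for a, p in pts if 0.0 < p < 1.0]
                if len(usable) < 2:
                    # saturated band: flat at the cap
                    curve = IncidenceCurve(sex=hip_curve.sex, site=site,
                                           intercept=0.0, slope=0.0, domain=(seg_lo, seg_hi))
                else:
                    curve = fit_exponential_curve(usable, sex=hip_curve.sex, site=site,
                                                  domain=(seg_lo, seg_hi))
            segments.append((seg_lo, seg_hi, curve))
        covered = sorted(s[:2] for s in segments)
        age = lo_dom
        for lo, hi in covered:
            if lo > age:
                raise ValueError(f"no ratio band covers ages [{age}, {lo - 1}] for site {site}")
            age = hi + 1
        if age <= hi_dom:
            raise ValueError(f"no ratio band covers ages [{age}, {hi_dom}] for site {site}")
        out[site] = PiecewiseIncidenceCurve(sex=hip_curve.sex, site=site, segments=tuple(segments))
    return out


@dataclass(frozen=True)
class RiskModifiers:
    """Multiplicative relative risks acting on annual fracture probabilities."""

    prior_fx_rr: Dict[str, float] = field(default_factory=lambda: dict(DEFAULT_PRIOR_FX_RR))
    stratum_rr: Dict[str, Dict[str, float]] = field(
        default_factory=lambda: {
            "general": {s: 1.0 for s in SITES},
            "osteoporosis": {s: 2.0 for s in SITES},
            "prevalent_fracture": {s: 2.0 for s in SITES},
        }
    )
    efficacy_rr: Dict[str, float] = field(default_factory=lambda: dict(DEFAULT_EFFICACY_RR))

    def __post_init__(self) -> None:
        for name, table in (("prior_fx_rr", self.prior_fx_rr), ("efficacy_rr", self.efficacy_rr)):
            for site in SITES:
                if table.get(site, 0.0) <= 0:
                    raise ValueError(f"{name}[{site}] must be positive")
        for stratum, per_site in self.stratum_rr.items():
            for site, rr in per_site.items():
                if rr <= 0:
                    raise ValueError(f"stratum_rr[{stratum}][{site}] must be positive")


def expected_history_rr(
    site: str, history_split: Optional[Dict[str, float]], prior_fx_rr: Dict[str, float]
) -> float:
    """Mean same-site prior-fracture elevation over a starting-history mixture.

    ``history_split`` maps prior-fracture site -> fraction of the stratum that
    starts with that site in history (e.g. {"hip": 0.5, "vertebral": 0.5}).
    """
    if not history_split:
        return 1.0
    return sum(
        frac * (prior_fx_rr[site] if prior_site == site else 1.0)
        for prior_site, frac in history_split.items()
    )


def calibrate_stratum_incidence(
    population_curve,
    prevalence,
    modifiers: RiskModifiers,
    age: int,
    sex: str,
    site: str,
    pf_history_split: Optional[Dict[str, float]] = None,
) -> Dict[str, float]:
    """Split a population-average incidence into per-stratum baseline incidences.

    With stratum weights w and per-stratum effective relative risks RR, the
    general-stratum probability is p_pop / sum_s(w_s * RR_s); each stratum's
    baseline probability is p_gen times its stratum RR.  The prevalent-fracture
    stratum's starting-history elevation (same-site prior-fracture RRs) enters
    the mixture denominator but is NOT folded into its returned baseline, since
    the transition engine applies prior-fracture RRs from the history state.
    """
    weights = prevalence.fractions(sex, age)
    if all(w <= 0 for w in weights.values()):
        raise ValueError("mixture weights must include a positive entry")
    rr_op = modifiers.stratum_rr["osteoporosis"][site]
    rr_pf_base = modifiers.stratum_rr["prevalent_fracture"][site]
    rr_pf_eff = rr_pf_base * expected_history_rr(site, pf_history_split, modifiers.prior_fx_rr)
    denom = (
        weights["general"] * modifiers.stratum_rr["general"][site]
        + weights["osteoporosis"] * rr_op
        + weights["prevalent_fracture"] * rr_pf_eff
    )
    if denom <= 0:
        raise ValueError("calibration denominator must be positive")
    p_pop = population_curve.probability(age)
    p_gen = p_pop / denom
    return {
        "general": p_gen * modifiers.stratum_rr["general"][site],
        "osteoporosis": p_gen * rr_op,
        "prevalent_fracture": p_gen * rr_pf_base,
    }


def stratum_scaling_factor(
    prevalence,
    modifiers: RiskModifiers,
    baseline_age: int,
    sex: str,
    site: str,
    stratum: str,
    pf_history_split: Optional[Dict[str, float]] = None,
) -> float:
    """Multiplier turning the population curve into a stratum baseline curve.

    Calibrated at the cohort's baseline age and held constant over the
    projection, so the stratum mixture reproduces the population curve exactly
    at baseline and proportionally thereafter.
    """
    weights = prevalence.fractions(sex, baseline_age)
    rr_pf_eff = modifiers.stratum_rr["prevalent_fracture"][site] * expected_history_rr(
        site, pf_history_split, modifiers.prior_fx_rr
    )
    denom = (
        weights["general"] * modifiers.stratum_rr["general"][site]
        + weights["osteoporosis"] * modifiers.stratum_rr["osteoporosis"][site]
        + weights["prevalent_fracture"] * rr_pf_eff
    )
    if denom <= 0:
        raise ValueError("calibration denominator must be positive")
    return modifiers.stratum_rr[stratum][site] / denom


def adjusted_fracture_probability(
    base: float,
    site: str,
    history: FrozenSet[str],
    arm: str,
    modifiers: RiskModifiers,
) -> float:
    """Annual fracture probability after history and intervention adjustments.

    The stratum relative risk is already embedded in the stratum-specific base
    and is not reapplied.  A prior fracture at the same site multiplies the
    probability by that site's re-fracture RR; the intervention arm multiplies
    by the efficacy RR.  The result is capped at 1.
    """
    if not (0.0 <= base <= 1.0):
        raise ValueError(f"base probability {base} outside [0, 1]")
    if arm not in ("intervention", "control"):
        raise ValueError(f"unknown arm {arm!r}")
    p = base
    if site in history:
        p *= modifiers.prior_fx_rr[site]
    if arm == "intervention":
        p *= modifiers.efficacy_rr[site]
    return min(1.0, p)


def make_site_base_curves(
    population_curves: Dict[str, object],
    prevalence,
    modifiers: RiskModifiers,
    baseline_age: int,
    sex: str,
    stratum: str,
    pf_history_split: Optional[Dict[str, float]] = None,
) -> Dict[str, Callable[[int], float]]:
    """Per-site callables giving the stratum's baseline annual probability by age."""
    out: Dict[str, Callable[[int], float]] = {}
    for site in SITES:
        factor = stratum_scaling_factor(
            prevalence, modifiers, baseline_age, sex, site, stratum, pf_history_split
        )
        curve = population_curves[site]
        out[site] = (lambda c, f: (lambda age: min(1.0, c.probability(age) * f)))(curve, factor)
    return out
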