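"""Scenario configuration files: YAML schema, validation, round-trip dump.

A configuration file contains any subset of the keys of the fully-resolved
default configuration; omitted keys take their defaults, unknown keys are
rejected with their full key path.  ``load_config`` returns the resolved
bundle; ``dump_config`` writes it back so that load -> dump -> load is the
identity.
"""

from __future__ import annotations

import copy
import numbers
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Union

import yaml

from .demography import PREVALENCE_SUM_TOL, SEXES
from .risk import NONHIP_SITES, SITES
from .scenario import DEFAULT_CONFIG, Scenario, build_scenario


class ConfigError(ValueError):
    """Configuration rejected; the message names the offending key path."""


def _is_number(x) -> bool:
    return isinstance(x, numbers.Real) and not isinstance(x, bool)


def _check_leaf(path: str, value, default) -> None:
    if isinstance(default, bool):
        if not isinstance(value, bool):
            raise ConfigError(f"{path}: expected a boolean, got {value!r}")
    elif isinstance(default, numbers.Real):
        if not _is_number(value):
            raise ConfigError(f"{path}: expected a number, got {value!r}")
    elif isinstance(default, str):
        if not isinstance(value, str):
            raise ConfigError(f"{path}: expected a string, got {value!r}")


def _merge(path: str, default, override):
    """Deep-merge ``override`` onto ``default``, rejecting unknown keys."""
    if path == "config.demography.population":
        # polymorphic: the string "packaged" or an inline {women, men} table
        if not isinstance(override, (str, dict)):
            raise ConfigError(f"{path}: expected 'packaged' or a mapping, got {override!r}")
        return copy.deepcopy(override)
    if isinstance(default, dict):
        if not isinstance(override, dict):
            raise ConfigError(f"{path}: expected a mapping, got {override!r}")
        out = {}
        for key in override:
            if key not in default:
                raise ConfigError(f"{path}.{key}: unknown configuration key")
        for key, dval in default.items():
            if key in override:
                out[key] = _merge(f"{path}.{key}", dval, override[key])
            else:
                out[key] = copy.deepcopy(dval)
        return out
    if isinstance(default, list):
        if not isinstance(override, list):
            raise ConfigError(f"{path}: expected a list, got {override!r}")
        return copy.deepcopy(override)
    _check_leaf(path, override, default)
    return override


def _validate_resolved(cfg: Dict) -> None:
    demo, riskc, econ, runc = cfg["demography"], cfg["risk"], cfg["economics"], cfg["run"]
    if demo["max_age"] <= 81:
        raise ConfigError("demography.max_age: must exceed the oldest baseline age (80)")
    pop = demo["population"]
    if pop != "packaged":
        if not isinstance(pop, dict) or set(pop) - set(SEXES):
            raise ConfigError("demography.population: must be 'packaged' or a {women, men} mapping")
        for sex in SEXES:
            for i, rec in enumerate(pop.get(sex, [])):
                where = f"demography.population.{sex}[{i}]"
                needed = {"age", "total", "general_pct", "osteoporosis_pct", "prevalent_fx_pct"}
                if set(rec) != needed:
                    raise ConfigError(f"{where}: requires exactly the keys {sorted(needed)}")
                total = rec["general_pct"] + rec["osteoporosis_pct"] + rec["prevalent_fx_pct"]
                if total > 1.0 + PREVALENCE_SUM_TOL:
                    raise ConfigError(
                        f"{where}: prevalence fractions sum to {total:.4f} > 1 + {PREVALENCE_SUM_TOL}"
                    )
    for sex in SEXES:
        hi = demo["hip_incidence"][sex]
        if not (0.0 < hi["rate_at_50"] < 1.0):
            raise ConfigError(f"demography.hip_incidence.{sex}.rate_at_50: must lie in (0, 1)")
        if hi["doubling_time"] <= 0:
            raise ConfigError(f"demography.hip_incidence.{sex}.doubling_time: must be positive")
        for i, band in enumerate(riskc["ratio_bands"][sex]):
            where = f"risk.ratio_bands.{sex}[{i}]"
            for key in ("from_age", "to_age", *NONHIP_SITES):
                if key not in band:
                    raise ConfigError(f"{where}.{key}: required")
            if band["from_age"] > band["to_age"]:
                raise ConfigError(f"{where}: from_age exceeds to_age")
    for site in SITES:
        if riskc["efficacy_rr"][site] <= 0:
            raise ConfigError(f"risk.efficacy_rr.{site}: must be positive")
        if riskc["prior_fracture_rr"][site] <= 0:
            raise ConfigError(f"risk.prior_fracture_rr.{site}: must be positive")
    split = riskc["prevalent_fracture_split"]
    if abs(sum(split.values()) - 1.0) > 1e-9:
        raise ConfigError("risk.prevalent_fracture_split: fractions must sum to 1")
    if any(p < 0 for p in econ["supplement_prices"]):
        raise ConfigError("economics.supplement_prices: prices must be non-negative")
    if econ["discount_rate_costs"] < 0 or econ["discount_rate_effects"] < 0:
        raise ConfigError("economics.discount_rate_*: rates must be non-negative")
    if runc["excess_mortality_multiplier"] < 1:
        raise ConfigError("run.excess_mortality_multiplier: must be >= 1")
    if not 0 <= runc["excess_attributable_fraction"] <= 1:
        raise ConfigError("run.excess_attributable_fraction: must lie in [0, 1]")


@dataclass
class ScenarioConfig:
    """A fully-resolved, validated configuration bundle."""

    data: Dict

    def build(self) -> Scenario:
        return build_scenario(self.data)

    def with_seed(self, seed: int) -> "ScenarioConfig":
        out = copy.deepcopy(self.data)
        out["run"]["seed"] = int(seed)
        return ScenarioConfig(data=out)


def resolve_config(partial: Dict) -> ScenarioConfig:
    """Merge a partial configuration mapping over the defaults and validate."""
    resolved = _merge("config", DEFAULT_CONFIG, partial if partial is not None else {})
    _validate_resolved(resolved)
    return ScenarioConfig(data=resolved)


def load_config(path: Union[str, Path]) -> ScenarioConfig:
    """Load, resolve and validate a YAML scenario configuration file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError("config: top level must be a mapping")
    return resolve_config(raw)


def dump_config(config: ScenarioConfig, path: Union[str, Path]) -> None:
    """Write the fully-resolved configuration; load(dump(c)) == c."""
    with open(path, "w") as fh:
        yaml.safe_dump(config.data, fh, sort_keys=False)


def default_config() -> ScenarioConfig:
    return resolve_config({})
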