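"""End-to-end runs: all cohorts x arms x prices, table export, provenance.

Output layout mirrors the published table style: one delimited impact table
per sex and supplement price (rows stratum x metric, columns baseline age),
plus a full-precision per-cohort comparison table, per-cohort traces, and a
provenance summary from which any table can be regenerated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd
import yaml

from .config import ScenarioConfig
from .demography import BASELINE_AGES, SEXES, STRATA, Cohort
from .economics import arm_costs
from .engine import CohortTrace, run_cohort
from .outcomes import AggregateResult, ComparisonResult, aggregate, price_sweep
from .scenario import Scenario

log = logging.getLogger("osteoecon")

ARMS = ("control", "intervention")


def parse_cohort_selector(selector: str) -> Tuple[str, int, str]:
    """Parse a ``sex:age:stratum`` selector such as ``women:70:general``."""
    try:
        sex, age, stratum = selector.split(":")
        return sex, int(age), stratum
    except ValueError as err:
        raise ValueError(f"bad cohort selector {selector!r}; expected sex:age:stratum") from err


@dataclass
class RunResult:
    """Everything one pipeline run produced, in memory."""

    scenario: Scenario
    traces: Dict[Tuple[str, str], CohortTrace]  # (cohort_id, arm) -> trace
    comparisons: List[ComparisonResult]  # at the scenario's base price
    by_price: Dict[float, List[ComparisonResult]] = field(default_factory=dict)
    aggregates: Dict[float, AggregateResult] = field(default_factory=dict)

    def comparison_frame(self) -> pd.DataFrame:
        return pd.DataFrame([r.as_row() for r in self.comparisons])


def run_cohort_pair(
    scenario: Scenario, cohort: Cohort
) -> Tuple[CohortTrace, CohortTrace]:
    """Run control and intervention arms of one cohort on identical inputs."""
    inputs = scenario.engine_inputs(cohort)
    control = run_cohort(cohort, "control", inputs, scenario.max_age)
    intervention = run_cohort(cohort, "intervention", inputs, scenario.max_age)
    return control, intervention


def run_scenario(
    scenario: Scenario,
    cohort_selector: Optional[str] = None,
    prices: Optional[Sequence[float]] = None,
) -> RunResult:
    """Project every requested cohort under both arms and sweep the prices."""
    prices = list(prices) if prices is not None else list(scenario.prices)
    cohorts = scenario.cohorts()
    if cohort_selector is not None and cohort_selector != "all":
        sex, age, stratum = parse_cohort_selector(cohort_selector)
        cohorts = [
            c for c in cohorts if (c.sex, c.baseline_age, c.stratum) == (sex, age, stratum)
        ]
        if not cohorts:
            raise ValueError(f"cohort selector {cohort_selector!r} matches no cohort")

    traces: Dict[Tuple[str, str], CohortTrace] = {}
    comparisons: List[ComparisonResult] = []
    per_price: Dict[float, List[ComparisonResult]] = {p: [] for p in prices}
    for cohort in cohorts:
        log.info("projecting cohort %s", cohort.cohort_id)
        control, intervention = run_cohort_pair(scenario, cohort)
        traces[(cohort.cohort_id, "control")] = control
        traces[(cohort.cohort_id, "intervention")] = intervention
        swept = price_sweep(
            intervention,
            control,
            scenario.schedule,
            prices,
            arm_costs,
            headline_discounted=scenario.headline_discounted,
        )
        for res in swept:
            per_price[res.supplement_price].append(res)
        base_price = scenario.schedule.supplement_annual_price
        base = [r for r in swept if r.supplement_price == base_price]
        comparisons.append(base[0] if base else swept[0])

    result = RunResult(
        scenario=scenario, traces=traces, comparisons=comparisons, by_price=per_price
    )
    for price, results in per_price.items():
        if results:
            result.aggregates[price] = aggregate(results)
    return result


def _fmt_money(x) -> str:
    return f"{x:.0f}" if isinstance(x, (int, float)) else str(x)


def impact_table(results: Sequence[ComparisonResult], sex: str) -> pd.DataFrame:
    """Published-style impact table: rows stratum x metric, columns baseline age."""
    cols = [str(a) for a in BASELINE_AGES]
    rows = []
    index = []
    by_key = {r.cohort_id: r for r in results if r.cohort_id.startswith(sex + ":")}
    metrics = [
        ("fractures_avoided", lambda r: f"{r.fractures_avoided['total']:.0f}"),
        ("lyg", lambda r: f"{r.lyg:.1f}"),
        ("cost_per_fracture_avoided", lambda r: f"{r.cost_per_fracture_avoided:.0f}"),
        ("cost_per_lyg", lambda r: f"{r.cost_per_lyg:.0f}"),
    ]
    for stratum in STRATA:
        for metric, fmt in metrics:
            row = {}
            for age in BASELINE_AGES:
                r = by_key.get(f"{sex}:{age}:{stratum}")
                row[str(age)] = fmt(r) if r is not None else ""
            rows.append(row)
            index.append(f"{stratum}:{metric}")
    return pd.DataFrame(rows, index=pd.Index(index, name="stratum:metric"), columns=cols)


def write_outputs(result: RunResult, output_dir) -> List[Path]:
    """Write impact tables, the comparison table, traces and provenance."""
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: List[Path] = []

    all_results = {p: rows for p, rows in result.by_price.items() if rows}
    for price, rows in all_results.items():
        for sex in SEXES:
            if not any(r.cohort_id.startswith(sex + ":") for r in rows):
                continue
            path = out / f"impact_{sex}_eur{price:.0f}.tsv"
            impact_table(rows, sex).to_csv(path, sep="\t")
            written.append(path)

    comp_path = out / "comparisons.tsv"
    frames = []
    for price, rows in all_results.items():
        frames.append(pd.DataFrame([r.as_row() for r in rows]))
    if frames:
        pd.concat(frames, ignore_index=True).to_csv(comp_path, sep="\t", index=False)
        written.append(comp_path)

    traces_dir = out / "traces"
    traces_dir.mkdir(exist_ok=True)
    for (cohort_id, arm), trace in result.traces.items():
        stem = cohort_id.replace(":", "_")
        occ = traces_dir / f"{stem}_{arm}_occupancy.tsv"
        flows = traces_dir / f"{stem}_{arm}_flows.tsv"
        trace.occupancy_frame().to_csv(occ, sep="\t", index=False)
        trace.flows_frame().to_csv(flows, sep="\t", index=False)
        written.extend([occ, flows])

    agg_rows = []
    for price, agg in result.aggregates.items():
        for sex, vals in agg.by_sex.items():
            agg_rows.append({"price": price, "sex": sex, **vals})
        agg_rows.append({"price": price, "sex": "all", **agg.overall})
    if agg_rows:
        agg_path = out / "aggregates.tsv"
        pd.DataFrame(agg_rows).to_csv(agg_path, sep="\t", index=False)
        written.append(agg_path)

    from . import __version__

    summary = {
        "package_version": __version__,
        "seed": result.scenario.seed,
        "config": result.scenario.config,
    }
    summary_path = out / "run_summary.yaml"
    with open(summary_path, "w") as fh:
        yaml.safe_dump(summary, fh, sort_keys=False)
    written.append(summary_path)
    return written


def run_pipeline(
    config: ScenarioConfig, output_dir, cohort_selector: Optional[str] = None
) -> List[Path]:
    """Build the scenario, run everything it requests, write all outputs."""
    scenario = config.build()
    selector = cohort_selector or (
        config.data["run"]["cohorts"] if config.data["run"]["cohorts"] != "all" else None
    )
    result = run_scenario(scenario, cohort_selector=selector)
    return write_outputs(result, output_dir)
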