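# osteoecon

A Markov cohort model of the population health and economic impact of daily
calcium/vitamin-D supplementation through fortified dairy products on
osteoporotic fractures, written for health economists and epidemiologists who
want a transparent, fully testable implementation of this class of
cost-effectiveness analysis.

## The model

Closed national age cohorts (women and men, baseline ages 50, 60, 70 and 80)
are each split into three baseline-risk strata — general population,
densitometric osteoporosis (BMD T-score ≤ −2.5), and prevalent hip or
vertebral fracture — using printed national head counts and prevalences that
ship with the package. Every cohort is projected in annual cycles over its
remaining lifetime through a state space of fracture histories (all subsets of
{hip, clinical vertebral, wrist, other}) plus an absorbing death state:

- Annual fracture probabilities per site are exponential (log-linear) in age.
  Hip incidence is fitted through observed anchors; non-hip incidence is
  derived through age-banded site-to-hip ratios. Stratum-specific baselines
  are calibrated so the strata recompose the population average at baseline.
- Multiplicative relative risks modify the annual probability: same-site
  prior-fracture RRs (hip 2.3, vertebral 4.4, wrist 3.3, other 1.9), stratum
  RRs, and in the intervention arm lifetime supplementation efficacy
  (RR 0.82 hip, 0.87 vertebral, 0.80 non-hip non-vertebral).
- Each year every individual faces age- and sex-specific background mortality
  q(x); the death probability is multiplied by 5.5 in the year of a hip or
  vertebral fracture. Persons dying within a cycle are credited half a
  person-year.
- Costs (payer perspective, direct medical only) cover acute fracture costs
  interpolated in age by power or polynomial regression, extra costs in the
  year after hip fracture, and the supplement price (€250/person-year,
  tested at €150–€350). Costs and effects are discounted at 3 %/year.

Comparing the supplementation arm against no intervention yields, per cohort:
fractures avoided, life-years gained (LYG), incremental cost, cost per
fracture avoided, and cost per LYG (the ICER). A fully independent
individual-level microsimulation of the same transition contract serves as a
Monte-Carlo validation oracle for the deterministic engine.

National mortality, hip incidence and cost data are not redistributable, so
the reference scenario substitutes parametric stand-ins (Gompertz–Makeham
mortality, exponential hip incidence, smooth cost anchors) that are seeded and
reproducible; the printed cohort tables are packaged verbatim.

## Worked example

```sh
python examples/04_cost_effectiveness_tables.py
```

prints, for women at the base supplement price (seed 1):

```
                                                  50      60      70      80
stratum:metric
general:fractures_avoided                      24542   15036    6977    2159
general:cost_per_fracture_avoided              13889   12926   11477   10157
general:cost_per_lyg                           57659   37439   22231   12978
osteoporosis:cost_per_lyg                      27370   16110    8246    3988
prevalent_fracture:cost_per_lyg                21884   11706    5022    1709
```

Columns are baseline ages. Reading down a column, the cost of buying one
avoided fracture (or one life-year) falls from the general population to the
high-risk strata; reading across a row it falls with baseline age — prevention
is cheapest where fracture risk is highest. The other examples cover cohort
stratification, the synthetic life tables and incidence curves, a single
cohort projection, the price sweep (cost per LYG is exactly affine in the
supplement price), and the microsimulation cross-check.

A thin CLI wraps the same pipeline:

```sh
osteoecon run --out results/ --seed 1          # all cohorts, all prices
osteoecon oracle --cohort women:70:general     # Monte-Carlo estimates
osteoecon fixtures --out fixtures/             # emit the packaged cohort tables
osteoecon validate --config scenario.yaml      # schema-check a scenario file
```

All parameters live in one YAML scenario file (any subset of keys; the rest
take reference defaults) and every run writes a `run_summary.yaml` from which
its tables can be regenerated exactly.

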