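# Methods

## Model structure

The model is a deterministic Markov cohort (expected-value) projection with
annual cycles and a lifetime horizon. Alive states are the 16 subsets of
fracture history over the four index sites (hip, clinical vertebral, wrist,
other); one absorbing Dead state closes the space. History sets only grow, so
"prior fracture at site s" is read directly off the state. Occupancy is
fractional (persons are expected values); stochasticity lives exclusively in
the validation microsimulation.

Within a cycle the event order is: fracture first, then death conditional on
fracture status. This ordering lets the excess-mortality multiplier act on
exactly the subpopulation that fractured that year. At most one index
fracture can occur per person-year: the total fracture probability is
`P = min(Σ_s p_s, 0.999)` with site shares proportional to the per-site
probabilities. The cap keeps shares well defined when site probabilities are
extreme; at realistic incidence levels it never binds. Survivors who
fractured at site s move to the history class with s added; fracture counts
are recorded as flows whether or not the person survives the cycle.

There is no half-cycle correction on state occupancy; instead, persons dying
within a cycle are credited half a person-year (the standard half-cycle death
credit). With zero incidence this makes model life expectancy equal the
life-table closed form `Σ_t S_t·[(1−q_t) + q_t/2]` to numerical precision,
which the tests verify at 1e-9.

## Fracture risk

Hip incidence is anchored at observed (age, probability) points and
interpolated by exponential regression — ordinary least squares of
log-probability on age — the standard device for sparse age-specific
incidence. Non-hip incidence is hip incidence times an age-banded
site-to-hip ratio; within each band the derived points are refit
log-linearly, which is exact because the ratio is constant on the band. Band
edges and ratios are configuration.

Stratum calibration preserves the population average: with stratum weights w
and effective relative risks RR, the general-stratum probability is
`p_pop / Σ_s w_s·RR_s`, and each stratum's baseline is that value times its
stratum RR. The prevalent-fracture stratum's starting history (default 50 %
hip, 50 % vertebral) enters the mixture denominator through the expected
same-site prior-fracture RR, but is *not* folded into the stratum baseline —
the engine applies prior-fracture RRs from the history state, so folding it
in would double-count. Calibration is done once at the cohort's baseline age
and the resulting scaling factor is held constant over the projection.

Risk modifiers are multiplicative on the annual probability and capped at 1:
same-site prior-fracture RRs (hip 2.3, vertebral 4.4, wrist 3.3, other 1.9 —
cross-site elevation is deliberately not modelled), stratum RRs, and in the
intervention arm the efficacy RRs (0.82 hip, 0.87 vertebral, 0.80 wrist and
other). Efficacy applies from the first cycle for the remaining lifetime with
full adherence and no waning. The 0.80 figure is a pooled non-hip
non-vertebral effect; applying it to wrist and "other" separately is an
assumption, flagged here.

The osteoporosis stratum's baseline RR (2.0 on every site) is a required
input, not an observed quantity. The prevalent-fracture stratum also carries
a stratum RR of 2.0 *in addition to* its starting history, because prevalent
hip/vertebral fracture patients are drawn from the osteoporotic population;
with history-only elevation the stratum's overall risk (≈1.5× general) would
fall below the osteoporosis stratum's, inverting the expected risk gradient.
With both components its effective elevation is ≈3× general, and the model
reproduces the canonical ordering of cost-effectiveness ratios
(prevalent fracture < osteoporosis < general at every age).

## Mortality

Background mortality is an age- and sex-indexed annual death probability with
an absorbing terminal age (default 105, configurable). In the year of a hip
or clinical vertebral fracture the death probability becomes
`min(1, q·(1 + f·(m − 1)))` with multiplier m = 5.5 and attributable fraction
f = 1 by default; wrist and other fractures carry no excess mortality. The
duration of the excess is not an established quantity; the default applies it
in the fracture cycle only, with a configurable extension of N further cycles
(implemented by augmenting alive states with a decrementing counter, so the
default keeps the 17-state space).

## Economics

Only direct medical costs from the payer perspective: acute fracture costs
(age-interpolated by a power law on the log-log scale or a quadratic, per
configuration), extra costs in the year following a hip fracture applied at
t+1 to fracture survivors (configurably folded into the acute cost), non-hip
costs as fixed fractions of the acute hip cost with no long-term component,
and the supplement price times person-years alive in the intervention arm. A
long-term annual hip cost parameter exists and defaults to 0. Costs and
effects are discounted at independently configurable rates, both 3 %/year by
default, with t = 0 at baseline. All configured costs are assumed to be in a
single currency-year; no price-index adjustment is performed.

Headline life-years gained are discounted at the effects rate by default
(configurable toggle), and the cost-per-LYG uses the headline convention.
Ratios with non-positive denominators are typed outcomes (no_effect,
dominated, cost_saving), never sentinel numbers.

## Synthetic reference conditions

The cohort head counts and stratum prevalences are packaged printed values.
The remaining inputs are national data that cannot be redistributed, so the
reference scenario uses parametric stand-ins chosen once to be demographically
plausible for a western-European population:

- Mortality: Gompertz–Makeham hazard `a + b·exp(c·(age−50))`, women
  a = 5e-4, b = 2e-3, c = 0.10 (life expectancy 34.4 y at 50, q(80) ≈ 4.0 %),
  men a = 1.2e-3, b = 3.5e-3, c = 0.098 (29.4 y at 50, q(80) ≈ 6.5 %).
- Hip incidence: 0.05 % at 50 doubling every 6 y (women); 0.03 % doubling
  every 7 y (men); anchors at ages 50–90.
- Site-to-hip ratios in three bands (50–64, 65–79, 80+), falling with age so
  wrist/other dominate younger ages and hip the oldest — the familiar
  Scandinavian ratio pattern.
- Hip acute cost anchors rising from €8,000 at 50 to €12,500 at 90 (power
  family); €6,000 first-year extra; non-hip costs 60 % (vertebral), 20 %
  (wrist), 30 % (other) of acute hip.

The scenario seed applies a small multiplicative log-normal jitter
(σ = 0.03) to the incidence and cost anchors, so different seeds give
distinct but structurally identical conditions while the printed cohort
tables stay fixed. Because the stand-ins are synthetic, the model's absolute
population totals are scenario-specific; what carries over to real data are
the structural results the tests pin down (conservation, null equivalence,
price affinity, the life-table limit, oracle agreement, and the
age/risk gradients of the cost-effectiveness ratios), not the totals
themselves.

## Validation microsimulation

The oracle simulates individuals through the identical annual contract —
same probabilities, same ordering, same cost rules — with independent
transition code (the two implementations share only parameter parsing).
Random draws come from a counter-based Philox stream keyed on (seed, cycle)
and indexed by individual, so results are independent of iteration order and
reproducible bit-for-bit. Estimates are scaled to the cohort head count with
standard errors from the per-individual sample variance; the engine is
required to sit within 4 SE of the oracle at n = 20,000 on fractures (total
and per site), deaths, life-years and costs. Over the lifetime horizon
everyone dies, so the deaths metric is degenerate (SE 0) and is compared with
a float tolerance.

## Numerical choices and problem sizes

- Stratum head counts use round-half-away-from-zero of total × printed
  fraction, which reproduces every printed table cell; the general stratum
  uses its own printed percentage rather than the complement, accepting ±2
  persons of reconciliation slack from independent rounding.
- Person conservation (alive + dead = initial size) is enforced to 1e-9
  relative error at every cycle; in practice it holds to ~1e-15.
- Exponential and power fits go through ordinary least squares on the log
  scale (numpy lstsq); with two noise-free anchors they are exact.
- The default test and acceptance runs project all 24 cohorts × 2 arms over
  the full horizon (a fraction of a second) and use 20,000 microsimulation
  individuals (well under a minute), sizes at which Monte-Carlo error is
  small relative to the 4-SE acceptance band.

## Known limitations

Cohorts are closed (no migration, no calendar-time incidence trends);
re-fracture within a cycle is excluded by the one-event-per-year contract;
adherence is perfect; quality-of-life weights, societal costs and co-benefits
of supplementation are out of scope; and the stratum baseline RRs are
assumptions exposed as configuration, not estimates.
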