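"""Supplement price sensitivity: EUR 150 / 250 / 350 per person-year.

The traces are computed once per arm; only the supplement cost term changes,
so the cost-per-LYG is exactly affine in the price.
"""

import osteoecon as oe
from osteoecon.economics import arm_costs
from osteoecon.pipeline import run_cohort_pair

scenario = oe.make_reference_scenario(seed=1)
cohort = next(c for c in scenario.cohorts() if c.cohort_id == "women:70:general")
control, intervention = run_cohort_pair(scenario, cohort)

sweep = oe.price_sweep(intervention, control, scenario.schedule,
                       [150.0, 250.0, 350.0], arm_costs)
print(f"cohort {cohort.cohort_id}")
print(f"{'price':>8s} {'cost/fracture avoided':>22s} {'cost/LYG':>12s}")
for res in sweep:
    print(f"{res.supplement_price:>8.0f} {res.cost_per_fracture_avoided:>22.0f} "
          f"{res.cost_per_lyg:>12.0f}")

v = [r.cost_per_lyg.value for r in sweep]
print(f"\nequal price steps give equal cost-per-LYG steps: "
      f"{v[1] - v[0]:,.2f} vs {v[2] - v[1]:,.2f} EUR/LYG")
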