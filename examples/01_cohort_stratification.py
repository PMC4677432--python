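"""Stratify the packaged national age cohorts by baseline fracture risk.

Loads the reference cohort tables (head counts and prevalence of osteoporosis
and prior hip/vertebral fracture for women and men aged 50/60/70/80) and
splits each cohort into its three risk strata.
"""

import osteoecon as oe

projection, prevalence = oe.load_population_tables()
cohorts = oe.build_cohorts(projection, prevalence)

print(f"{'cohort':32s} {'persons':>10s}")
for cohort in cohorts:
    print(f"{cohort.cohort_id:32s} {cohort.size:>10,d}")

total = sum(c.size for c in cohorts)
print(f"\n{len(cohorts)} strata over {total:,d} persons.")
print("Each row is the head count entering the model in that sex/age/risk stratum;")
print("stratum sizes are the printed population totals times the printed prevalences.")
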