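"""Per-facility refits: one model per dividing-strip configuration.

The default plan mirrors the field study's per-facility tables: each
stratum has its own variable set, local reference levels (e.g. 3-vs-2 motor
lanes within the barriers stratum) and its own set of random coefficients.
Strata below the minimum size are skipped with a log entry.
"""

import lanelogit as ll

covariates = ll.sample_covariates(ll.default_scheme(), 8_000, seed=5)
truth = ll.TrueModel(
    mu={"intercept": -1.2, "gender:male vs female": 0.6,
        "bike_type:e_scooter vs c_bike": 1.8},
    seed=5,
)
dataset = ll.simulate_outcomes(covariates, truth)

plan = ll.default_plan(min_size=400)
strata = ll.subset_by_facility(dataset.observations, plan)
print("stratum sizes:", {k: v.n for k, v in strata.items()})

fits = ll.fit_stratified(
    strata, plan, config=ll.MCMCConfig(chains=2, iterations=1_500, burnin=700, seed=50)
)
for label, fit in fits.items():
    if fit.draws is None:
        print(f"\n{label}: skipped ({fit.skipped})")
        continue
    row = fit.summary[fit.summary.parameter == "gender:male vs female"].iloc[0]
    print(f"\n{label} (n={fit.n}): gender OR {row.odds_ratio:.3f} "
          f"(log-odds mean 95% CI {row['q2.5']:.3f} to {row['q97.5']:.3f})")
# The generating gender effect is the same 0.6 everywhere, so each
# stratum's interval should cover exp-scale ~1.82; with field data the
# strata genuinely differ, which is the point of the stratified refits.
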