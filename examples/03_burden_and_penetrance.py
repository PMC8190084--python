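"""Carrier burden regression and penetrance with exact intervals.

Simulates a cohort, estimates the carrier effect on LDL by covariate-adjusted
OLS and the diabetes odds ratio by Firth-penalized logistic regression, then
computes penetrance (fraction of carriers crossing the clinical threshold)
with Clopper-Pearson 95% intervals.
"""

import numpy as np

from penexome import (
    ConditionSpec,
    SimulationConfig,
    clopper_pearson,
    dichotomize,
    fit_firth_logistic,
    fit_linear_burden,
    harmonize_cohort,
    simulate_cohort,
)

cfg = SimulationConfig(
    n_individuals=20_000,
    seed=11,
    conditions=(
        ConditionSpec("high_ldl", ("LDLR", "APOB"), "ldl", 80 / 20_000, 54.2),
        ConditionSpec("mody", ("GCK", "HNF1A"), "diabetes", 20 / 20_000, float(np.log(21))),
    ),
)
sim = simulate_cohort(cfg)
cohort = harmonize_cohort(sim.cohort)  # inverts the statin masking
covs = cohort[["age", "sex", "pc1", "pc2"]].astype(float)

lin = fit_linear_burden(cohort["carrier_high_ldl"], cohort["ldl"], covs)
print(f"high-LDL burden: beta {lin.beta:.1f} mg/dL (se {lin.se:.1f}), "
      f"p {lin.p_value:.2g}, {lin.n_carriers} carriers")
print("  planted effect was 54.2 mg/dL; the estimate should land within ~2 se.")

fir = fit_firth_logistic(cohort["carrier_mody"], cohort["diabetes"].astype(float),
                         cohort[["age", "sex"]].astype(float))
print(f"\nMODY burden: OR {fir.odds_ratio:.1f} "
      f"(95% profile CI {fir.or_ci[0]:.1f}-{fir.or_ci[1]:.1f}), p {fir.p_value:.2g}")
print("  planted OR was 21; Firth's penalty keeps this finite even if all "
      "carriers happened to be cases.")

case = dichotomize(cohort, "high_ldl")  # adjusted LDL >= 190 mg/dL
carr = cohort["carrier_high_ldl"]
k = int(case[carr].sum())
n = int(carr.sum())
lo, hi = clopper_pearson(k, n)
print(f"\nhigh-LDL penetrance at the 190 mg/dL cut-off: {k}/{n} = {k / n:.1%} "
      f"(95% CI {lo:.1%}-{hi:.1%})")
print("  incomplete penetrance is expected: the threshold sits ~1.6 sd above "
      "the carrier trait mean.")
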