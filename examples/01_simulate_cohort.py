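"""Simulate a small biobank-style cohort and look at carrier effects.

Draws 20,000 individuals with rare monogenic carriers (high/low LDL, high
HDL, high TG, obesity, MODY), a polygenic trait component, and
treatment-masked lipids, then prints the raw carrier vs non-carrier trait
means for the high-LDL condition.
"""

from penexome import SimulationConfig, simulate_cohort

sim = simulate_cohort(SimulationConfig(n_individuals=20_000, seed=1))
cohort = sim.cohort

print(f"cohort: {len(cohort)} individuals, {sim.genotypes.shape[1]} planted variants")
for cond in sim.config.conditions:
    n = int(cohort[f"carrier_{cond.name}"].sum())
    print(f"  {cond.name:<10} carriers: {n:>3}  (target frequency {cond.carrier_frequency:.2e})")

carr = cohort["carrier_high_ldl"]
print("\nhigh-LDL carriers, raw LDL mean:     "
      f"{cohort.loc[carr, 'ldl_raw'].mean():6.1f} mg/dL")
print("non-carriers, raw LDL mean:          "
      f"{cohort.loc[~carr, 'ldl_raw'].mean():6.1f} mg/dL")
print("difference should sit near the planted effect of +54.2 mg/dL "
      "(within sampling error at ~40 carriers).")
print(f"\n{int(cohort['on_lipid_med'].sum())} individuals are on lipid-lowering "
      "medication; their observed LDL is masked by the factor 0.7 that the "
      "harmonization step inverts.")
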