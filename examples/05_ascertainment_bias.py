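"""Phenotypic vs genetic ascertainment of the same variants.

Cohorts recruited for extreme biomarker values over-sample the upper tail of
the carrier distribution, inflating apparent expressivity.  This example
selects individuals above the 98th LDL percentile (blind to carrier status)
and compares carrier means under the two ascertainment modes against the
truncated-normal closed form.
"""

from penexome import (
    ConditionSpec,
    SimulationConfig,
    ascertainment_contrast,
    simulate_cohort,
)

cfg = SimulationConfig(
    n_individuals=100_000,
    seed=13,
    conditions=(ConditionSpec("high_ldl", ("LDLR", "APOB"), "ldl", 0.008, 55.0),),
)
sim = simulate_cohort(cfg)

c = ascertainment_contrast(
    sim.cohort, sim.cohort["carrier_high_ldl"], "ldl_raw",
    tail=0.02, side="upper",
    carrier_mu=cfg.trait_means["ldl"] + 55.0, carrier_sigma=cfg.trait_sds["ldl"],
)

print(f"selection threshold (98th population percentile): {c.threshold:.0f} mg/dL")
print(f"carrier mean, genetic ascertainment (all carriers):   {c.mean_unascertained:6.1f} mg/dL")
print(f"carrier mean, phenotypic ascertainment (selected):    {c.mean_ascertained:6.1f} mg/dL")
print(f"ascertainment-induced difference:                     {c.difference:6.1f} mg/dL")
print(f"truncated-normal expectation for that difference:     "
      f"{c.expected_difference_closed_form:6.1f} mg/dL")
print(f"\napparent carrier effect if one only saw the ascertained group: "
      f"{c.apparent_effect_ascertained:.1f} mg/dL")
print(f"true carrier effect (population sample):                       "
      f"{c.true_effect:.1f} mg/dL")
print("\nPhenotypic ascertainment inflates the apparent effect well past the "
      "planted 55 mg/dL - the bias can rival the effect itself.")
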