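# penexome

Penetrance and expressivity of monogenic metabolic conditions, estimated the
way biobank-scale exome studies do it — as a tested, reusable Python library.

Clinical genetics has traditionally estimated the risk conferred by
"pathogenic" variants from families ascertained on phenotype, which inflates
both penetrance (the fraction of carriers who manifest the condition) and
expressivity (how severely they manifest it). Population cohorts with exome
sequences and biomarker panels allow the opposite design: find carriers first,
look at phenotypes second. `penexome` implements that analysis for
autosomal-dominant metabolic conditions (monogenic diabetes/MODY,
dyslipidemias, monogenic obesity) and is aimed at statistical geneticists and
methodologists who want each stage as an importable, separately testable
component:

- **variant triage** (`penexome.triage`) — genotype QC (GQ ≥ 20, DP ≥ 10,
  minor allele balance > 0.25 for hets); ClinVar acceptance of P/LP assertions
  made since 2017-01-01 by high-volume clinical labs (>15,000 submissions,
  updated since 2017), gated on a cohort-adjusted gnomAD allele frequency
  `max(AC − cohort carriers, 0)/AN`; and a five-category predicted
  loss-of-function engine: NMD escape (last exon or final 50 bp of the
  penultimate exon) ⇒ not LoF unless >25 % of the CDS is truncated, in-frame
  splice rescue within ±6 bp (likely not LoF) or 6–21 bp (uncertain unless
  validated), with pext and gnomAD-filter downgrades.
- **phenotype harmonization** (`penexome.harmonize`) — statin adjustment
  (LDL/0.7, TG/0.85), mmol/L→mg/dL conversion, ADA-style glycemic
  classification (diabetes HbA1c ≥ 6.5 %; prediabetes HbA1c ≥ 5.7 %, FG ≥ 100,
  OGTT-2h ≥ 140), and clinical dichotomization (LDL ≥ 190, LDL ≤ 80,
  HDL ≥ 70, TG ≥ 200 mg/dL, BMI ≥ 30).
- **burden association** (`penexome.association`) — covariate-adjusted OLS for
  biomarkers and Firth-penalized logistic regression
  (ℓ(β) + ½ log det I(β)) for binary outcomes, finite under complete
  separation, with profile-penalized-likelihood confidence intervals.
- **penetrance** (`penexome.penetrance`) — k-of-n proportions with exact
  Clopper–Pearson intervals from Beta quantiles.
- **polygenic contrasts** (`penexome.polygenic`) — PGS scoring with
  effect-allele reconciliation, top-1 % vs interquartile contrasts,
  carrier-only expressivity regression, carrier×score interaction, the
  truncated-normal tail fraction equivalent to a monogenic effect, and the
  Fisher-z carrier count `n = ⌈((z₁₋α + z_pow)/atanh r)² + 3⌉`.
- **ascertainment bias** (`penexome.ascertainment`) — truncated-normal model
  of extreme-phenotype recruitment,
  E[X | X > t] = μ + σ·φ(a)/(1 − Φ(a)).
- **synthetic cohorts** (`penexome.simulate`) — the generator that stands in
  for access-restricted cohort data: additive carrier effects, a polygenic
  component with fixed SNP heritability, treatment-masked lipids, logistic
  diabetes liability, extreme-phenotype subsampling.
- **pipeline** (`penexome.pipeline` / `penexome` CLI) — one-config
  orchestration with per-stage TSV outputs and a hashed provenance manifest.

## Worked example

```bash
python examples/03_burden_and_penetrance.py
```

prints (deterministic, seed 11):

```
high-LDL burden: beta 53.0 mg/dL (se 3.7), p 9.7e-47, 81 carriers
MODY burden: OR 21.7 (95% profile CI 8.6-63.9), p 2e-09
high-LDL penetrance at the 190 mg/dL cut-off: 41/81 = 50.6% (95% CI 39.3%-61.9%)
```

Read: among 20,000 simulated individuals, the 81 carriers of high-LDL
variants run ~53 mg/dL above non-carriers after statin adjustment (planted
effect 54.2); carrying a MODY variant multiplies the odds of diabetes by ~22
(planted 21), estimated stably despite only ~20 carriers thanks to the Firth
penalty; and only half of high-LDL carriers actually cross the 190 mg/dL
diagnostic threshold — marked effect sizes coexist with incomplete
penetrance, which is the analysis' central point. The other examples cover
cohort simulation, the triage rule engines with their evidence trails,
polygenic-vs-monogenic contrasts, and ascertainment bias.

The full pipeline runs from the shell:

```bash
penexome run --out run1 --seed 1        # simulate → triage → … → power tables
penexome simulate --out simdir --n 20000 --seed 1
penexome triage --annotations ann.tsv --out decisions.tsv
```

## Documentation

`docs/methods.md` describes the statistical model, the rule engines, what the
synthetic cohorts do and do not emulate, numerical choices, and known
limitations.
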