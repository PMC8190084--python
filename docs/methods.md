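# Methods

## The estimation problem

For an autosomal-dominant metabolic condition, the quantities of interest are
the carrier effect size (the mean biomarker shift, or odds ratio, conferred by
carrying a clinically significant variant), the penetrance (the probability a
carrier crosses a clinical diagnostic threshold), and the modifiers of
expressivity (polygenic background, ascertainment mode). The statistical
difficulty is scale mismatch: cohorts are large (tens of thousands of exomes)
but carriers are rare (roughly 7–90 per condition), so every method must be
exact or penalized rather than asymptotic, and every upstream filtering rule
materially changes who counts as a carrier.

## Variant triage

Carriers are defined by two deterministic rule engines applied to annotated
variants; both return an ordered evidence trail so any call can be audited.

**ClinVar registry triage.** A laboratory registry is built from a
submission-summary table: labs with more than 15,000 ClinVar submissions whose
records were updated on or after 2017-01-01 (the current ACMG-guideline era),
minus a configurable manual-exclusion list (default: Counsyl, whose
assertions conflicted across phenotypes and are curated by hand instead). A
variant is accepted as clinically significant when a registry lab asserted
P/LP on or after 2017-01-01; registry B/LB excludes it; conflicting or absent
registry assertions defer to manual review. Before any acceptance, a
frequency gate excludes variants whose cohort-adjusted gnomAD frequency
`max(AC − cohort carriers, 0)/AN` exceeds the per-condition cut-off — the
frequency check runs first because it is the cheapest disqualifier and
mirrors first-pass clinical practice (BA1/BS1-style screening). The
subtraction floors at zero when the cohort contributes more carriers than
gnomAD records.

**pLoF engine.** LOFTEE high-confidence stop-gain, frameshift and essential
splice variants are classified on a five-point scale (LoF, likely LoF,
uncertain, likely not LoF, not LoF):

1. non-HC annotation or a site on the genotyping-quality blacklist ⇒ not LoF
   outright (the blacklist stands in for sites whose genotypes cannot be
   trusted, configured rather than hard-coded);
2. gnomAD variant-QC filter flag ⇒ one-class downgrade;
3. truncations in the NMD-escape region — the last exon or the final 50 bp
   of the penultimate exon, in transcript coordinates — are not LoF, unless
   the truncation removes more than 25 % of the coding sequence, which
   overrides the escape argument. "25 % of the gene" is interpreted as the
   truncated fraction of CDS length, not genomic span, because the
   NMD-escape pathogenicity argument is about protein-level impact. Exon
   intervals are 1-based closed at I/O and treated as coding sequence;
4. essential splice variants with an in-frame alternative splice site within
   6 bp are likely not LoF (essential rescue); between 6 and 21 bp the rescue
   is possible — likely not LoF if externally validated, otherwise
   uncertain, since in-silico validation of distal rescues is a manual step
   outside this package;
5. pext (proportion of expression across transcripts) below a configurable
   threshold downgrades one class; a missing pext skips the rule with an
   evidence note. The default threshold (0.10) is a package choice — the
   numeric cut-offs used in the original curation are not machine-readable —
   and should be set per analysis.

The engine is a pure function (identical inputs ⇒ identical class and
evidence order) and monotone: lowering pext or moving a truncation 3′-ward
never upgrades a variant toward LoF. Two-reviewer adjudication of read-level
artifacts is collapsed into this single deterministic pass; read review
itself is out of scope.

**Genotype QC and carriers.** Genotypes require GQ ≥ 20, DP ≥ 10 and, for
heterozygotes, minor allele balance min(ref, alt)/(ref+alt) > 0.25; failures
become missing, never errors. An individual carries a condition if they have
at least one non-missing alt genotype at a variant that is clinically
significant or classed LoF/likely LoF in the condition's gene panel
(composite sets supported, e.g. MODY = GCK, HNF1A, HNF1B, HNF4A, PDX1).
Because APOB and PCSK9 appear in both the high-LDL panel (gain-of-function
missense) and the low-LDL panel (loss of function), carrier assembly accepts
an optional per-variant condition assignment in addition to gene sets.

## Phenotype harmonization

Observed lipids in treated individuals are divided by 0.7 (LDL) and 0.85
(TG) to undo the expected treatment effect; HDL is never adjusted. Lipids in
mmol/L convert at ×38.67 (cholesterol) and ×88.57 (triglycerides) — standard
molar-mass factors. Glycemia: diabetes is HbA1c ≥ 6.5 % or an explicit
record flag (nurse/ICD-style fields are collapsed into one boolean; the
granular field mapping of any particular biobank is not reconstructed);
prediabetes is HbA1c ≥ 5.7 %, fasting glucose ≥ 100 mg/dL or 2-h OGTT
≥ 140 mg/dL; all boundaries inclusive; individuals with no glycemic
information are indeterminate and excluded from penetrance denominators.
Continuous conditions dichotomize at LDL ≥ 190, LDL ≤ 80, HDL ≥ 70,
TG ≥ 200 mg/dL and BMI ≥ 30 kg/m², after adjustment. Where a source provides
multiple visits, lipids/BMI should enter as the per-individual mean and
HbA1c as the maximum, before classification. TG and BMI are log-transformed
inside the association module, not here.

## Association

Continuous biomarkers: OLS of the (possibly log) trait on a carrier
indicator plus covariates (age, sex, 10 PCs by default; diabetes status as
an additional covariate for lipid/BMI models in the pipeline), two-sided
Wald p-values. Binary outcomes: Firth-penalized logistic regression,
maximizing ℓ(β) + ½ log det I(β). The penalized score is solved by Newton
iterations with step-halving; convergence requires relative penalized
log-likelihood change below 1e-8 *and* a final step below 1e-6 in every
coordinate (the second condition guards against premature stops that leave
the estimate several parts in 1e4 off the optimum), max 50 iterations.
Standard errors come from the inverse penalized Fisher information;
confidence intervals from the profile penalized likelihood by default (Wald
optional for speed), because Wald intervals are badly asymmetric-blind at
5–20 carriers. Composite estimates use the union of per-gene carriers,
counting multi-gene carriers once; per-gene rows are emitted alongside.

## Penetrance

k affected among n evaluable carriers, with exact Clopper–Pearson 95 %
intervals: lower = BetaInv(α/2; k, n−k+1), upper = BetaInv(1−α/2; k+1, n−k),
closed at k = 0 and k = n. Carriers with indeterminate phenotype are removed
from the denominator rather than imputed. For monogenic diabetes both
outcome definitions (diabetes only; diabetes or prediabetes) are emitted,
since either may be the clinically relevant endpoint.

## Polygenic scores and planning

Scores are Σ weight × effect-allele dosage with per-variant mean imputation
of missing dosages, standardized over the analysis cohort; weight files with
flipped effect alleles reconcile to identical scores, and low-LDL analyses
use the sign-flipped LDL score (an orientation flag, not a recomputation).
Tail contrasts compare the top 1 % of the score against the 25–75 % range by
GLM with covariates, restricted to age ≥ 60 (a lifetime-risk score is
diluted in the young); percentiles are assigned within that restricted
subset. Expressivity is the within-carrier regression of phenotype on the
standardized score; the interaction test adds a carrier×score product term.

Two planning calculations close the loop. The tail-equivalence solver finds
the fraction q of the population whose top polygenic scores match a
monogenic mean shift, solving √h² · sd · φ(z_q)/q = shift by bracketed root
finding on q ∈ [1e-8, 0.5] (the left-hand side is strictly decreasing in q,
so the solution is unique; shifts above the q = 1e-8 value raise an error).
The correlation power formula n = ⌈((z₁₋α + z_power)/atanh r)² + 3⌉ uses a
one-sided α by default, which reproduces the published carrier count of 98
for r = 0.25 at 80 % power (the two-sided variant gives 124); sidedness is
exposed because the convention is genuinely ambiguous in this literature.
Cohort size is then ⌈carriers/prevalence⌉.

## Ascertainment bias

Recruiting on an extreme biomarker (e.g. beyond the 98th/2nd population
percentile) selects carriers from the upper tail of their own trait
distribution. With carrier trait values N(μ, σ²) and threshold t, the
selected carrier mean is the truncated-normal expectation
μ + σ·φ(a)/(1−Φ(a)), a = (t−μ)/σ. The empirical contrast reports, for the
same variants, the mean in phenotypically ascertained carriers vs all
(genetically ascertained) carriers, the induced difference, its closed-form
expectation, and the *apparent* carrier effect in the ascertained stratum
(ascertained carrier mean − non-carrier mean). At 98th-percentile selection
with a 55 mg/dL carrier effect on an sd-33 trait, the induced difference is
≈35 mg/dL and the apparent effect ≈90 mg/dL — the bias is of the same order
as the effect itself, and the induced difference alone overtakes the effect
once selection passes roughly the 99.9th percentile. Real extreme-phenotype
recruitment (maximum-ever values, assay differences, repeated measures) is
not modelled; a single cross-sectional trait with quantile selection
captures the mechanism.

## The synthetic cohort generator

Real cohort data are access-restricted, so the generator emulates their
statistical structure: traits follow mean + carrier·β + g + e with
g ~ N(0, h²·sd²) and e ~ N(0, (1−h²)·sd²); carriers are Bernoulli draws at
the configured frequency; diabetes is a logistic liability on age, sex, a
standardized diabetes score and the carrier log-odds, calibrated to a
configurable non-carrier baseline (default 10 %, a typical middle-aged
prevalence — the source analyses report only odds ratios); treatment is
logistic in raw LDL, and treated individuals' observed LDL/TG carry the
exact inverse of the harmonization divisors, so adjustment∘masking is the
identity. Defaults are the population-biobank study conditions: n = 38,566,
carrier counts of ~16–90 per condition, effects +54.2/−56.4/+16.8/+126.0
mg/dL, +2.2 kg/m², diabetes OR 21, heritabilities LDL 0.1347, HDL 0.1572,
TG 0.1525 (BMI 0.20, a conventional SNP-h² chosen here). Trait means/sds are
package choices on the additive-normal scale; the TG sd is 65 mg/dL rather
than the ~85 seen on the skewed natural scale, because a normal TG with
sd 85 would censor ~4 % of draws at the non-negativity floor and distort the
variance decomposition the generator promises (h² recovered within 0.01 at
n = 1e5).

The polygenic component is drawn directly as a normal deviate — tests of
score *arithmetic* use a separate small Hardy–Weinberg SNP panel
(≤1,000 biallelic SNPs) so that genome-scale genotypes are never needed. A
single master seed spawns independent per-module child streams
(numpy SeedSequence), making output byte-identical under a fixed seed.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: linkage disequilibrium and relatedness, ancestry
stratification, longitudinal measurement, skewed trait distributions,
genotype batch effects, and real selection protocols. Tests demonstrate that
the estimators recover the parameters of this generating model at the study
sample sizes, not that any particular real-world estimate is correct.

## Numerical choices and degenerate inputs

Zero-depth heterozygotes fail QC (not an error); an=0 in the frequency
adjustment is an error; transcript positions outside every exon are errors;
empty carrier strata, single-class outcomes, constant carrier indicators and
rank-deficient designs raise informative errors; zero evaluable carriers
drop the penetrance row with a warning; zero carriers drawn by the simulator
set a warning flag on the output. Problem sizes in the test suite (cohorts
of 5,000–100,000; 200 replicates for parameter-recovery checks; 2,000
replicates for interval coverage) were chosen as the smallest at which the
Monte-Carlo error of each check is comfortably below the tolerance being
asserted.

## Known limitations

Full ACMG evidence-code combination (PVS1/PS/PM/PP), read-level review, MNV
re-phasing, LD-aware weight estimation, survival/age-at-onset penetrance,
meta-analysis across cohorts and family-based segregation correction are out
of scope. The Firth implementation targets dense, modest-dimension designs
(tens of covariates), not genome-wide scans.
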