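"""Synthetic biobank cohort generator.

Real cohorts with exome sequence, deep metabolic phenotyping and consent for
penetrance analyses are access-restricted, so every downstream stage of this
package is exercised against simulated data with the same statistical
structure: rare autosomal-dominant carriers at realistic counts (tens of
carriers per condition among tens of thousands of individuals), additive
carrier effects on lipids/BMI in measured units, carrier log-odds on diabetes,
a normally distributed polygenic component with fixed SNP heritability per
trait, treatment-masked lipid values, ADA-style glycemic classification, and
optional extreme-phenotype or case-control ascertainment.

Defaults reproduce the population-biobank arm of the study conditions:
n = 38,566 individuals aged 40-70, carrier counts of roughly 16-90 per
condition, lipid effects of +54.2 / -56.4 / +16.8 / +126.0 mg/dL and
+2.2 kg/m^2 for BMI, a diabetes odds ratio of 21 for monogenic diabetes, and
SNP heritabilities of 0.1347 (LDL), 0.1572 (HDL) and 0.1525 (TG).

The generator draws the polygenic component directly as a normal deviate; a
separate small SNP panel (``simulate_snp_panel``) exists for testing the
polygenic-score arithmetic itself without genome-scale data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from datetime import date
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .harmonize import HarmonizationConfig, classify_glycemia
from .triage import ClinVarSubmission, SpliceContext, TranscriptModel, VariantRecord

__all__ = [
    "ConditionSpec",
    "SimulationConfig",
    "AscertainmentScheme",
    "SimulatedCohort",
    "AnnotationFixtures",
    "default_conditions",
    "simulate_cohort",
    "simulate_snp_panel",
    "simulate_variant_annotations",
    "apply_ascertainment",
]


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConditionSpec:
    name: str
    genes: tuple[str, ...]
    trait: str  # ldl | hdl | tg | bmi | diabetes
    carrier_frequency: float
    effect: float  # trait units, or log-odds for binary traits
    penetrance_target: float | None = None

    def __post_init__(self):
        if not 0 < self.carrier_frequency < 0.01:
            raise ValueError("carrier_frequency must lie in (0, 0.01)")
        if not np.isfinite(self.effect):
            raise ValueError("effect must be finite")
        if not self.genes:
            raise ValueError("gene set must be non-empty")


_N_DEFAULT = 38_566


def default_conditions() -> tuple[ConditionSpec, ...]:
    """Study conditions: gene panels, carrier counts and effect sizes."""
    n = _N_DEFAULT
    return (
        ConditionSpec("high_ldl", ("LDLR", "APOB"), "ldl", 83 / n, 54.2),
        ConditionSpec("low_ldl", ("APOB", "PCSK9"), "ldl", 90 / n, -56.4),
        ConditionSpec("high_hdl", ("CETP",), "hdl", 20 / n, 16.8),
        ConditionSpec("high_tg", ("APOA5", "LPL"), "tg", 54 / n, 126.0),
        ConditionSpec("obesity", ("MC4R",), "bmi", 31 / n, 2.2),
        ConditionSpec(
            "mody", ("GCK", "HNF1A", "HNF1B", "HNF4A", "PDX1"), "diabetes",
            16 / n, float(np.log(21.0)),
        ),
    )


@dataclass(frozen=True)
class SimulationConfig:
    n_individuals: int = _N_DEFAULT
    seed: int = 0
    conditions: tuple[ConditionSpec, ...] = field(default_factory=default_conditions)
    h2_by_trait: Mapping[str, float] = field(
        default_factory=lambda: {"tg": 0.1525, "ldl": 0.1347, "hdl": 0.1572, "bmi": 0.20}
    )
    trait_means: Mapping[str, float] = field(
        default_factory=lambda: {"ldl": 138.0, "hdl": 58.0, "tg": 150.0, "bmi": 27.4}
    )
    trait_sds: Mapping[str, float] = field(
        default_factory=lambda: {"ldl": 33.0, "hdl": 15.0, "tg": 65.0, "bmi": 4.75}
    )
    baseline_diabetes_prevalence: float = 0.10
    diabetes_pgs_logor: float = 0.4  # per SD of the diabetes polygenic score
    # treatment probability: expit(intercept + slope * (raw LDL - center))
    medication_intercept: float = -2.0
    medication_slope: float = 0.025
    medication_center: float = 160.0

    def __post_init__(self):
        if self.n_individuals <= 0:
            raise ValueError("n_individuals must be positive")
        for t, h2 in self.h2_by_trait.items():
            if not 0 <= h2 < 1:
                raise ValueError(f"h2 for {t} must lie in [0, 1)")
        for t, sd in self.trait_sds.items():
            if sd <= 0:
                raise ValueError(f"trait sd for {t} must be positive")


@dataclass(frozen=True)
class AscertainmentScheme:
    kind: str = "population"  # population | extreme_phenotype | case_control
    trait: str | None = None
    tail: float = 0.02
    side: str = "both"  # upper | lower | both
    outcome: str | None = None


@dataclass
class SimulatedCohort:
    cohort: pd.DataFrame
    genotypes: pd.DataFrame  # individuals x variant_id, alt allele counts
    variants: pd.DataFrame  # variant_id, gene, condition
    config: SimulationConfig
    zero_carrier_conditions: tuple[str, ...] = ()


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------

def _child_rngs(seed: int, names: Sequence[str]) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {name: np.random.default_rng(ss) for name, ss in zip(names, children)}


def simulate_cohort(config: SimulationConfig = SimulationConfig()) -> SimulatedCohort:
    """Draw a cohort table and rare-variant genotype matrix.

    Continuous traits follow mean + carrier effect + polygenic + residual with
    the polygenic component carrying the configured heritability fraction of
    the trait variance.  Diabetes status comes from a logistic liability on
    age, sex, a standardized diabetes polygenic score and the carrier
    log-odds, calibrated to the configured non-carrier baseline prevalence.
    Treated individuals have observed LDL multiplied by 0.7 and TG by 0.85
    (the exact inverse of the harmonization adjustment); raw values are kept
    in ``*_raw`` columns, which real data would not have.
    """
    n = config.n_individuals
    rngs = _child_rngs(
        config.seed,
        ["demographics", "carriers", "polygenic", "residual", "glycemia", "medication", "genotypes"],
    )

    rng = rngs["demographics"]
    cohort = pd.DataFrame(
        {
            "id": [f"S{i:06d}" for i in range(n)],
            "age": rng.integers(40, 71, size=n),
            "sex": rng.integers(0, 2, size=n),
        }
    )
    for k in range(1, 11):
        cohort[f"pc{k}"] = rng.normal(0.0, 1.0, size=n)

    # carrier draws, blind to everything else
    rngc = rngs["carriers"]
    zero_carrier = []
    for cond in config.conditions:
        flags = rngc.random(n) < cond.carrier_frequency
        cohort[f"carrier_{cond.name}"] = flags
        if not flags.any():
            zero_carrier.append(cond.name)
    if zero_carrier:
        warnings.warn(f"no carriers drawn for: {zero_carrier}")

    # polygenic components, stored standardized for reuse as a direct gePS
    rngp = rngs["polygenic"]
    gps = {t: rngp.normal(0.0, 1.0, size=n) for t in ("ldl", "hdl", "tg", "bmi", "t2d")}
    for t, z in gps.items():
        cohort[f"gps_{t}"] = z

    # continuous traits
    rngr = rngs["residual"]
    for trait in ("ldl", "hdl", "tg", "bmi"):
        mu = config.trait_means[trait]
        sd = config.trait_sds[trait]
        h2 = config.h2_by_trait.get(trait, 0.0)
        value = mu + np.sqrt(h2) * sd * gps[trait] + rngr.normal(0.0, np.sqrt(1 - h2) * sd, size=n)
        for cond in config.conditions:
            if cond.trait == trait:
                value = value + cond.effect * cohort[f"carrier_{cond.name}"].to_numpy()
        cohort[f"{trait}_raw"] = np.clip(value, 1.0, None)

    # diabetes liability and glycemic biomarkers
    rngg = rngs["glycemia"]
    eta = (
        logit(config.baseline_diabetes_prevalence)
        + 0.03 * (cohort["age"].to_numpy() - 55)
        + 0.2 * (cohort["sex"].to_numpy() - 0.5)
        + config.diabetes_pgs_logor * gps["t2d"]
    )
    for cond in config.conditions:
        if cond.trait == "diabetes":
            eta = eta + cond.effect * cohort[f"carrier_{cond.name}"].to_numpy()
    diabetic = rngg.random(n) < expit(eta)
    cohort["diabetes_record_flag"] = diabetic
    hba1c = np.where(
        diabetic,
        np.clip(rngg.normal(7.2, 0.8, size=n), 5.0, 14.0),
        np.clip(rngg.normal(5.35, 0.35, size=n), 4.0, 6.4),
    )
    cohort["hba1c"] = np.round(hba1c, 2)
    fg = np.where(
        diabetic,
        np.clip(rngg.normal(145.0, 30.0, size=n), 80.0, None),
        np.clip(rngg.normal(90.0, 8.0, size=n), 55.0, 125.9),
    )
    cohort["fasting_glucose"] = np.round(fg, 1)
    have_ogtt = rngg.random(n) < 0.2
    ogtt = np.where(
        diabetic,
        np.clip(rngg.normal(220.0, 40.0, size=n), 100.0, None),
        np.clip(rngg.normal(110.0, 20.0, size=n), 50.0, None),
    )
    cohort["ogtt_2h"] = np.where(have_ogtt, np.round(ogtt, 1), np.nan)

    # medication assignment and masking of observed lipids
    rngm = rngs["medication"]
    p_med = expit(
        config.medication_intercept
        + config.medication_slope * (cohort["ldl_raw"].to_numpy() - config.medication_center)
    )
    on_med = rngm.random(n) < p_med
    cohort["on_lipid_med"] = on_med
    cohort["ldl"] = np.where(on_med, cohort["ldl_raw"] * 0.7, cohort["ldl_raw"])
    cohort["tg"] = np.where(on_med, cohort["tg_raw"] * 0.85, cohort["tg_raw"])
    cohort["hdl"] = cohort["hdl_raw"]
    cohort["bmi"] = cohort["bmi_raw"]

    # glycemia flags consistent with the harmonization rules
    hc = HarmonizationConfig()
    cohort["glycemia"] = [
        classify_glycemia(h, g, o, r, hc)
        for h, g, o, r in zip(
            cohort["hba1c"], cohort["fasting_glucose"], cohort["ogtt_2h"],
            cohort["diabetes_record_flag"],
        )
    ]
    cohort["diabetes"] = cohort["glycemia"] == "diabetes"
    cohort["prediabetes"] = cohort["glycemia"] == "prediabetes"
    cohort = cohort.set_index("id")

    genotypes, variants = _rare_variant_genotypes(cohort, config, rngs["genotypes"])
    return SimulatedCohort(
        cohort=cohort,
        genotypes=genotypes,
        variants=variants,
        config=config,
        zero_carrier_conditions=tuple(zero_carrier),
    )


def _rare_variant_genotypes(cohort, config, rng):
    """Assign each carrier one planted heterozygous variant in a panel gene."""
    records = []
    columns: dict[str, np.ndarray] = {}
    n = len(cohort)
    for ci, cond in enumerate(config.conditions):
        vids = []
        for gi, gene in enumerate(cond.genes):
            for k in range(2):
                vid = f"{ci + 1}-{1000 * (gi + 1) + 10 * k}-A-T"
                vids.append(vid)
                records.append(
                    {"variant_id": vid, "gene": gene, "condition": cond.name,
                     "chrom": str(ci + 1), "pos": 1000 * (gi + 1) + 10 * k,
                     "ref": "A", "alt": "T"}
                )
        carriers = np.flatnonzero(cohort[f"carrier_{cond.name}"].to_numpy())
        assignment = rng.integers(0, len(vids), size=carriers.size)
        for vi, vid in enumerate(vids):
            col = np.zeros(n)
            col[carriers[assignment == vi]] = 1.0
            columns[vid] = col
    genotypes = pd.DataFrame(columns, index=cohort.index)
    variants = pd.DataFrame(
        records,
        columns=["variant_id", "gene", "condition", "chrom", "pos", "ref", "alt"],
    ).set_index("variant_id")
    return genotypes, variants


def simulate_snp_panel(
    n_individuals: int,
    n_snps: int = 200,
    seed: int = 0,
    maf_range: tuple[float, float] = (0.05, 0.5),
    weight_sd: float = 1.0,
):
    """Small biallelic SNP panel under Hardy-Weinberg with a weight table.

    Returns (dosages, alleles, weights): dosages individuals x snp (0/1/2
    counting the alt allele), an allele map, and PGS weights on the alt
    allele.  Meant for testing score arithmetic, not for trait generation.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    freqs = rng.uniform(*maf_range, size=n_snps)
    ids = [f"snp{i:04d}" for i in range(n_snps)]
    dosages = pd.DataFrame(
        rng.binomial(2, freqs, size=(n_individuals, n_snps)).astype(float),
        columns=ids,
        index=[f"S{i:06d}" for i in range(n_individuals)],
    )
    alleles = pd.DataFrame({"variant_id": ids, "ref": "A", "alt": "G"})
    weights = pd.DataFrame(
        {"variant_id": ids, "effect_allele": "G", "weight": rng.normal(0.0, weight_sd, n_snps)}
    )
    return dosages, alleles, weights


# ---------------------------------------------------------------------------
# ascertainment subsampling
# ---------------------------------------------------------------------------

def apply_ascertainment(cohort: pd.DataFrame, scheme: AscertainmentScheme) -> pd.DataFrame:
    """Subsample a cohort the way a study design would.

    ``population`` returns the cohort unchanged; ``extreme_phenotype`` keeps
    individuals at or beyond the empirical tail quantile(s) of a trait
    (selection blind to carrier status); ``case_control`` keeps individuals
    with a truthy value of the outcome column plus an equal-sized random-free
    complement of controls (all non-cases).
    """
    if scheme.kind == "population":
        return cohort
    if scheme.kind == "extreme_phenotype":
        if scheme.trait is None or scheme.trait not in cohort.columns:
            raise ValueError(f"trait {scheme.trait!r} absent from cohort")
        if not 0 < scheme.tail < 0.5:
            raise ValueError("tail fraction must lie in (0, 0.5)")
        vals = cohort[scheme.trait].astype(float)
        keep = pd.Series(False, index=cohort.index)
        if scheme.side in ("upper", "both"):
            keep |= vals >= vals.quantile(1 - scheme.tail)
        if scheme.side in ("lower", "both"):
            keep |= vals <= vals.quantile(scheme.tail)
        if scheme.side not in ("upper", "lower", "both"):
            raise ValueError("side must be upper, lower or both")
        return cohort[keep]
    if scheme.kind == "case_control":
        if scheme.outcome is None or scheme.outcome not in cohort.columns:
            raise ValueError(f"outcome {scheme.outcome!r} absent from cohort")
        return cohort  # full cohort already contains both cases and controls
    raise ValueError(f"unknown ascertainment kind {scheme.kind!r}")


# ---------------------------------------------------------------------------
# rule-engine fixtures
# ---------------------------------------------------------------------------

@dataclass
class AnnotationFixtures:
    variants: list[VariantRecord]
    transcripts: dict[str, TranscriptModel]
    splice_contexts: dict[str, SpliceContext]
    clinvar: dict[str, list[ClinVarSubmission]]
    lab_summary: pd.DataFrame
    af_cutoffs: dict[str, float]
    expected_lof: dict[str, str]
    expected_triage: dict[str, str]


def simulate_variant_annotations(gene: str = "GCK") -> AnnotationFixtures:
    """Deterministic fixture bundle exercising every triage rule branch.

    One plus-strand transcript (four coding exons, 2,100 bp CDS) carries
    truncating variants placed mid-CDS, in the last exon (10 % of CDS lost),
    and in the final 50 bp of the penultimate exon (30 % lost, firing the
    >25 % override), splice variants with in-frame alternative sites 4 and
    10 bp away, and variants hit by the pext, gnomAD-filter and blacklist
    downgrades.  ClinVar records span registry and non-registry labs with
    report dates straddling 2017-01-01, plus a conflict and a common variant
    caught by the frequency gate.
    """
    tx = TranscriptModel(
        gene=gene,
        strand="+",
        exons=((101, 700), (801, 1400), (1501, 1800), (1901, 2500)),
        cds_length=2100,
    )
    mk = lambda pos, cons, **kw: VariantRecord(
        chrom="7", pos=pos, ref="C", alt="T", gene=gene, consequence=cons,
        loftee=kw.pop("loftee", "HC"), **kw,
    )
    variants = {
        "mid_stop": mk(900, "stop_gained", pext=0.95),
        "last_exon_10pct": mk(2290, "stop_gained", pext=0.95),  # cds 1891, 10% lost
        "penult_tail_30pct": mk(1771, "stop_gained", pext=0.95),  # cds 1471, 30% lost
        "splice_rescue_4bp": mk(700, "splice_donor", pext=0.95),
        "splice_possible_10bp": mk(700, "splice_donor", pext=0.95),
        "splice_validated_10bp": mk(700, "splice_donor", pext=0.95),
        "low_pext_stop": mk(900, "stop_gained", pext=0.02),
        "gnomad_flagged_stop": mk(900, "stop_gained", pext=0.95, gnomad_filter_flag=True),
        "blacklisted": mk(900, "frameshift", pext=0.95, site_blacklisted=True),
        "loftee_lc": mk(900, "stop_gained", loftee="LC", pext=0.95),
    }
    splice_contexts = {
        "splice_rescue_4bp": SpliceContext(4),
        "splice_possible_10bp": SpliceContext(10, validated=False),
        "splice_validated_10bp": SpliceContext(10, validated=True),
    }
    expected_lof = {
        "mid_stop": "LoF",
        "last_exon_10pct": "not_LoF",
        "penult_tail_30pct": "LoF",
        "splice_rescue_4bp": "likely_not_LoF",
        "splice_possible_10bp": "uncertain",
        "splice_validated_10bp": "likely_not_LoF",
        "low_pext_stop": "likely_LoF",
        "gnomad_flagged_stop": "likely_LoF",
        "blacklisted": "not_LoF",
        "loftee_lc": "not_LoF",
    }

    lab_summary = pd.DataFrame(
        {
            "lab": ["BigLab", "SmallLab", "StaleLab", "Counsyl"],
            "n_total_lab_submissions": [20_000, 8_000, 22_000, 19_000],
            "last_update": ["2019-03-01", "2019-03-01", "2016-06-01", "2019-03-01"],
        }
    )
    sub = lambda lab, sig, d: ClinVarSubmission(
        lab=lab, significance=sig, date_reported=date.fromisoformat(d), phenotype="MODY"
    )
    cv_variants = {
        "cv_accept": mk(950, "missense", gnomad_ac=4, gnomad_an=250_000),
        "cv_predates": mk(951, "missense", gnomad_ac=4, gnomad_an=250_000),
        "cv_benign": mk(952, "missense", gnomad_ac=4, gnomad_an=250_000),
        "cv_conflict": mk(953, "missense", gnomad_ac=4, gnomad_an=250_000),
        "cv_nonregistry": mk(954, "missense", gnomad_ac=4, gnomad_an=250_000),
        "cv_highfreq": mk(955, "missense", gnomad_ac=5_000, gnomad_an=250_000),
    }
    clinvar = {
        "cv_accept": [sub("BigLab", "P", "2018-05-01")],
        "cv_predates": [sub("BigLab", "P", "2016-06-01")],
        "cv_benign": [sub("BigLab", "B", "2018-05-01")],
        "cv_conflict": [sub("BigLab", "P", "2018-05-01"), sub("BigLab", "LB", "2018-06-01")],
        "cv_nonregistry": [sub("SmallLab", "P", "2018-05-01")],
        "cv_highfreq": [sub("BigLab", "P", "2018-05-01")],
    }
    expected_triage = {
        "cv_accept": "clinically_significant",
        "cv_predates": "manual_review",
        "cv_benign": "excluded",
        "cv_conflict": "manual_review",
        "cv_nonregistry": "manual_review",
        "cv_highfreq": "excluded",
    }
    all_variants = []
    for name, v in {**variants, **cv_variants}.items():
        all_variants.append(replace(v, variant_id=name))
    return AnnotationFixtures(
        variants=all_variants,
        transcripts={gene: tx},
        splice_contexts=splice_contexts,
        clinvar=clinvar,
        lab_summary=lab_summary,
        af_cutoffs={"MODY": 1e-4},
        expected_lof=expected_lof,
        expected_triage=expected_triage,
    )
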