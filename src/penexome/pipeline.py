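"""End-to-end orchestration: simulate -> triage -> harmonize -> associate ->
penetrance -> polygenic -> ascertainment, with per-stage tab-delimited outputs
and a provenance manifest.

Each stage's output table is the contract with the next stage (no opaque
binary state), so a run directory can be inspected or partially re-run with
standard tools.  The manifest records the configuration, seed, per-stage
output files with SHA-256 digests and the list of completed stages; a rerun
with the same configuration and seed is bit-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as pio
from .ascertainment import ascertainment_contrast
from .association import composite_burden
from .harmonize import HarmonizationConfig, dichotomize, harmonize_cohort
from .penetrance import penetrance_table
from .polygenic import (
    PowerQuery,
    carrier_geps_regression,
    compute_pgs,
    contrast_top_tail,
    interaction_test,
    n_for_correlation,
    required_cohort_size,
)
from .simulate import (
    SimulationConfig,
    default_conditions,
    simulate_cohort,
    simulate_snp_panel,
    simulate_variant_annotations,
)
from .triage import (
    build_lab_registry,
    carrier_matrix,
    classify_plof,
    triage_clinvar,
)

__all__ = ["RunConfig", "PipelineStageError", "run_pipeline"]

_TRAIT_FOR = {
    "high_ldl": ("ldl", False, False),
    "low_ldl": ("ldl", False, False),
    "high_hdl": ("hdl", False, False),
    "high_tg": ("tg", False, True),
    "obesity": ("bmi", False, True),
    "mody": ("diabetes", True, False),
}
_GEPS_FOR = {"high_ldl": "gps_ldl", "low_ldl": "gps_ldl", "high_hdl": "gps_hdl",
             "high_tg": "gps_tg", "obesity": "gps_bmi", "mody": "gps_t2d"}


@dataclass
class RunConfig:
    out_dir: str | Path = "penexome_run"
    seed: int = 0
    n_individuals: int = 20_000
    min_carriers: int = 1
    ascertainment_tail: float = 0.02
    firth_ci: str = "profile"
    simulation: SimulationConfig | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = pio.load_yaml(path)
        return cls(**raw)

    def resolved_simulation(self) -> SimulationConfig:
        if self.simulation is not None:
            return self.simulation
        return SimulationConfig(n_individuals=self.n_individuals, seed=self.seed)


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"pipeline aborted at stage {stage!r}: {cause}")
        self.stage = stage
        self.cause = cause


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage, writing tables and a provenance manifest.

    Returns the manifest dict.  A stage failure writes a partial manifest
    marking completed stages and raises :class:`PipelineStageError`.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sim_config = config.resolved_simulation()
    manifest: dict = {
        "seed": config.seed,
        "n_individuals": sim_config.n_individuals,
        "completed_stages": [],
        "outputs": {},
        "config_hash": hashlib.sha256(
            json.dumps(asdict(sim_config), sort_keys=True, default=str).encode()
        ).hexdigest(),
    }
    state: dict = {}

    def record(stage: str, files: dict[str, Path]):
        manifest["completed_stages"].append(stage)
        for name, path in files.items():
            manifest["outputs"][name] = {
                "path": str(path.relative_to(out)),
                "sha256": _sha256(path),
            }

    stages = [
        ("simulate", _stage_simulate),
        ("triage", _stage_triage),
        ("harmonize", _stage_harmonize),
        ("associate", _stage_associate),
        ("penetrance", _stage_penetrance),
        ("pgs", _stage_pgs),
        ("ascertain", _stage_ascertain),
        ("power", _stage_power),
    ]
    for name, fn in stages:
        try:
            files = fn(config, sim_config, state, out)
        except Exception as exc:  # abort with partial manifest
            (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
            raise PipelineStageError(name, exc) from exc
        record(name, files)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _stage_simulate(config, sim_config, state, out):
    sim = simulate_cohort(sim_config)
    state["sim"] = sim
    files = {
        "phenotypes": pio.write_table(sim.cohort, out / "phenotypes.tsv"),
        "variants": pio.write_table(sim.variants, out / "variants.tsv"),
        "vcf": pio.write_vcf(out / "genotypes.vcf", sim.genotypes, sim.variants, seed=config.seed),
    }
    fixtures = simulate_variant_annotations()
    state["fixtures"] = fixtures
    ann = pd.DataFrame(
        [
            {
                "variant_id": v.variant_id, "gene": v.gene, "consequence": v.consequence,
                "loftee": v.loftee, "pext": v.pext, "gnomad_ac": v.gnomad_ac,
                "gnomad_an": v.gnomad_an, "gnomad_filter_flag": v.gnomad_filter_flag,
                "site_blacklisted": v.site_blacklisted,
            }
            for v in fixtures.variants
        ]
    ).set_index("variant_id")
    files["annotations"] = pio.write_table(ann, out / "annotations.tsv")
    files["clinvar_labs"] = pio.write_table(fixtures.lab_summary, out / "clinvar_labs.tsv", index=False)
    return files


def _stage_triage(config, sim_config, state, out):
    fixtures = state["fixtures"]
    registry = build_lab_registry(fixtures.lab_summary)
    rows = []
    for v in fixtures.variants:
        if v.variant_id in fixtures.clinvar:
            d = triage_clinvar(
                v, fixtures.clinvar[v.variant_id], registry,
                cohort_carrier_count=0, af_cutoff=fixtures.af_cutoffs.get("MODY"),
            )
            rows.append({"variant_id": v.variant_id, "kind": "clinvar",
                         "decision": d.decision.value, "lof_class": "",
                         "evidence": " | ".join(d.evidence)})
        else:
            cls, ev = classify_plof(
                v, fixtures.transcripts[v.gene], fixtures.splice_contexts.get(v.variant_id)
            )
            rows.append({"variant_id": v.variant_id, "kind": "plof",
                         "decision": "", "lof_class": cls.value,
                         "evidence": " | ".join(ev)})
    decisions = pd.DataFrame(rows).set_index("variant_id")
    files = {"decisions": pio.write_table(decisions, out / "decisions.tsv")}

    # carrier flags from the VCF (planted variants are the accepted set)
    genotypes = pio.read_vcf_genotypes(out / "genotypes.vcf")
    sim = state["sim"]
    vdec = pd.DataFrame(
        {"gene": sim.variants["gene"], "condition": sim.variants["condition"],
         "qualifying": True},
        index=sim.variants.index,
    )
    gene_sets = {c.name: list(c.genes) for c in sim_config.conditions}
    carriers = carrier_matrix(vdec, genotypes, gene_sets)
    gene_carriers = {
        cond: carrier_matrix(
            vdec[vdec["condition"] == cond].drop(columns="condition"),
            genotypes, {g: [g] for g in genes},
        )
        for cond, genes in gene_sets.items()
    }
    state["carriers"] = carriers
    state["gene_carriers"] = gene_carriers
    files["carriers"] = pio.write_table(carriers, out / "carriers.tsv")
    return files


def _stage_harmonize(config, sim_config, state, out):
    cohort = harmonize_cohort(state["sim"].cohort)
    state["cohort"] = cohort
    return {"cohort_harmonized": pio.write_table(cohort, out / "cohort_harmonized.tsv")}


def _covariates(cohort, extra=()):
    cols = ["age", "sex"] + [f"pc{k}" for k in range(1, 11)] + list(extra)
    return cohort[cols].astype(float)


def _stage_associate(config, sim_config, state, out):
    cohort = state["cohort"]
    gene_sets = {c.name: list(c.genes) for c in sim_config.conditions}
    phenos, binary, logsc = {}, {}, {}
    for cond in gene_sets:
        trait, is_binary, log_scale = _TRAIT_FOR.get(cond, (None, False, False))
        if trait is None or trait not in cohort:
            continue
        phenos[cond] = cohort[trait].astype(float)
        binary[cond] = is_binary
        logsc[cond] = log_scale
    results = composite_burden(
        gene_sets, state["gene_carriers"], phenos,
        covariates=_covariates(cohort), binary=binary, log_scale=logsc,
        firth_ci=config.firth_ci,
    )
    state["association"] = results
    return {"association": pio.write_table(results, out / "association.tsv", index=False)}


def _stage_penetrance(config, sim_config, state, out):
    cohort = state["cohort"]
    hc = HarmonizationConfig()
    cases = {}
    for cond in state["carriers"].columns:
        if cond in hc.thresholds:
            cases[cond] = dichotomize(cohort, cond, hc).rename(cond)
    if "mody" in state["carriers"].columns:
        diab = cohort["diabetes"].astype("boolean")
        any_dysglycemia = (cohort["glycemia"].isin(["diabetes", "prediabetes"])).astype("boolean")
        indeterminate = cohort["glycemia"] == "indeterminate"
        cases["mody"] = diab.mask(indeterminate).rename("mody")
        cases["mody_or_prediabetes"] = any_dysglycemia.mask(indeterminate)
    carr = state["carriers"]
    tables = [penetrance_table(carr, cases, gene_carriers=state["gene_carriers"])]
    if "mody" in carr.columns and "mody_or_prediabetes" in cases:
        alt = penetrance_table(
            carr[["mody"]],
            {"mody": cases["mody_or_prediabetes"].rename("diabetes_or_prediabetes")},
            gene_carriers={"mody": state["gene_carriers"]["mody"]},
        )
        tables.append(alt)
    pen = pd.concat(tables, ignore_index=True)
    state["penetrance"] = pen
    return {"penetrance": pio.write_table(pen, out / "penetrance.tsv", index=False)}


def _stage_pgs(config, sim_config, state, out):
    cohort = state["cohort"]
    # demonstrate score arithmetic on a small SNP panel
    dosages, alleles, weights = simulate_snp_panel(len(cohort), n_snps=100, seed=config.seed)
    dosages.index = cohort.index
    panel = compute_pgs(dosages, alleles, weights)
    files = {
        "pgs_weights": pio.write_table(weights, out / "pgs_weights.tsv", index=False),
        "pgs_scores": pio.write_table(
            pd.DataFrame({"raw": panel.raw, "z": panel.z, "percentile": panel.percentile}),
            out / "pgs_scores.tsv",
        ),
    }
    rows = []
    for cond, geps_col in _GEPS_FOR.items():
        if cond not in state["carriers"].columns or geps_col not in cohort:
            continue
        trait, is_binary, _ = _TRAIT_FOR[cond]
        scores = cohort[geps_col]
        if cond == "low_ldl":
            scores = -scores  # inverse of the LDL-raising score
        carrier = state["carriers"][cond]
        covs = ["age", "sex"] + [f"pc{k}" for k in range(1, 11)]
        try:
            contrasts = contrast_top_tail(
                cohort, scores, trait, covariates=covs, logistic=is_binary, carrier=carrier
            )
            for label, est in contrasts.items():
                rows.append({"condition": cond, "analysis": label, "beta": est.beta,
                             "se": est.se, "p_value": est.p_value, "n": est.n_total})
        except ValueError:
            pass
        if carrier.sum() >= 14:
            est = carrier_geps_regression(cohort, carrier, scores, trait, covariates=covs,
                                          logistic=is_binary)
            rows.append({"condition": cond, "analysis": "carrier_geps", "beta": est.beta,
                         "se": est.se, "p_value": est.p_value, "n": est.n_total})
        est = interaction_test(cohort, carrier, scores, trait, covariates=covs,
                               logistic=is_binary)
        rows.append({"condition": cond, "analysis": "carrier_x_geps", "beta": est.beta,
                     "se": est.se, "p_value": est.p_value, "n": est.n_total})
    contrasts_df = pd.DataFrame(rows)
    state["pgs_contrasts"] = contrasts_df
    files["pgs_contrasts"] = pio.write_table(contrasts_df, out / "pgs_contrasts.tsv", index=False)
    return files


def _stage_ascertain(config, sim_config, state, out):
    cohort = state["cohort"]
    cond = next((c for c in sim_config.conditions if c.name == "high_ldl"), None)
    rows = []
    if cond is not None and state["carriers"]["high_ldl"].any():
        mu = sim_config.trait_means["ldl"] + cond.effect
        sigma = sim_config.trait_sds["ldl"]
        c = ascertainment_contrast(
            cohort, state["carriers"]["high_ldl"], "ldl",
            tail=config.ascertainment_tail, side="upper",
            carrier_mu=mu, carrier_sigma=sigma,
        )
        rows.append(vars(c))
    df = pd.DataFrame(rows)
    state["ascertainment"] = df
    return {"ascertainment": pio.write_table(df, out / "ascertainment.tsv", index=False)}


def _stage_power(config, sim_config, state, out):
    n98 = n_for_correlation(PowerQuery(r=0.25, power=0.8, alpha=0.05, sided="one"))
    rows = [
        {"quantity": "carriers_for_r0.25_power0.8_alpha0.05_one_sided", "value": n98},
        {"quantity": "cohort_size_at_prevalence_1e-4", "value": required_cohort_size(n98, 1e-4)},
    ]
    df = pd.DataFrame(rows)
    state["power"] = df
    return {"power": pio.write_table(df, out / "power.tsv", index=False)}
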