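"""Polygenic score application and monogenic-vs-polygenic contrasts.

A global extended polygenic score (gePS) is a weighted sum of common-variant
allele dosages, standardized to mean 0 / SD 1 over the analysis cohort.  The
module scores genotypes against a weight table (reconciling effect alleles and
mean-imputing missing dosages), contrasts the top-1 % score tail against the
interquartile range and against monogenic variant carriers, regresses
phenotype on the score within carriers only, tests a carrier x gePS
interaction, and provides the two planning calculations: the normal-tail
fraction polygenically equivalent to a monogenic effect, and the Fisher-z
carrier count needed to detect a trait-score correlation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, stats

from .association import EffectEstimate

__all__ = [
    "PgsResult",
    "PowerQuery",
    "TailEquivalence",
    "compute_pgs",
    "contrast_top_tail",
    "carrier_geps_regression",
    "interaction_test",
    "equivalent_tail_fraction",
    "n_for_correlation",
    "required_cohort_size",
]


@dataclass
class PgsResult:
    raw: pd.Series
    z: pd.Series
    percentile: pd.Series  # 1-100 bins
    orientation: int = 1
    n_variants_used: int = 0

    def inverted(self) -> "PgsResult":
        """Sign-flipped score (e.g. LDL-raising score reused for low-LDL analyses)."""
        z = -self.z
        pct = pd.Series(
            pd.qcut(z.rank(method="first"), 100, labels=False) + 1, index=z.index
        )
        return PgsResult(-self.raw, z, pct, -self.orientation, self.n_variants_used)


def compute_pgs(
    dosages: pd.DataFrame,
    variant_alleles: pd.DataFrame,
    weights: pd.DataFrame,
) -> PgsResult:
    """Score individuals as the weighted sum of effect-allele dosages.

    ``dosages`` is individuals x variant_id (0/1/2, NaN missing, counting the
    alt allele); ``variant_alleles`` maps variant_id -> ref, alt;
    ``weights`` has columns variant_id, effect_allele, weight.  Weights whose
    effect allele is the ref allele are applied to the flipped dosage 2 - d,
    so allele-flipped weight files score identically.  Missing dosages are
    mean-imputed per variant.  Scores are standardized over the cohort.
    """
    alleles = variant_alleles.set_index("variant_id")
    w = weights.set_index("variant_id")
    shared = [v for v in w.index if v in dosages.columns and v in alleles.index]
    if not shared:
        raise ValueError("no overlapping variants between dosages and weight table")
    raw = pd.Series(0.0, index=dosages.index)
    used = 0
    for vid in shared:
        eff = w.at[vid, "effect_allele"]
        weight = float(w.at[vid, "weight"])
        d = dosages[vid].astype(float)
        d = d.fillna(d.mean())
        if eff == alleles.at[vid, "alt"]:
            raw = raw + weight * d
        elif eff == alleles.at[vid, "ref"]:
            raw = raw + weight * (2.0 - d)
        else:
            continue
        used += 1
    if used == 0:
        raise ValueError("no weight could be reconciled to either allele")
    sd = raw.std(ddof=0)
    z = (raw - raw.mean()) / sd if sd > 0 else raw * 0.0
    pct = pd.Series(pd.qcut(z.rank(method="first"), 100, labels=False) + 1, index=z.index)
    return PgsResult(raw=raw, z=z, percentile=pct, n_variants_used=used)


def _glm(y, X, logistic):
    if logistic:
        return sm.GLM(y, X, family=sm.families.Binomial()).fit()
    return sm.OLS(y, X).fit()


def _estimate(res, term, n_carriers, n_total, covariates, method):
    ci = res.conf_int().loc[term]
    return EffectEstimate(
        beta=float(res.params[term]),
        se=float(res.bse[term]),
        p_value=float(res.pvalues[term]),
        ci=(float(ci[0]), float(ci[1])),
        n_carriers=n_carriers,
        n_total=n_total,
        covariates=covariates,
        method=method,
    )


def contrast_top_tail(
    cohort: pd.DataFrame,
    scores: pd.Series,
    phenotype: str,
    tail: float = 0.01,
    reference: tuple[float, float] = (0.25, 0.75),
    age_min: float = 60,
    covariates: list[str] | None = None,
    logistic: bool = False,
    carrier: pd.Series | None = None,
) -> dict[str, EffectEstimate]:
    """Top-score-tail vs interquartile-range phenotype contrast.

    The analysis subset is restricted to age >= ``age_min`` (a polygenic score
    predicts lifetime risk, so younger individuals dilute the contrast) and
    percentiles are assigned within that subset.  Returns the tail-vs-IQR
    estimate and, when carrier flags are given, a carrier-vs-top-tail
    contrast on the same phenotype.
    """
    subset = cohort[cohort["age"] >= age_min]
    if subset.empty:
        raise ValueError("empty analysis subset after age filter")
    z = scores.loc[subset.index]
    lo, hi = z.quantile(reference[0]), z.quantile(reference[1])
    top_cut = z.quantile(1 - tail)
    in_top = z > top_cut
    in_ref = (z >= lo) & (z <= hi)
    if not in_top.any():
        raise ValueError("empty top tail after age filter")
    covariates = covariates or []
    out: dict[str, EffectEstimate] = {}

    ana = subset[in_top | in_ref]
    y = ana[phenotype].astype(float)
    X = pd.DataFrame({"const": 1.0, "top_tail": in_top[ana.index].astype(float)})
    for c in covariates:
        X[c] = ana[c].astype(float)
    res = _glm(y, X, logistic)
    out["tail_vs_iqr"] = _estimate(
        res, "top_tail", int(in_top.sum()), len(ana), covariates,
        "logistic" if logistic else "ols",
    )

    if carrier is not None:
        carr = carrier.loc[subset.index].astype(bool)
        grp = subset[carr | in_top]
        y2 = grp[phenotype].astype(float)
        X2 = pd.DataFrame({"const": 1.0, "carrier": carr[grp.index].astype(float)})
        for c in covariates:
            X2[c] = grp[c].astype(float)
        res2 = _glm(y2, X2, logistic)
        out["carrier_vs_tail"] = _estimate(
            res2, "carrier", int(carr.sum()), len(grp), covariates,
            "logistic" if logistic else "ols",
        )
    return out


def carrier_geps_regression(
    cohort: pd.DataFrame,
    carrier: pd.Series,
    scores: pd.Series,
    phenotype: str,
    covariates: list[str] | None = None,
    logistic: bool = False,
) -> EffectEstimate:
    """Phenotype on standardized gePS within carriers only (expressivity model)."""
    covariates = covariates or []
    idx = cohort.index[carrier.astype(bool)]
    if len(idx) < len(covariates) + 2:
        raise ValueError(
            f"{len(idx)} carriers cannot support {len(covariates)} covariates + slope"
        )
    sub = cohort.loc[idx]
    y = sub[phenotype].astype(float)
    X = pd.DataFrame({"const": 1.0, "geps": scores.loc[idx].astype(float)})
    for c in covariates:
        X[c] = sub[c].astype(float)
    res = _glm(y, X, logistic)
    return _estimate(res, "geps", len(idx), len(idx), covariates,
                     "logistic" if logistic else "ols")


def interaction_test(
    cohort: pd.DataFrame,
    carrier: pd.Series,
    scores: pd.Series,
    phenotype: str,
    covariates: list[str] | None = None,
    logistic: bool = False,
) -> EffectEstimate:
    """Carrier x gePS product-term test with main effects and covariates."""
    covariates = covariates or []
    carr = carrier.astype(float)
    if carr.nunique() < 2:
        raise ValueError("both carriers and non-carriers required")
    y = cohort[phenotype].astype(float)
    X = pd.DataFrame(
        {
            "const": 1.0,
            "carrier": carr,
            "geps": scores.astype(float),
            "carrier_x_geps": carr * scores.astype(float),
        }
    )
    for c in covariates:
        X[c] = cohort[c].astype(float)
    res = _glm(y, X, logistic)
    return _estimate(res, "carrier_x_geps", int(carr.sum()), len(y), covariates,
                     "logistic" if logistic else "ols")


# ---------------------------------------------------------------------------
# planning calculations
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PowerQuery:
    r: float
    power: float = 0.8
    alpha: float = 0.05
    sided: str = "one"  # 'one' | 'two'

    def __post_init__(self):
        if not 0 < self.r < 1:
            raise ValueError("r must lie in (0, 1)")
        if not 0 < self.power < 1:
            raise ValueError("power must lie in (0, 1)")
        if not 0 < self.alpha < 0.5:
            raise ValueError("alpha must lie in (0, 0.5)")


@dataclass(frozen=True)
class TailEquivalence:
    h2: float
    trait_sd: float
    target_shift: float
    q: float
    top_tail_mean_shift: float


def _tail_mean_shift(q: float, h2: float, trait_sd: float) -> float:
    """Mean excess of the top-q fraction of a polygenic score explaining h2."""
    zq = stats.norm.ppf(1 - q)
    return np.sqrt(h2) * trait_sd * stats.norm.pdf(zq) / q


def equivalent_tail_fraction(
    h2: float, trait_sd: float, target_shift: float, q_min: float = 1e-8
) -> TailEquivalence:
    """Tail fraction whose mean polygenic shift equals a monogenic effect.

    Solves sqrt(h2) * sd * phi(z_q) / q = target_shift for q in (q_min, 0.5],
    i.e. how selective one must be on the polygenic score before the selected
    group's expected trait mean matches the carrier mean shift.
    """
    if not 0 < h2 < 1:
        raise ValueError("h2 must lie in (0, 1)")
    if trait_sd <= 0 or target_shift <= 0:
        raise ValueError("trait_sd and target_shift must be positive")
    f = lambda q: _tail_mean_shift(q, h2, trait_sd) - target_shift
    if f(q_min) < 0:
        raise ValueError(
            f"shift {target_shift} unattainable: even the top {q_min:g} tail "
            f"averages only {_tail_mean_shift(q_min, h2, trait_sd):.3g}"
        )
    if f(0.5) >= 0:
        q = 0.5
    else:
        q = optimize.brentq(f, q_min, 0.5, xtol=1e-12, rtol=1e-12)
    return TailEquivalence(h2, trait_sd, target_shift, float(q),
                           float(_tail_mean_shift(q, h2, trait_sd)))


def n_for_correlation(query: PowerQuery) -> int:
    """Minimum sample size to detect a correlation, Fisher-z approximation.

    n = ceil( ((z_{1-alpha} + z_{power}) / atanh(r))^2 + 3 ), with
    z_{1-alpha} replaced by z_{1-alpha/2} for a two-sided test.
    """
    alpha = query.alpha if query.sided == "one" else query.alpha / 2
    za = stats.norm.ppf(1 - alpha)
    zb = stats.norm.ppf(query.power)
    n = np.ceil(((za + zb) / np.arctanh(query.r)) ** 2 + 3)
    return int(n)


def required_cohort_size(n_carriers: int, prevalence: float) -> int:
    """Population cohort size needed to observe a target carrier count."""
    if not 0 < prevalence <= 1:
        raise ValueError("prevalence must lie in (0, 1]")
    if n_carriers < 1:
        raise ValueError("n_carriers must be >= 1")
    return int(np.ceil(n_carriers / prevalence))
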