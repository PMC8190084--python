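"""Phenotypic-ascertainment bias under a truncated-normal model.

Cohorts recruited for extreme biomarker values (e.g. LDL beyond the 98th or
below the 2nd population percentile) over-represent the upper tail of the
carrier trait distribution.  If carrier trait values are N(mu, sigma^2) and
selection keeps values above a threshold t, the selected carrier mean is the
truncated-normal expectation mu + sigma * phi(a) / (1 - Phi(a)), a = (t -
mu)/sigma.  The module provides this closed form, and an empirical contrast
that compares ascertained with unascertained carriers of the same variants
and reports both the ascertainment-induced difference and the apparent
carrier effect a phenotypically ascertained sample would suggest.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["AscertainmentContrast", "truncated_mean", "ascertainment_contrast", "strip_chart"]


@dataclass(frozen=True)
class AscertainmentContrast:
    trait: str
    threshold: float
    side: str
    mean_ascertained: float
    mean_unascertained: float
    difference: float  # ascertained - unascertained carrier means
    expected_difference_closed_form: float | None
    mean_noncarrier: float
    apparent_effect_ascertained: float  # ascertained carrier mean - non-carrier mean
    true_effect: float  # unascertained carrier mean - non-carrier mean
    n_ascertained: int
    n_unascertained: int


def truncated_mean(mu: float, sigma: float, threshold: float, side: str = "upper") -> float:
    """Expected value of N(mu, sigma^2) conditional on crossing ``threshold``.

    ``side='upper'`` conditions on X > threshold, ``'lower'`` on X < threshold.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    a = (threshold - mu) / sigma
    if side == "upper":
        return mu + sigma * stats.norm.pdf(a) / stats.norm.sf(a)
    if side == "lower":
        return mu - sigma * stats.norm.pdf(a) / stats.norm.cdf(a)
    raise ValueError("side must be 'upper' or 'lower'")


def ascertainment_contrast(
    cohort: pd.DataFrame,
    carrier: pd.Series,
    trait: str,
    tail: float = 0.02,
    side: str = "upper",
    carrier_mu: float | None = None,
    carrier_sigma: float | None = None,
) -> AscertainmentContrast:
    """Contrast carrier trait means under phenotypic vs genetic ascertainment.

    Selection keeps individuals beyond the empirical population ``tail``
    quantile of ``trait`` (blind to carrier status).  Carriers inside the
    selected stratum play the phenotypically ascertained group; all carriers
    play the genetically ascertained (population) group.  If the carrier
    distribution parameters are known (simulator ground truth) the closed-form
    expected difference is reported alongside the empirical one.
    """
    if trait not in cohort.columns:
        raise ValueError(f"trait {trait!r} absent from cohort")
    if not 0 < tail < 0.5:
        raise ValueError("tail fraction must lie in (0, 0.5)")
    values = cohort[trait].to_numpy(dtype=float)
    carrier = carrier.astype(bool).to_numpy()
    q = 1 - tail if side == "upper" else tail
    threshold = float(np.quantile(values, q))
    selected = values > threshold if side == "upper" else values < threshold

    asc = values[selected & carrier]
    unasc = values[carrier]
    nonc = values[~carrier]
    if asc.size == 0 or unasc.size == 0:
        raise ValueError("empty carrier stratum under this selection scheme")

    expected = None
    if carrier_mu is not None and carrier_sigma is not None:
        expected = truncated_mean(carrier_mu, carrier_sigma, threshold, side) - carrier_mu

    mean_asc = float(asc.mean())
    mean_unasc = float(unasc.mean())
    mean_nonc = float(nonc.mean())
    return AscertainmentContrast(
        trait=trait,
        threshold=threshold,
        side=side,
        mean_ascertained=mean_asc,
        mean_unascertained=mean_unasc,
        difference=mean_asc - mean_unasc,
        expected_difference_closed_form=expected,
        mean_noncarrier=mean_nonc,
        apparent_effect_ascertained=mean_asc - mean_nonc,
        true_effect=mean_unasc - mean_nonc,
        n_ascertained=int(asc.size),
        n_unascertained=int(unasc.size),
    )


def strip_chart(cohort: pd.DataFrame, carrier: pd.Series, trait: str, tail: float = 0.02,
                side: str = "upper", ax=None):
    """Strip chart of trait values: non-carriers, unascertained and ascertained carriers."""
    import matplotlib.pyplot as plt

    values = cohort[trait].to_numpy(dtype=float)
    carrier = carrier.astype(bool).to_numpy()
    q = 1 - tail if side == "upper" else tail
    threshold = np.quantile(values, q)
    selected = values > threshold if side == "upper" else values < threshold
    groups = {
        "non-carriers": values[~carrier],
        "carriers\n(genetic asc.)": values[carrier],
        "carriers\n(phenotypic asc.)": values[selected & carrier],
    }
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    rng = np.random.default_rng(0)
    for i, (label, vals) in enumerate(groups.items()):
        x = rng.normal(i, 0.06, size=vals.size)
        ax.plot(x, vals, ".", alpha=0.4, markersize=3)
        ax.plot(i, vals.mean(), "k_", markersize=20)
    ax.axhline(threshold, ls="--", color="grey", lw=0.8)
    ax.set_xticks(range(len(groups)), groups)
    ax.set_ylabel(trait)
    return ax
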