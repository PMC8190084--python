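"""Penetrance estimation with exact binomial confidence intervals.

Penetrance is the proportion of carriers of a clinically significant variant
who exhibit the expected condition.  Carrier counts here are tiny (7-90 per
condition), so intervals are exact Clopper-Pearson rather than asymptotic:
lower = BetaInv(alpha/2; k, n-k+1), upper = BetaInv(1-alpha/2; k+1, n-k),
with the conventional closed ends at k=0 and k=n.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd
from scipy import stats

__all__ = ["PenetranceEstimate", "clopper_pearson", "penetrance_table"]


@dataclass(frozen=True)
class PenetranceEstimate:
    condition: str
    group: str  # gene symbol or 'composite'
    outcome: str
    k: int
    n: int
    point: float
    ci: tuple[float, float]
    level: float = 0.95


def clopper_pearson(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Exact two-sided binomial confidence interval for k successes of n."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= k <= n:
        raise ValueError("k must lie in [0, n]")
    alpha = 1.0 - level
    lower = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2, k, n - k + 1))
    upper = 1.0 if k == n else float(stats.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return lower, upper


def penetrance_table(
    carriers: pd.DataFrame,
    cases: Mapping[str, pd.Series] | pd.DataFrame,
    gene_sets: Mapping[str, Mapping[str, Sequence[str]]] | None = None,
    gene_carriers: Mapping[str, pd.DataFrame] | None = None,
    level: float = 0.95,
) -> pd.DataFrame:
    """Per-condition (and optionally per-gene) penetrance estimates.

    Parameters
    ----------
    carriers
        individuals x conditions boolean carrier flags (composite gene sets).
    cases
        per-condition nullable-boolean case flags aligned to the same index;
        <NA> marks an indeterminate phenotype, which removes the carrier from
        the denominator rather than being imputed.
    gene_carriers
        optional mapping condition -> (individuals x gene) carrier flags, to
        emit per-gene rows alongside the composite.

    Rows with zero evaluable carriers are omitted with a warning.
    """
    rows = []

    def _one(condition: str, group: str, carrier: pd.Series, case: pd.Series):
        case = case.astype("boolean")
        evaluable = carrier.astype(bool) & case.notna()
        n = int(evaluable.sum())
        if n == 0:
            warnings.warn(f"{condition}/{group}: zero evaluable carriers, row omitted")
            return
        k = int((case[evaluable].astype(bool)).sum())
        lo, hi = clopper_pearson(k, n, level)
        rows.append(
            {
                "condition": condition,
                "group": group,
                "outcome": case.name or condition,
                "k": k,
                "n": n,
                "point": k / n,
                "lower": lo,
                "upper": hi,
                "level": level,
            }
        )

    for condition in carriers.columns:
        if condition not in cases:
            continue
        _one(condition, "composite", carriers[condition], cases[condition])
        if gene_carriers and condition in gene_carriers:
            gdf = gene_carriers[condition]
            for gene in gdf.columns:
                _one(condition, gene, gdf[gene], cases[condition])
    return pd.DataFrame(rows)
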