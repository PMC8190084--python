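"""Phenotype harmonization: medication adjustment, units, glycemia, dichotomization.

Lipid values measured on treatment understate the underlying biology; the
standard correction divides observed LDL by 0.7 and triglycerides by 0.85 for
individuals on lipid-lowering medication.  Glycemic status uses ADA-style
cut-offs (diabetes: HbA1c >= 6.5 % or an explicit record flag; prediabetes:
HbA1c >= 5.7 %, fasting glucose >= 100 mg/dL, or 2-h OGTT >= 140 mg/dL).
Continuous biomarkers are dichotomized at clinical diagnosis thresholds with
inclusive boundaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "HarmonizationConfig",
    "adjust_lipids",
    "convert_units",
    "classify_glycemia",
    "dichotomize",
    "harmonize_cohort",
    "MMOL_TO_MGDL_CHOL",
    "MMOL_TO_MGDL_TG",
]

MMOL_TO_MGDL_CHOL = 38.67
MMOL_TO_MGDL_TG = 88.57

_DEFAULT_THRESHOLDS: dict[str, tuple[str, str, float]] = {
    # condition -> (trait column, direction, threshold); boundaries inclusive
    "high_ldl": ("ldl", ">=", 190.0),
    "low_ldl": ("ldl", "<=", 80.0),
    "high_hdl": ("hdl", ">=", 70.0),
    "high_tg": ("tg", ">=", 200.0),
    "obesity": ("bmi", ">=", 30.0),
}


@dataclass(frozen=True)
class HarmonizationConfig:
    statin_ldl_divisor: float = 0.7
    statin_tg_divisor: float = 0.85
    thresholds: Mapping[str, tuple[str, str, float]] = field(
        default_factory=lambda: dict(_DEFAULT_THRESHOLDS)
    )
    diabetes_hba1c: float = 6.5
    prediabetes_hba1c: float = 5.7
    prediabetes_fasting_glucose: float = 100.0
    prediabetes_ogtt_2h: float = 140.0

    def __post_init__(self):
        if not (0 < self.statin_ldl_divisor <= 1 and 0 < self.statin_tg_divisor <= 1):
            raise ValueError("medication divisors must lie in (0, 1]")


def adjust_lipids(value, trait: str, on_medication, config: HarmonizationConfig = HarmonizationConfig()):
    """Undo the expected treatment effect on LDL or TG for treated individuals.

    HDL is never adjusted. Accepts scalars or aligned arrays/Series.
    """
    trait = trait.lower()
    if trait == "ldl":
        divisor = config.statin_ldl_divisor
    elif trait == "tg":
        divisor = config.statin_tg_divisor
    else:
        raise ValueError(f"no medication adjustment defined for trait {trait!r}")
    value = np.asarray(value, dtype=float) if not np.isscalar(value) else value
    med = np.asarray(on_medication, dtype=bool) if not np.isscalar(on_medication) else bool(on_medication)
    return np.where(med, np.asarray(value) / divisor, value) if not np.isscalar(value) else (value / divisor if med else value)


def convert_units(value, trait: str):
    """mmol/L -> mg/dL for lipids (cholesterol x38.67, triglycerides x88.57)."""
    trait = trait.lower()
    if trait in ("ldl", "hdl", "cholesterol", "total_cholesterol"):
        return np.asarray(value) * MMOL_TO_MGDL_CHOL if not np.isscalar(value) else value * MMOL_TO_MGDL_CHOL
    if trait in ("tg", "triglycerides"):
        return np.asarray(value) * MMOL_TO_MGDL_TG if not np.isscalar(value) else value * MMOL_TO_MGDL_TG
    raise ValueError(f"unknown trait for unit conversion: {trait!r}")


def _missing(x) -> bool:
    return x is None or (isinstance(x, float) and math.isnan(x))


def classify_glycemia(
    hba1c=None,
    fasting_glucose=None,
    ogtt_2h=None,
    record_diabetes: bool = False,
    config: HarmonizationConfig = HarmonizationConfig(),
) -> str:
    """Classify one individual as diabetes / prediabetes / normoglycemic.

    Missing inputs are skipped; if every input is missing and no record flag
    is set the status is 'indeterminate' and the individual is excluded from
    penetrance denominators downstream.
    """
    inputs = [hba1c, fasting_glucose, ogtt_2h]
    if all(_missing(x) for x in inputs) and not record_diabetes:
        return "indeterminate"
    if record_diabetes or (not _missing(hba1c) and hba1c >= config.diabetes_hba1c):
        return "diabetes"
    if (
        (not _missing(hba1c) and hba1c >= config.prediabetes_hba1c)
        or (not _missing(fasting_glucose) and fasting_glucose >= config.prediabetes_fasting_glucose)
        or (not _missing(ogtt_2h) and ogtt_2h >= config.prediabetes_ogtt_2h)
    ):
        return "prediabetes"
    return "normoglycemic"


def dichotomize(
    cohort: pd.DataFrame, condition: str, config: HarmonizationConfig = HarmonizationConfig()
) -> pd.Series:
    """Case flags for a condition from harmonized trait values.

    Returns a nullable boolean Series; missing trait values yield <NA> and
    are excluded from penetrance denominators.
    """
    if condition not in config.thresholds:
        raise ValueError(f"no dichotomization threshold for condition {condition!r}")
    trait, op, cut = config.thresholds[condition]
    if trait not in cohort.columns:
        raise ValueError(f"trait column {trait!r} absent from cohort")
    vals = cohort[trait]
    flags = vals >= cut if op == ">=" else vals <= cut
    return flags.astype("boolean").mask(vals.isna())


def harmonize_cohort(
    cohort: pd.DataFrame, config: HarmonizationConfig = HarmonizationConfig()
) -> pd.DataFrame:
    """Apply medication adjustment and glycemia classification to a cohort table.

    Expects observed (possibly treatment-masked) ``ldl``/``tg`` plus an
    ``on_lipid_med`` flag; adds/overwrites harmonized lipid columns in place
    of the observed ones, a ``glycemia`` status column and boolean
    ``diabetes``/``prediabetes`` flags.  Idempotent once ``on_lipid_med`` is
    consumed: the function records adjustment in ``lipids_adjusted`` and will
    not re-divide on a second call.
    """
    out = cohort.copy()
    if not out.attrs.get("lipids_adjusted", False):
        med = out["on_lipid_med"].astype(bool).to_numpy()
        out["ldl"] = np.where(med, out["ldl"] / config.statin_ldl_divisor, out["ldl"])
        out["tg"] = np.where(med, out["tg"] / config.statin_tg_divisor, out["tg"])
        out.attrs["lipids_adjusted"] = True
    record = (
        out["diabetes_record_flag"].astype(bool)
        if "diabetes_record_flag" in out
        else pd.Series(False, index=out.index)
    )
    ogtt = out["ogtt_2h"] if "ogtt_2h" in out else pd.Series(np.nan, index=out.index)
    out["glycemia"] = [
        classify_glycemia(h, g, o, r, config)
        for h, g, o, r in zip(out["hba1c"], out["fasting_glucose"], ogtt, record)
    ]
    out["diabetes"] = out["glycemia"] == "diabetes"
    out["prediabetes"] = out["glycemia"] == "prediabetes"
    return out
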