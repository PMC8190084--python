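"""Deterministic clinical variant triage.

Re-implements, as pure functions, the curation pipeline used to call carriers of
clinically significant variants in autosomal-dominant metabolic-disease genes:

* genotype-level QC (genotype quality, depth, allele balance),
* a ClinVar triage that trusts recent assertions from high-volume clinical
  testing laboratories, gated on a cohort-adjusted gnomAD allele frequency,
* a five-category predicted loss-of-function (pLoF) rule engine encoding
  nonsense-mediated-decay escape, the >25 %-of-CDS truncation override,
  in-frame splice-site rescue windows, expression (pext) downgrades and
  site-level quality flags,
* assembly of per-individual, per-condition carrier flags from triage
  decisions, genotype matrices and composite gene sets.

Every function is deterministic: identical inputs yield an identical class and
an identically ordered evidence trail.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field
from datetime import date
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "GenotypeCall",
    "VariantRecord",
    "TranscriptModel",
    "ClinVarSubmission",
    "TriageDecision",
    "Decision",
    "LofClass",
    "PlofConfig",
    "SpliceContext",
    "filter_genotype",
    "build_lab_registry",
    "adjusted_af",
    "triage_clinvar",
    "classify_plof",
    "carrier_matrix",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

class Decision(str, enum.Enum):
    CLINICALLY_SIGNIFICANT = "clinically_significant"
    EXCLUDED = "excluded"
    MANUAL_REVIEW = "manual_review"


class LofClass(str, enum.Enum):
    """Five-category loss-of-function confidence scale, best to worst."""

    LOF = "LoF"
    LIKELY_LOF = "likely_LoF"
    UNCERTAIN = "uncertain"
    LIKELY_NOT_LOF = "likely_not_LoF"
    NOT_LOF = "not_LoF"


_LOF_ORDER = [
    LofClass.LOF,
    LofClass.LIKELY_LOF,
    LofClass.UNCERTAIN,
    LofClass.LIKELY_NOT_LOF,
    LofClass.NOT_LOF,
]

#: classes that qualify an individual as a carrier downstream
QUALIFYING_LOF = frozenset({LofClass.LOF, LofClass.LIKELY_LOF})


def _downgrade(cls: LofClass, steps: int) -> LofClass:
    idx = min(_LOF_ORDER.index(cls) + steps, len(_LOF_ORDER) - 1)
    return _LOF_ORDER[idx]


@dataclass(frozen=True)
class GenotypeCall:
    gt: str  # hom_ref | het | hom_alt | missing
    gq: float
    dp: float
    ad: tuple[int, int]  # (ref reads, alt reads)


@dataclass(frozen=True)
class VariantRecord:
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    gene: str
    consequence: str  # stop_gained | frameshift | splice_donor | splice_acceptor | missense | other
    loftee: str = "none"  # HC | LC | none
    pext: float | None = None
    gnomad_ac: int = 0
    gnomad_an: int = 0
    gnomad_filter_flag: bool = False
    site_blacklisted: bool = False
    variant_id: str = ""

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError("pos must be 1-based and positive")
        if self.pext is not None and not (0.0 <= self.pext <= 1.0):
            raise ValueError("pext must lie in [0, 1]")
        if self.gnomad_an and self.gnomad_ac > self.gnomad_an:
            raise ValueError("gnomad_ac cannot exceed gnomad_an")
        if not self.variant_id:
            object.__setattr__(
                self, "variant_id", f"{self.chrom}-{self.pos}-{self.ref}-{self.alt}"
            )


@dataclass(frozen=True)
class TranscriptModel:
    """Coding transcript as ordered CDS exon intervals.

    ``exons`` are 1-based closed genomic intervals listed 5'→3' in transcript
    orientation (so for a minus-strand gene the first interval has the largest
    coordinates).  The intervals are treated as coding sequence; ``cds_length``
    must equal their summed length.
    """

    gene: str
    strand: str  # '+' | '-'
    exons: tuple[tuple[int, int], ...]
    cds_length: int

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")
        total = sum(e - s + 1 for s, e in self.exons)
        if total != self.cds_length:
            raise ValueError(
                f"cds_length {self.cds_length} != summed exon length {total}"
            )

    def cds_position(self, pos: int) -> int:
        """1-based coding coordinate of a genomic position, or raise."""
        offset = 0
        for start, end in self.exons:
            if start <= pos <= end:
                within = (pos - start) if self.strand == "+" else (end - pos)
                return offset + within + 1
            offset += end - start + 1
        raise ValueError(f"position {pos} outside transcript of {self.gene}")

    def truncated_fraction(self, pos: int) -> float:
        """Fraction of the CDS at or 3' of ``pos`` (lost to a truncation)."""
        cp = self.cds_position(pos)
        return (self.cds_length - cp + 1) / self.cds_length

    def in_nmd_escape(self, pos: int) -> bool:
        """True in the last exon or the final 50 bp of the penultimate exon."""
        cp = self.cds_position(pos)
        last_len = self.exons[-1][1] - self.exons[-1][0] + 1
        return cp > self.cds_length - last_len - 50


@dataclass(frozen=True)
class ClinVarSubmission:
    lab: str
    significance: str  # P | LP | VUS | LB | B
    date_reported: date
    phenotype: str = ""
    n_total_lab_submissions: int = 0
    last_update: date | None = None


@dataclass(frozen=True)
class SpliceContext:
    """Nearest in-frame alternative splice site around a splice variant."""

    inframe_site_distance_bp: int | None = None
    validated: bool = False


@dataclass
class TriageDecision:
    decision: Decision
    evidence: list[str] = field(default_factory=list)
    lof_class: LofClass | None = None


@dataclass(frozen=True)
class PlofConfig:
    """Tunables of the pLoF rule engine.

    ``pext_low_threshold`` flags poorly expressed exons; the cut-off is a
    package choice (supplementary curation data is not machine-readable) and
    should be set per analysis.
    """

    pext_low_threshold: float = 0.1
    nmd_override_fraction: float = 0.25
    essential_rescue_bp: int = 6
    possible_rescue_bp: int = 21


# ---------------------------------------------------------------------------
# genotype QC
# ---------------------------------------------------------------------------

def filter_genotype(
    call: GenotypeCall, min_gq: float = 20, min_dp: float = 10, min_balance: float = 0.25
) -> bool:
    """High-quality genotype filter.

    Pass requires GQ >= 20 and DP >= 10; heterozygous calls additionally
    require minor allele balance min(ref, alt)/(ref+alt) > 0.25.  A failing
    genotype is treated as missing downstream, never as an error.
    """
    if call.gt == "missing":
        return False
    if call.gq < min_gq or call.dp < min_dp:
        return False
    if call.gt == "het":
        ref, alt = call.ad
        total = ref + alt
        if total == 0:
            return False
        if min(ref, alt) / total <= min_balance:
            return False
    return True


# ---------------------------------------------------------------------------
# ClinVar triage
# ---------------------------------------------------------------------------

def build_lab_registry(
    submission_summary: pd.DataFrame,
    min_submissions: int = 15_000,
    updated_since: date = date(2017, 1, 1),
    manual_exclusions: Iterable[str] = ("Counsyl",),
) -> set[str]:
    """High-confidence clinical testing laboratories.

    A lab qualifies if it has submitted more than ``min_submissions`` variants
    and last updated its submissions on or after ``updated_since`` (post the
    current ACMG interpretation guidelines).  Labs on the manual-exclusion
    list are removed regardless (conflicting phenotype assertions are curated
    by hand instead).

    ``submission_summary`` columns: lab, n_total_lab_submissions, last_update.
    """
    if submission_summary.empty:
        warnings.warn("empty submission summary: registry is empty")
        return set()
    df = submission_summary
    last = pd.to_datetime(df["last_update"]).dt.date
    keep = (df["n_total_lab_submissions"] > min_submissions) & (last >= updated_since)
    registry = set(df.loc[keep, "lab"]) - set(manual_exclusions)
    return registry


def adjusted_af(gnomad_ac: int, cohort_carrier_count: int, gnomad_an: int) -> float:
    """Cohort-adjusted gnomAD allele frequency.

    Study cohorts overlapping gnomAD inflate its allele counts, so the
    cohort's own carriers are subtracted before computing the frequency,
    floored at zero.
    """
    if gnomad_an <= 0:
        raise ValueError("gnomad_an must be positive to define a frequency")
    if gnomad_ac < 0 or cohort_carrier_count < 0:
        raise ValueError("allele counts must be non-negative")
    return max(gnomad_ac - cohort_carrier_count, 0) / gnomad_an


_PATHOGENIC = {"P", "LP"}
_BENIGN = {"B", "LB"}


def triage_clinvar(
    variant: VariantRecord,
    submissions: Sequence[ClinVarSubmission],
    registry: set[str],
    cohort_carrier_count: int = 0,
    af_cutoff: float | None = None,
    accepted_since: date = date(2017, 1, 1),
) -> TriageDecision:
    """Accept, exclude, or defer a variant based on ClinVar assertions.

    The allele-frequency gate runs first: if the cohort-adjusted gnomAD
    frequency exceeds the per-condition cut-off the variant is excluded
    outright.  Otherwise P/LP from a registry lab dated on/after
    ``accepted_since`` is accepted, registry B/LB (same recency) excludes,
    conflicting registry assertions or no qualifying registry assertion defer
    to manual review.
    """
    evidence: list[str] = []
    if af_cutoff is not None and variant.gnomad_an > 0:
        af = adjusted_af(variant.gnomad_ac, cohort_carrier_count, variant.gnomad_an)
        if af > af_cutoff:
            evidence.append(
                f"adjusted_af {af:.3g} exceeds condition cut-off {af_cutoff:.3g}"
            )
            return TriageDecision(Decision.EXCLUDED, evidence)
        evidence.append(f"adjusted_af {af:.3g} within cut-off {af_cutoff:.3g}")

    qualifying = [
        s
        for s in submissions
        if s.lab in registry and s.date_reported >= accepted_since
    ]
    has_path = any(s.significance in _PATHOGENIC for s in qualifying)
    has_benign = any(s.significance in _BENIGN for s in qualifying)

    if has_path and has_benign:
        evidence.append("conflicting registry assertions (P/LP vs B/LB)")
        return TriageDecision(Decision.MANUAL_REVIEW, evidence)
    if has_path:
        labs = sorted({s.lab for s in qualifying if s.significance in _PATHOGENIC})
        evidence.append(f"P/LP from registry lab(s) {','.join(labs)} since {accepted_since}")
        return TriageDecision(Decision.CLINICALLY_SIGNIFICANT, evidence)
    if has_benign:
        labs = sorted({s.lab for s in qualifying if s.significance in _BENIGN})
        evidence.append(f"B/LB from registry lab(s) {','.join(labs)} since {accepted_since}")
        return TriageDecision(Decision.EXCLUDED, evidence)
    return TriageDecision(
        Decision.MANUAL_REVIEW, evidence + ["no qualifying registry submission"]
    )


# ---------------------------------------------------------------------------
# pLoF rule engine
# ---------------------------------------------------------------------------

_TRUNCATING = {"stop_gained", "frameshift"}
_SPLICE = {"splice_donor", "splice_acceptor"}


def classify_plof(
    variant: VariantRecord,
    transcript: TranscriptModel,
    splice_context: SpliceContext | None = None,
    config: PlofConfig = PlofConfig(),
) -> tuple[LofClass, list[str]]:
    """Five-category pLoF classification with an ordered evidence trail.

    Rule order: LOFTEE gate, site blacklist, gnomAD filter flag (one-step
    downgrade), NMD-escape (not LoF unless >25 % of the CDS is truncated),
    in-frame splice rescue windows (±6 bp essential; 6–21 bp possible, rescue
    only if externally validated), and a low-pext one-step downgrade.
    """
    ev: list[str] = []
    if variant.loftee != "HC":
        return LofClass.NOT_LOF, ["LOFTEE annotation not high-confidence"]
    if variant.site_blacklisted:
        return LofClass.NOT_LOF, ["site on genotyping-quality blacklist"]

    downgrades = 0
    if variant.gnomad_filter_flag:
        downgrades += 1
        ev.append("flagged by gnomAD variant QC: downgraded one class")

    base = LofClass.LOF
    cons = variant.consequence
    if cons in _TRUNCATING:
        frac = transcript.truncated_fraction(variant.pos)
        if transcript.in_nmd_escape(variant.pos):
            if frac > config.nmd_override_fraction:
                ev.append(
                    f"NMD-escape region but truncates {frac:.0%} of CDS "
                    f"(> {config.nmd_override_fraction:.0%}): override, kept LoF"
                )
            else:
                ev.append(
                    f"NMD-escape region (last exon / final 50 bp of penultimate), "
                    f"truncates only {frac:.0%} of CDS: not LoF"
                )
                return LofClass.NOT_LOF, ev
        else:
            ev.append(f"truncation subject to NMD ({frac:.0%} of CDS lost)")
    elif cons in _SPLICE:
        d = splice_context.inframe_site_distance_bp if splice_context else None
        if d is not None and d <= config.essential_rescue_bp:
            ev.append(f"in-frame alternative splice site {d} bp away: essential rescue")
            base = LofClass.LIKELY_NOT_LOF
        elif d is not None and d <= config.possible_rescue_bp:
            if splice_context.validated:
                ev.append(
                    f"in-frame alternative site {d} bp away, externally validated rescue"
                )
                base = LofClass.LIKELY_NOT_LOF
            else:
                ev.append(
                    f"possible in-frame rescue {d} bp away, not validated: uncertain"
                )
                base = LofClass.UNCERTAIN
        else:
            ev.append("essential splice variant, no in-frame rescue within 21 bp")
    else:
        # transcript coverage check still applies for completeness
        transcript.cds_position(variant.pos)
        ev.append(f"consequence {cons} retained at face value")

    if variant.pext is None:
        ev.append("pext missing: expression rule skipped")
    elif variant.pext < config.pext_low_threshold:
        downgrades += 1
        ev.append(
            f"pext {variant.pext:.2f} below {config.pext_low_threshold:.2f}: "
            "downgraded one class"
        )

    return _downgrade(base, downgrades), ev


# ---------------------------------------------------------------------------
# carrier assembly
# ---------------------------------------------------------------------------

def carrier_matrix(
    decisions: pd.DataFrame,
    genotypes: pd.DataFrame,
    gene_sets: Mapping[str, Sequence[str]],
) -> pd.DataFrame:
    """Per-individual carrier flags per condition.

    ``decisions`` indexed by variant_id with columns ``gene`` and
    ``qualifying`` (clinically significant, or pLoF class LoF/likely LoF);
    ``genotypes`` is individuals × variant_id with alt-allele counts
    (NaN = missing/failed QC).  An individual carries a condition iff they
    have at least one non-missing alt genotype at a qualifying variant in
    that condition's gene set.  Variants assigned to no gene set are dropped
    with a warning.

    Some genes sit in two condition panels with opposite variant classes
    (APOB/PCSK9 raise LDL through gain-of-function missense but lower it
    through loss of function), so when ``decisions`` carries a ``condition``
    column a variant counts only toward that condition.
    """
    qualifying = decisions.loc[decisions["qualifying"]]
    all_genes = {g for genes in gene_sets.values() for g in genes}
    orphans = sorted(set(qualifying["gene"]) - all_genes)
    if orphans:
        warnings.warn(f"variants in genes outside every gene set ignored: {orphans}")
    has_condition = "condition" in qualifying.columns

    out = pd.DataFrame(False, index=genotypes.index, columns=list(gene_sets))
    for condition, genes in gene_sets.items():
        vids = [
            v
            for v in qualifying.index
            if qualifying.at[v, "gene"] in set(genes)
            and v in genotypes.columns
            and (not has_condition or qualifying.at[v, "condition"] == condition)
        ]
        if not vids:
            continue
        sub = genotypes[vids]
        out[condition] = (sub.fillna(0) > 0).any(axis=1)
    return out
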