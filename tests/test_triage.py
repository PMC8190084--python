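"""Variant triage: genotype QC, lab registry, ClinVar gating, pLoF rules, carriers."""

from datetime import date

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from penexome import (
    ClinVarSubmission,
    Decision,
    GenotypeCall,
    LofClass,
    PlofConfig,
    SpliceContext,
    TranscriptModel,
    VariantRecord,
    adjusted_af,
    build_lab_registry,
    carrier_matrix,
    classify_plof,
    filter_genotype,
    triage_clinvar,
)


# ---------------------------------------------------------------------------
# genotype QC
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "call,expected",
    [
        (GenotypeCall("het", gq=19, dp=30, ad=(15, 15)), False),  # GQ below 20
        (GenotypeCall("het", gq=60, dp=20, ad=(17, 3)), False),  # balance 0.15
        (GenotypeCall("hom_alt", gq=60, dp=20, ad=(0, 20)), True),  # balance het-only
        (GenotypeCall("het", gq=60, dp=20, ad=(10, 10)), True),
        (GenotypeCall("het", gq=60, dp=9, ad=(5, 4)), False),  # depth below 10
        (GenotypeCall("het", gq=60, dp=0, ad=(0, 0)), False),  # zero-depth het fails
        (GenotypeCall("missing", gq=99, dp=99, ad=(50, 49)), False),
    ],
)
def test_genotype_filter(call, expected):
    assert filter_genotype(call) is expected


def test_genotype_filter_balance_is_minor_allele():
    # reference-skewed and alt-skewed hets fail symmetrically
    assert not filter_genotype(GenotypeCall("het", gq=60, dp=20, ad=(3, 17)))
    assert not filter_genotype(GenotypeCall("het", gq=60, dp=20, ad=(17, 3)))


# ---------------------------------------------------------------------------
# lab registry
# ---------------------------------------------------------------------------

def _summary(rows):
    return pd.DataFrame(rows, columns=["lab", "n_total_lab_submissions", "last_update"])


def test_lab_registry_rules():
    summary = _summary(
        [
            ("Big", 16_000, "2018-01-01"),
            ("AlmostBig", 14_999, "2018-01-01"),
            ("Exactly", 15_000, "2018-01-01"),  # strict > threshold
            ("Stale", 30_000, "2016-12-31"),
            ("Counsyl", 30_000, "2019-01-01"),  # manual exclusion
        ]
    )
    assert build_lab_registry(summary) == {"Big"}


def test_empty_summary_warns_and_returns_empty():
    with pytest.warns(UserWarning):
        assert build_lab_registry(_summary([])) == set()


# ---------------------------------------------------------------------------
# adjusted allele frequency
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "ac,cohort,an,expected",
    [(20, 5, 250_000, 6.0e-5), (3, 5, 250_000, 0.0), (0, 0, 250_000, 0.0)],
)
def test_adjusted_af(ac, cohort, an, expected):
    assert adjusted_af(ac, cohort, an) == pytest.approx(expected)


def test_adjusted_af_zero_an_errors():
    with pytest.raises(ValueError):
        adjusted_af(1, 0, 0)


@settings(max_examples=100, derandomize=True, deadline=None)
@given(
    ac=st.integers(0, 10_000),
    cohort=st.integers(0, 10_000),
    an=st.integers(1, 1_000_000),
)
def test_adjusted_af_floored_and_bounded(ac, cohort, an):
    af = adjusted_af(ac, cohort, min(an + ac, 1_000_000) if ac > an else an)
    assert 0.0 <= af <= 1.0
    assert af <= ac / an if ac <= an else True


# ---------------------------------------------------------------------------
# ClinVar triage
# ---------------------------------------------------------------------------

def _variant(**kw):
    defaults = dict(chrom="1", pos=100, ref="A", alt="T", gene="GCK",
                    consequence="missense", gnomad_ac=2, gnomad_an=200_000)
    defaults.update(kw)
    return VariantRecord(**defaults)


def _sub(sig, day, lab="Big"):
    return ClinVarSubmission(lab=lab, significance=sig, date_reported=date.fromisoformat(day))


def test_triage_accepts_recent_registry_pathogenic():
    d = triage_clinvar(_variant(), [_sub("P", "2018-05-01")], {"Big"}, af_cutoff=1e-4)
    assert d.decision is Decision.CLINICALLY_SIGNIFICANT
    assert d.evidence  # non-empty trail whenever not manual review


def test_triage_predating_window_defers():
    d = triage_clinvar(_variant(), [_sub("P", "2016-06-01")], {"Big"}, af_cutoff=1e-4)
    assert d.decision is Decision.MANUAL_REVIEW


def test_frequency_gate_precedes_acceptance():
    v = _variant(gnomad_ac=400, gnomad_an=200_000)
    d = triage_clinvar(v, [_sub("P", "2018-05-01")], {"Big"},
                       cohort_carrier_count=2, af_cutoff=1e-4)
    assert d.decision is Decision.EXCLUDED
    assert "cut-off" in d.evidence[0]  # frequency evidence recorded first


def test_conflicting_registry_assertions_never_silently_resolved():
    d = triage_clinvar(
        _variant(), [_sub("P", "2018-05-01"), _sub("LB", "2018-06-01")], {"Big"}
    )
    assert d.decision is Decision.MANUAL_REVIEW


def test_benign_registry_assertion_excludes():
    d = triage_clinvar(_variant(), [_sub("B", "2018-05-01")], {"Big"})
    assert d.decision is Decision.EXCLUDED


# ---------------------------------------------------------------------------
# pLoF rule engine
# ---------------------------------------------------------------------------

TX = TranscriptModel(
    gene="GCK", strand="+",
    exons=((101, 700), (801, 1400), (1501, 1800), (1901, 2500)),
    cds_length=2100,
)


def test_transcript_coordinates_and_strand():
    assert TX.cds_position(101) == 1
    assert TX.cds_position(2500) == 2100
    minus = TranscriptModel(gene="X", strand="-", exons=((900, 1000), (100, 500)),
                            cds_length=502)
    assert minus.cds_position(1000) == 1
    assert minus.cds_position(100) == 502


def test_position_outside_transcript_errors():
    with pytest.raises(ValueError):
        TX.cds_position(750)


def test_nmd_escape_without_override_is_not_lof():
    v = _variant(pos=2290, consequence="stop_gained", loftee="HC", pext=0.9)
    cls, ev = classify_plof(v, TX)
    assert cls is LofClass.NOT_LOF


def test_nmd_escape_override_above_quarter_of_cds():
    v = _variant(pos=1771, consequence="stop_gained", loftee="HC", pext=0.9)
    cls, _ = classify_plof(v, TX)
    assert cls is LofClass.LOF


def test_splice_rescue_windows():
    v = _variant(pos=700, consequence="splice_donor", loftee="HC", pext=0.9)
    assert classify_plof(v, TX, SpliceContext(4))[0] is LofClass.LIKELY_NOT_LOF
    assert classify_plof(v, TX, SpliceContext(10))[0] is LofClass.UNCERTAIN
    assert classify_plof(v, TX, SpliceContext(10, validated=True))[0] is LofClass.LIKELY_NOT_LOF
    assert classify_plof(v, TX, SpliceContext(25))[0] is LofClass.LOF


def test_non_hc_short_circuits():
    v = _variant(pos=900, consequence="stop_gained", loftee="LC")
    cls, ev = classify_plof(v, TX)
    assert cls is LofClass.NOT_LOF and len(ev) == 1


def test_missing_pext_skips_rule_with_note():
    v = _variant(pos=900, consequence="stop_gained", loftee="HC", pext=None)
    cls, ev = classify_plof(v, TX)
    assert cls is LofClass.LOF
    assert any("skipped" in e for e in ev)


def test_rule_engine_is_pure(fixtures):
    for v in fixtures.variants:
        if v.variant_id in fixtures.expected_lof:
            ctx = fixtures.splice_contexts.get(v.variant_id)
            a = classify_plof(v, fixtures.transcripts[v.gene], ctx)
            b = classify_plof(v, fixtures.transcripts[v.gene], ctx)
            assert a == b


@settings(max_examples=60, derandomize=True, deadline=None)
@given(pext_hi=st.floats(0.0, 1.0), pext_lo=st.floats(0.0, 1.0))
def test_lower_pext_never_upgrades(pext_hi, pext_lo):
    pext_hi, pext_lo = max(pext_hi, pext_lo), min(pext_hi, pext_lo)
    order = [LofClass.LOF, LofClass.LIKELY_LOF, LofClass.UNCERTAIN,
             LofClass.LIKELY_NOT_LOF, LofClass.NOT_LOF]
    v_hi = _variant(pos=900, consequence="stop_gained", loftee="HC", pext=pext_hi)
    v_lo = _variant(pos=900, consequence="stop_gained", loftee="HC", pext=pext_lo)
    cls_hi, _ = classify_plof(v_hi, TX)
    cls_lo, _ = classify_plof(v_lo, TX)
    assert order.index(cls_lo) >= order.index(cls_hi)


def test_truncation_moved_3prime_never_upgrades():
    order = [LofClass.LOF, LofClass.LIKELY_LOF, LofClass.UNCERTAIN,
             LofClass.LIKELY_NOT_LOF, LofClass.NOT_LOF]
    positions = [150, 900, 1550, 1771, 1950, 2290, 2450]  # 5' -> 3'
    ranks = []
    for pos in positions:
        v = _variant(pos=pos, consequence="stop_gained", loftee="HC", pext=0.9)
        ranks.append(order.index(classify_plof(v, TX)[0]))
    assert ranks == sorted(ranks)


def test_fixture_suite_reaches_all_five_classes(fixtures):
    seen = set()
    for v in fixtures.variants:
        if v.variant_id in fixtures.expected_lof:
            ctx = fixtures.splice_contexts.get(v.variant_id)
            cls, _ = classify_plof(v, fixtures.transcripts[v.gene], ctx)
            assert cls.value == fixtures.expected_lof[v.variant_id]
            seen.add(cls)
    assert seen == set(LofClass)


# ---------------------------------------------------------------------------
# carrier assembly
# ---------------------------------------------------------------------------

def test_carrier_matrix_rules():
    decisions = pd.DataFrame(
        {"gene": ["GCK", "HNF1A", "LDLR"], "qualifying": [True, True, False]},
        index=["v1", "v2", "v3"],
    )
    genotypes = pd.DataFrame(
        {
            "v1": [1.0, 0.0, np.nan, 0.0],
            "v2": [0.0, 1.0, 0.0, 0.0],
            "v3": [0.0, 0.0, 0.0, 2.0],  # non-qualifying variant
        },
        index=list("abcd"),
    )
    sets = {"mody": ["GCK", "HNF1A", "HNF1B", "HNF4A", "PDX1"]}
    out = carrier_matrix(decisions, genotypes, sets)
    assert list(out["mody"]) == [True, True, False, False]


def test_qc_failed_genotype_means_noncarrier():
    decisions = pd.DataFrame({"gene": ["GCK"], "qualifying": [True]}, index=["v1"])
    genotypes = pd.DataFrame({"v1": [np.nan]}, index=["a"])  # failed QC -> missing
    out = carrier_matrix(decisions, genotypes, {"mody": ["GCK"]})
    assert not out["mody"].iloc[0]


def test_planted_carrier_counts_recovered(small_sim):
    from penexome import carrier_matrix as cm

    decisions = pd.DataFrame(
        {"gene": small_sim.variants["gene"],
         "condition": small_sim.variants["condition"], "qualifying": True},
        index=small_sim.variants.index,
    )
    gene_sets = {c.name: list(c.genes) for c in small_sim.config.conditions}
    flags = cm(decisions, small_sim.genotypes, gene_sets)
    for cond in small_sim.config.conditions:
        planted = int(small_sim.cohort[f"carrier_{cond.name}"].sum())
        assert int(flags[cond.name].sum()) == planted
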