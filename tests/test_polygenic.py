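"""Polygenic scoring, tail contrasts, expressivity regressions, planning math."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from penexome import (
    PowerQuery,
    carrier_geps_regression,
    compute_pgs,
    contrast_top_tail,
    equivalent_tail_fraction,
    interaction_test,
    n_for_correlation,
    required_cohort_size,
    simulate_snp_panel,
)
from penexome.polygenic import _tail_mean_shift


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------

def test_zero_weights_zero_scores():
    d, a, w = simulate_snp_panel(500, 20, seed=1)
    w["weight"] = 0.0
    res = compute_pgs(d, a, w)
    assert (res.raw == 0).all()


def test_single_variant_score_is_standardized_dosage():
    d, a, w = simulate_snp_panel(500, 5, seed=2)
    w = w.iloc[[0]].copy()
    w["weight"] = 1.0
    res = compute_pgs(d, a, w)
    dose = d[w["variant_id"].iloc[0]]
    expected = (dose - dose.mean()) / dose.std(ddof=0)
    np.testing.assert_allclose(res.z, expected, atol=1e-12)


def test_allele_flip_consistency():
    d, a, w = simulate_snp_panel(800, 40, seed=3)
    flipped = w.copy()
    flipped["effect_allele"] = "A"  # the ref allele
    flipped["weight"] = -flipped["weight"]
    res = compute_pgs(d, a, w)
    res_f = compute_pgs(d, a, flipped)
    np.testing.assert_allclose(res.z, res_f.z, atol=1e-10)


def test_missing_dosages_mean_imputed():
    d, a, w = simulate_snp_panel(300, 10, seed=4)
    d.iloc[0, 0] = np.nan
    res = compute_pgs(d, a, w)
    assert np.isfinite(res.raw).all()


def test_no_overlap_errors():
    d, a, w = simulate_snp_panel(50, 5, seed=5)
    w["variant_id"] = "absent"
    with pytest.raises(ValueError):
        compute_pgs(d, a, w)


def test_standardization_and_percentiles():
    d, a, w = simulate_snp_panel(5_000, 60, seed=6)
    res = compute_pgs(d, a, w)
    assert abs(res.z.mean()) < 1e-10
    assert abs(res.z.std(ddof=0) - 1) < 1e-10
    counts = res.percentile.value_counts()
    assert set(counts.index) == set(range(1, 101))
    assert counts.max() - counts.min() <= 1  # bins partition the cohort


# ---------------------------------------------------------------------------
# contrasts
# ---------------------------------------------------------------------------

def _score_cohort(n=40_000, h2=0.157, sd=15.0, mu=58.0, seed=8):
    rng = np.random.default_rng(seed)
    z = rng.normal(0, 1, n)
    trait = mu + np.sqrt(h2) * sd * z + rng.normal(0, np.sqrt(1 - h2) * sd, n)
    cohort = pd.DataFrame(
        {"age": rng.integers(40, 71, n), "sex": rng.integers(0, 2, n), "hdl": trait}
    )
    return cohort, pd.Series(z, index=cohort.index)


def test_top_tail_shift_matches_truncated_normal_form():
    cohort, scores = _score_cohort()
    est = contrast_top_tail(cohort, scores, "hdl", tail=0.01, age_min=40)["tail_vs_iqr"]
    z99 = stats.norm.ppf(0.99)
    tail_mean = np.sqrt(0.157) * 15 * stats.norm.pdf(z99) / 0.01
    # IQR of a standard normal has mean 0, so the contrast approximates the tail mean
    assert est.beta == pytest.approx(tail_mean, abs=4 * est.se)


def test_half_split_null_shift_is_zero():
    rng = np.random.default_rng(9)
    n = 20_000
    cohort = pd.DataFrame(
        {"age": rng.integers(60, 71, n), "sex": rng.integers(0, 2, n),
         "hdl": rng.normal(58, 15, n)}
    )
    scores = pd.Series(rng.normal(0, 1, n), index=cohort.index)
    est = contrast_top_tail(cohort, scores, "hdl", tail=0.5, reference=(0.0, 0.5))["tail_vs_iqr"]
    assert abs(est.beta) < 4 * est.se


def test_carrier_vs_tail_contrast_positive_by_construction():
    cohort, scores = _score_cohort(n=20_000)
    carrier = pd.Series(False, index=cohort.index)
    carrier.iloc[:40] = True
    cohort.loc[carrier, "hdl"] += 30.0  # monogenic shift beyond any top-1% tail mean
    out = contrast_top_tail(cohort, scores, "hdl", age_min=40, carrier=carrier)
    est = out["carrier_vs_tail"]
    assert est.beta > 0 and est.p_value < 0.05


def test_carrier_geps_regression_recovers_slope():
    cohort, scores = _score_cohort(n=50_000, seed=12)
    carrier = pd.Series(False, index=cohort.index)
    carrier.iloc[:400] = True
    est = carrier_geps_regression(cohort, carrier, scores, "hdl")
    assert abs(est.beta - np.sqrt(0.157) * 15) < 2 * est.se


def test_carrier_geps_null_slope():
    rng = np.random.default_rng(13)
    n = 30_000
    cohort = pd.DataFrame(
        {"age": rng.integers(40, 71, n), "sex": rng.integers(0, 2, n),
         "hdl": rng.normal(58, 15, n)}
    )
    scores = pd.Series(rng.normal(0, 1, n), index=cohort.index)
    carrier = pd.Series(False, index=cohort.index)
    carrier.iloc[:300] = True
    est = carrier_geps_regression(cohort, carrier, scores, "hdl")
    assert abs(est.beta) < 3 * est.se


def test_too_few_carriers_for_covariates_errors():
    cohort, scores = _score_cohort(n=100)
    carrier = pd.Series(False, index=cohort.index)
    carrier.iloc[:3] = True
    with pytest.raises(ValueError):
        carrier_geps_regression(cohort, carrier, scores, "hdl",
                                covariates=["age", "sex"] * 6)


def test_interaction_null_type_one_error():
    rng = np.random.default_rng(14)
    n, reps = 4_000, 200
    rejections = 0
    for _ in range(reps):
        z = rng.normal(0, 1, n)
        carrier = np.zeros(n)
        carrier[rng.choice(n, 50, replace=False)] = 1
        trait = 10 * carrier + 4 * z + rng.normal(0, 10, n)
        cohort = pd.DataFrame({"hdl": trait})
        est = interaction_test(cohort, pd.Series(carrier), pd.Series(z), "hdl")
        rejections += est.p_value < 0.05
    rate = rejections / reps
    assert abs(rate - 0.05) < 3 * np.sqrt(0.05 * 0.95 / reps)


def test_interaction_detects_planted_effect():
    rng = np.random.default_rng(15)
    n = 30_000
    z = rng.normal(0, 1, n)
    carrier = np.zeros(n)
    carrier[rng.choice(n, 300, replace=False)] = 1
    trait = 15 * carrier + 4 * z + 8 * carrier * z + rng.normal(0, 10, n)
    cohort = pd.DataFrame({"hdl": trait})
    est = interaction_test(cohort, pd.Series(carrier), pd.Series(z), "hdl")
    assert est.beta > 0 and est.p_value < 1e-3


def test_all_carrier_input_errors():
    cohort = pd.DataFrame({"hdl": [1.0, 2.0, 3.0]})
    with pytest.raises(ValueError):
        interaction_test(cohort, pd.Series([1.0, 1.0, 1.0]),
                         pd.Series([0.1, 0.2, 0.3]), "hdl")


# ---------------------------------------------------------------------------
# planning math
# ---------------------------------------------------------------------------

def test_median_tail_identity():
    h2, sd = 0.157, 15.0
    shift = np.sqrt(h2) * sd * stats.norm.pdf(0) / 0.5
    res = equivalent_tail_fraction(h2, sd, shift)
    assert res.q == pytest.approx(0.5, abs=1e-9)


def test_tail_fraction_for_hdl_like_shift():
    res = equivalent_tail_fraction(0.157, 15.0, 16.8)
    assert res.q == pytest.approx(6.1e-3, rel=0.05)
    assert res.top_tail_mean_shift == pytest.approx(16.8, rel=1e-9)


def test_tail_fraction_inverts_forward_map():
    for q in (1e-4, 1e-3, 0.01, 0.1, 0.4):
        shift = _tail_mean_shift(q, 0.157, 15.0)
        rec = equivalent_tail_fraction(0.157, 15.0, shift)
        assert rec.q == pytest.approx(q, rel=1e-6)


def test_tail_fraction_monotone_in_shift_and_h2():
    shifts = np.linspace(5, 25, 9)
    qs = [equivalent_tail_fraction(0.157, 15.0, s).q for s in shifts]
    assert all(a > b for a, b in zip(qs, qs[1:]))
    h2s = [0.05, 0.1, 0.2, 0.4]
    qh = [equivalent_tail_fraction(h, 15.0, 10.0).q for h in h2s]
    assert all(a < b for a, b in zip(qh, qh[1:]))


def test_unattainable_shift_errors():
    with pytest.raises(ValueError, match="unattainable"):
        equivalent_tail_fraction(0.157, 15.0, 1e6)


@pytest.mark.parametrize(
    "sided,expected", [("one", 98), ("two", 124)]
)
def test_carriers_for_correlation(sided, expected):
    assert n_for_correlation(PowerQuery(r=0.25, power=0.8, alpha=0.05, sided=sided)) == expected


def test_two_sided_count_against_exact_power_inversion():
    """Fisher-z count is within one step of exact bivariate-normal power inversion."""
    rng = np.random.default_rng(20)
    n = 124
    reps = 2_000
    rejections = 0
    for _ in range(reps):
        x = rng.multivariate_normal([0, 0], [[1, 0.25], [0.25, 1]], size=n)
        r = np.corrcoef(x[:, 0], x[:, 1])[0, 1]
        t = r * np.sqrt((n - 2) / (1 - r**2))
        rejections += abs(t) > stats.t.ppf(0.975, n - 2)
    assert rejections / reps >= 0.78  # ~80% power at the Fisher-z count


def test_extreme_correlation_formula_floor():
    assert n_for_correlation(PowerQuery(r=0.999999, power=0.8, alpha=0.05)) == 4


@pytest.mark.parametrize(
    "carriers,prev,expected",
    [(98, 1e-4, 980_000), (1, 1.0, 1), (98, 0.5, 196)],
)
def test_required_cohort_size(carriers, prev, expected):
    assert required_cohort_size(carriers, prev) == expected


def test_required_cohort_size_zero_prevalence_errors():
    with pytest.raises(ValueError):
        required_cohort_size(98, 0.0)
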