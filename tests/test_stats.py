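"""Wilcoxon, Spearman, ICC and cohort statistics against independent oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import rankdata

from foramenvol.stats import (
    RaterTable,
    cohort_analysis,
    icc_two_way_mixed_absolute,
    spearman,
    wilcoxon_paired,
)


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank
# ---------------------------------------------------------------------------


def enumeration_p(d):
    """Two-sided p by explicit enumeration of all sign patterns."""
    ranks = rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    n = len(d)
    n_le = n_ge = 0
    for signs in itertools.product([0, 1], repeat=n):
        w = sum(r for s, r in zip(signs, ranks) if s)
        n_le += w <= w_obs + 1e-12
        n_ge += w >= w_obs - 1e-12
    return min(1.0, 2.0 * min(n_le, n_ge) / 2.0**n)


def test_identical_samples_give_p_one():
    x = np.arange(10.0)
    with pytest.warns(UserWarning, match="zero"):
        stat, p = wilcoxon_paired(x, x)
    assert p == 1.0


def test_all_positive_differences_n5():
    x = np.array([2.0, 3.0, 4.0, 5.0, 6.0])
    y = np.ones(5)
    stat, p = wilcoxon_paired(x, y)
    assert stat == 15.0
    assert p == pytest.approx(2.0 / 2.0**5)  # 0.0625 by enumeration


@pytest.mark.parametrize("trial", range(6))
def test_exact_p_matches_enumeration_oracle(trial):
    rng = np.random.default_rng(2 + trial)
    d = np.round(rng.normal(0.0, 2.0, 12), 1)  # rounding creates ties
    d[d == 0.0] = 0.1
    _, p = wilcoxon_paired(d, np.zeros_like(d))
    assert p == pytest.approx(enumeration_p(d), abs=1e-12)


def test_exact_agrees_with_scipy_without_ties():
    from scipy.stats import wilcoxon as scipy_wilcoxon

    rng = np.random.default_rng(10)
    d = rng.normal(0.0, 1.0, 14)
    _, p = wilcoxon_paired(d, np.zeros_like(d))
    assert p == pytest.approx(scipy_wilcoxon(d, method="exact").pvalue, abs=1e-12)


def test_normal_approximation_close_to_exact_at_boundary():
    rng = np.random.default_rng(11)
    d = rng.normal(0.3, 1.0, 16)  # n = 16: first size using the approximation
    _, p_approx = wilcoxon_paired(d, np.zeros_like(d))
    assert p_approx == pytest.approx(enumeration_p(d), rel=0.1)


def test_too_few_nonzero_differences_rejected():
    with pytest.raises(ValueError, match=">= 5"):
        wilcoxon_paired(np.array([1.0, 2, 3, 0, 0, 0]), np.zeros(6))


def test_null_rejection_rate_is_calibrated():
    """Type-I error of the paired test at alpha=0.05 over 1000 null replicates."""
    rng = np.random.default_rng(9)
    rejections = 0
    for _ in range(1000):
        v_n = rng.normal(15_000.0, 3000.0, 10)
        v_d = v_n + rng.normal(0.0, 30.0, 10)  # pure measurement noise
        _, p = wilcoxon_paired(v_d, v_n)
        rejections += p < 0.05
    assert 0.03 <= rejections / 1000 <= 0.07


# ---------------------------------------------------------------------------
# Spearman
# ---------------------------------------------------------------------------


def test_monotone_sequences_give_unit_rho():
    x = np.array([1.0, 2, 3, 7, 20])
    assert spearman(x, np.exp(x))[0] == pytest.approx(1.0)
    assert spearman(x, -(x**3))[0] == pytest.approx(-1.0)


def test_worked_five_point_example():
    rho, _ = spearman([1, 2, 3, 4, 5], [1, 3, 2, 5, 4])
    assert rho == pytest.approx(0.8)  # 1 - 6*2/(5*24)


def test_spearman_equals_pearson_on_midranks():
    rng = np.random.default_rng(6)
    x = np.round(rng.normal(size=30), 1)  # ties
    y = np.round(rng.normal(size=30), 1)
    rho, _ = spearman(x, y)
    rx, ry = rankdata(x), rankdata(y)
    pearson = np.corrcoef(rx, ry)[0, 1]
    assert rho == pytest.approx(pearson, abs=1e-12)


def test_spearman_needs_four_points():
    with pytest.raises(ValueError):
        spearman([1.0, 2, 3], [1.0, 2, 3])


# ---------------------------------------------------------------------------
# ICC
# ---------------------------------------------------------------------------


def test_identical_columns_give_perfect_icc():
    X = np.tile(np.arange(6.0)[:, None], (1, 2))
    for unit in ("single", "mean_of_k"):
        res = icc_two_way_mixed_absolute(X, unit)
        assert res.icc == pytest.approx(1.0)
        assert res.ci_lower == pytest.approx(1.0)


def test_offset_column_hand_computed_mean_squares():
    """6x2 table, col2 = col1 + 3: ANOVA mean squares computed by hand."""
    col = np.array([10.0, 12, 15, 17, 20, 26])
    X = np.column_stack([col, col + 3.0])
    n, k = 6, 2
    grand = X.mean()
    msr = k * ((X.mean(1) - grand) ** 2).sum() / (n - 1)  # independent arithmetic
    msc = n * ((X.mean(0) - grand) ** 2).sum() / (k - 1)
    mse = ((X - X.mean(1)[:, None] - X.mean(0)[None, :] + grand) ** 2).sum() / (
        (n - 1) * (k - 1)
    )
    expected_a1 = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
    res = icc_two_way_mixed_absolute(X, "single")
    assert res.icc == pytest.approx(expected_a1, abs=1e-12)
    assert res.icc < 1.0
    assert (res.msr, res.msc, res.mse) == pytest.approx((msr, msc, mse))


def test_independent_noise_columns_icc_near_zero():
    rng = np.random.default_rng(4)
    X = rng.normal(0.0, 1.0, size=(50, 2))
    res = icc_two_way_mixed_absolute(X, "single")
    assert abs(res.icc) <= 0.15


def test_mean_of_k_at_least_single():
    rng = np.random.default_rng(12)
    for _ in range(10):
        X = rng.normal(0, 1, (8, 4)) + rng.normal(0, 2, (8, 1))
        a1 = icc_two_way_mixed_absolute(X, "single")
        ak = icc_two_way_mixed_absolute(X, "mean_of_k")
        assert ak.icc >= a1.icc - 1e-12
        assert ak.ci_lower <= ak.icc <= ak.ci_upper


def test_matches_pingouin_reference():
    pingouin = pytest.importorskip("pingouin")
    rng = np.random.default_rng(4)
    X = rng.normal(50, 10, (12, 1)) + rng.normal(0, 3, (12, 4)) + np.arange(4.0)
    long = pd.DataFrame(
        [(i, j, X[i, j]) for i in range(12) for j in range(4)],
        columns=["subject", "rater", "value"],
    )
    ref = pingouin.intraclass_corr(
        long, targets="subject", raters="rater", ratings="value"
    ).set_index("Type")
    mine1 = icc_two_way_mixed_absolute(X, "single")
    minek = icc_two_way_mixed_absolute(RaterTable(X, ("a", "b", "c", "d")), "mean_of_k")
    assert mine1.icc == pytest.approx(ref.loc["ICC(A,1)", "ICC"], abs=1e-9)
    assert minek.icc == pytest.approx(ref.loc["ICC(A,k)", "ICC"], abs=1e-9)
    np.testing.assert_allclose(
        [mine1.ci_lower, mine1.ci_upper], ref.loc["ICC(A,1)", "CI95"], atol=5e-3
    )
    np.testing.assert_allclose(
        [minek.ci_lower, minek.ci_upper], ref.loc["ICC(A,k)", "CI95"], atol=5e-3
    )


def test_constant_table_undefined():
    with pytest.raises(ValueError, match="constant"):
        icc_two_way_mixed_absolute(np.full((6, 2), 3.0), "single")


# ---------------------------------------------------------------------------
# cohort analysis
# ---------------------------------------------------------------------------


def make_records(n, rng, effect=600.0, slope=0.2):
    rows = []
    for i in range(n):
        cement = rng.uniform(2000, 9000)
        for motion in ("flexion", "extension"):
            v_n = rng.normal(15_000, 2000)
            dv = effect + slope * (cement - 5500) + rng.normal(0, 250)
            rows.append(
                dict(
                    specimen=f"s{i:02d}",
                    level="L4-L5",
                    motion=motion,
                    v_nucleotomy=v_n,
                    v_discoplasty=v_n + dv,
                    cement_volume=cement,
                )
            )
    return pd.DataFrame(rows)


def test_cohort_detects_decompression_and_correlation():
    rng = np.random.default_rng(9)
    report = cohort_analysis(make_records(25, rng))
    for motion in ("flexion", "extension"):
        entry = report["per_motion"][motion]
        assert entry["n"] == 25
        assert entry["significant"]
        assert entry["spearman_rho"] > 0
        assert entry["spearman_p"] < 0.05
    assert "flexion/L4-L5" in report["per_level"]


def test_cohort_null_effect_not_significant():
    rng = np.random.default_rng(9)
    report = cohort_analysis(make_records(10, rng, effect=0.0, slope=0.0))
    assert report["per_motion"]["flexion"]["wilcoxon_p"] > 0.05


def test_cohort_requires_five_specimens():
    rng = np.random.default_rng(1)
    with pytest.raises(ValueError, match="insufficient"):
        cohort_analysis(make_records(1, rng))
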