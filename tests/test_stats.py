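"""Rank statistics against independent oracles (enumeration, scipy,
statsmodels, hand arithmetic)."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import mannwhitneyu, rankdata, spearmanr

from oatpquant import stats

# ---------------------------------------------------------------------------
# ranking
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "values,expected",
    [
        ([10, 20, 30], [1, 2, 3]),
        ([5, 5, 7], [1.5, 1.5, 3]),
        ([3, 1, 2, 2], [4, 1, 2.5, 2.5]),
    ],
)
def test_midranks(values, expected):
    assert stats.rank_with_ties(values) == pytest.approx(expected)


@given(st.lists(st.floats(-1e6, 1e6), min_size=1, max_size=50))
@settings(deadline=None, derandomize=True, max_examples=60)
def test_rank_sum_conservation_and_scipy_agreement(values):
    ranks = stats.rank_with_ties(values)
    n = len(values)
    assert ranks.sum() == pytest.approx(n * (n + 1) / 2)
    assert np.allclose(ranks, rankdata(values))


def test_rank_rejects_bad_input():
    with pytest.raises(ValueError):
        stats.rank_with_ties([])
    with pytest.raises(ValueError):
        stats.rank_with_ties([1.0, float("nan")])


# ---------------------------------------------------------------------------
# Mann-Whitney U
# ---------------------------------------------------------------------------


def enumeration_oracle(x, y):
    """Brute-force two-sided p: every split of the pooled values, mid-ranks
    via scipy, doubled smaller tail.  Independent of the implementation."""
    pooled = np.concatenate([x, y])
    n1 = len(x)
    ranks = rankdata(pooled)
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    us = [
        sum(ranks[list(idx)]) - n1 * (n1 + 1) / 2
        for idx in itertools.combinations(range(len(pooled)), n1)
    ]
    us = np.asarray(us)
    p_le = np.mean(us <= u_obs + 1e-9)
    p_ge = np.mean(us >= u_obs - 1e-9)
    return u_obs, min(1.0, 2.0 * min(p_le, p_ge))


def test_exact_separated_groups():
    # x entirely below y: U = 0; only 2 of the C(6,3)=20 splits are as extreme
    res = stats.mann_whitney_u([1, 2, 3], [4, 5, 6])
    assert res.method == "exact"
    assert res.statistic == 0
    assert res.p_two_sided == pytest.approx(0.1)


def test_degenerate_identical_values():
    res = stats.mann_whitney_u([3, 3, 3], [3, 3, 3])
    assert res.degenerate
    assert res.p_two_sided == 1.0
    assert res.statistic == pytest.approx(9 / 2)


@pytest.mark.parametrize(
    "x,y",
    [
        ([1, 2, 2, 5], [2, 6, 7, 8]),  # ties across groups, 70 splits
        ([1, 2, 3], [4, 5, 6]),
        ([5, 5, 5, 1], [2, 3, 9]),
        ([1.5, 2.5], [0.5, 3.5, 4.5]),
        ([1, 1, 2, 3, 3], [2, 2, 4, 4, 5]),
    ],
)
def test_exact_mode_matches_enumeration_oracle(x, y):
    u_ref, p_ref = enumeration_oracle(x, y)
    res = stats.mann_whitney_u(x, y, mode="exact")
    assert res.statistic == pytest.approx(u_ref)
    assert res.p_two_sided == pytest.approx(p_ref)


def test_exact_mode_matches_oracle_on_all_small_splits():
    """Every two-group split of two pooled multisets (with and without
    ties), n1+n2 <= 10."""
    for pooled in ([1, 2, 3, 4, 5, 6, 7], [1, 1, 2, 3, 3, 4, 5]):
        pooled = np.asarray(pooled, dtype=float)
        for n1 in (2, 3):
            for idx in itertools.combinations(range(len(pooled)), n1):
                x = pooled[list(idx)]
                y = np.delete(pooled, list(idx))
                u_ref, p_ref = enumeration_oracle(x, y)
                res = stats.mann_whitney_u(x, y, mode="exact")
                assert res.statistic == pytest.approx(u_ref)
                assert res.p_two_sided == pytest.approx(p_ref), (x, y)


def test_normal_approximation_matches_scipy(rng):
    for _ in range(10):
        x = rng.normal(size=25)
        y = rng.normal(loc=rng.uniform(-1, 1), size=8)
        ours = stats.mann_whitney_u(x, y)
        ref = mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        assert ours.method == "normal_approx"
        assert ours.statistic == pytest.approx(ref.statistic)
        assert ours.p_two_sided == pytest.approx(ref.pvalue, rel=1e-9)


def test_normal_approximation_with_ties_matches_scipy(rng):
    x = rng.integers(0, 5, size=20).astype(float)
    y = rng.integers(0, 5, size=15).astype(float)
    ours = stats.mann_whitney_u(x, y)
    ref = mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    assert ours.p_two_sided == pytest.approx(ref.pvalue, rel=1e-9)


def test_null_rejection_rate_is_nominal():
    """Under a shared continuous null at the study's group sizes (25 vs 8)
    the two-sided test rejects at alpha=0.05 about 5% of the time."""
    rng = np.random.default_rng(1)
    n_reps = 2000
    rejections = sum(
        stats.mann_whitney_u(rng.normal(size=25), rng.normal(size=8)).p_two_sided < 0.05
        for _ in range(n_reps)
    )
    assert 0.04 <= rejections / n_reps <= 0.06


# ---------------------------------------------------------------------------
# Spearman
# ---------------------------------------------------------------------------


def test_spearman_monotone_extremes():
    x = [1, 2, 5, 9]
    assert stats.spearman(x, [2, 4, 8, 16]).rho == 1.0
    assert stats.spearman(x, [16, 8, 4, 2]).rho == -1.0


def test_spearman_hand_computed_with_ties():
    # ranks of x = [1, 2.5, 2.5, 4], of y = [1, 2, 3, 4]
    # Pearson on those ranks: 4.5 / sqrt(4.5 * 5)
    res = stats.spearman([1, 2, 2, 4], [10, 20, 30, 40])
    assert res.rho == pytest.approx(4.5 / math.sqrt(22.5))
    assert res.approximate  # n < 10


def test_spearman_matches_scipy(rng):
    x = rng.normal(size=30)
    y = x + rng.normal(size=30)
    ours = stats.spearman(x, y)
    ref = spearmanr(x, y)
    assert ours.rho == pytest.approx(ref.statistic)
    assert ours.p == pytest.approx(ref.pvalue, rel=1e-6)


def test_spearman_rank_and_monotone_invariance(rng):
    x = rng.normal(size=25)
    y = rng.normal(size=25)
    base = stats.spearman(x, y).rho
    assert stats.spearman(rankdata(x), rankdata(y)).rho == pytest.approx(base)
    assert stats.spearman(np.exp(x), y**3).rho == pytest.approx(base)


def test_spearman_undefined_for_constant_input():
    res = stats.spearman([1, 1, 1, 1], [1, 2, 3, 4])
    assert res.undefined and math.isnan(res.rho)


# ---------------------------------------------------------------------------
# Benjamini-Hochberg
# ---------------------------------------------------------------------------


def test_bh_hand_computation():
    # q_i = p_i * 4 / i = [.04, .04, .04, .04] after the monotone pass
    assert stats.bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)


def test_bh_single_p_unchanged():
    assert stats.bh_adjust([0.2]) == pytest.approx([0.2])


@given(st.lists(st.floats(1e-6, 1.0, exclude_min=False), min_size=1, max_size=40))
@settings(deadline=None, derandomize=True, max_examples=60)
def test_bh_dominates_raw_and_matches_statsmodels(p):
    from statsmodels.stats.multitest import multipletests

    adj = stats.bh_adjust(p)
    assert np.all(adj >= np.asarray(p) - 1e-12)
    assert np.all(adj <= 1.0)
    assert np.allclose(adj, multipletests(p, method="fdr_bh")[1])


def test_bh_decision_equivalence(rng):
    """Thresholding adjusted p at q selects exactly the classical step-up
    set: the largest k with p_(k) <= k q / m."""
    for _ in range(20):
        p = rng.uniform(1e-4, 1, size=rng.integers(3, 30))
        q = rng.uniform(0.01, 0.3)
        adj = stats.bh_adjust(p)
        srt = np.sort(p)
        ks = np.nonzero(srt <= (np.arange(1, len(p) + 1) * q / len(p)))[0]
        n_classical = 0 if ks.size == 0 else ks[-1] + 1
        assert int(np.sum(adj <= q)) == n_classical


def test_bh_rejects_out_of_range():
    with pytest.raises(ValueError):
        stats.bh_adjust([0.0, 0.5])
    with pytest.raises(ValueError):
        stats.bh_adjust([0.5, 1.2])


# ---------------------------------------------------------------------------
# correlation matrix
# ---------------------------------------------------------------------------


def test_correlation_matrix_two_variables_consistency(rng):
    import pandas as pd

    x = rng.normal(size=12)
    y = rng.normal(size=12)
    table = pd.DataFrame({"a": x, "b": y})
    mat = stats.correlation_matrix(table)
    ref = stats.spearman(x, y)
    assert mat.rho.loc["a", "b"] == pytest.approx(ref.rho)
    assert mat.p.loc["a", "b"] == pytest.approx(ref.p)


def test_correlation_matrix_symmetry_diagonal_and_bh(rng):
    import pandas as pd

    table = pd.DataFrame(rng.normal(size=(15, 4)), columns=list("abcd"))
    mat = stats.correlation_matrix(table)
    assert np.allclose(mat.rho.to_numpy(), mat.rho.to_numpy().T)
    assert np.allclose(np.diag(mat.rho), 1.0)
    off = ~np.eye(4, dtype=bool)
    assert np.all(mat.p_adjusted.to_numpy()[off] >= mat.p.to_numpy()[off] - 1e-12)


def test_correlation_matrix_constant_column_flagged(rng):
    import pandas as pd

    table = pd.DataFrame({"a": rng.normal(size=10), "c": np.ones(10)})
    mat = stats.correlation_matrix(table)
    assert math.isnan(mat.rho.loc["a", "c"])
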