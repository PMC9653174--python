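"""Rank-based statistics used by the quantification pipeline.

The group comparisons in this package are two-sided Mann-Whitney U tests
and the association measures are Spearman rank correlations, with
Benjamini-Hochberg control of the false discovery rate across families of
tests.  These procedures are implemented here from their definitions (the
package's group comparisons must be auditable down to the rank level);
only tail probabilities of the normal and t reference distributions are
taken from scipy.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm as _norm
from scipy.stats import t as _t_dist

__all__ = [
    "TestResult",
    "SpearmanResult",
    "CorrelationMatrix",
    "rank_with_ties",
    "mann_whitney_u",
    "spearman",
    "bh_adjust",
    "correlation_matrix",
]


@dataclass(frozen=True)
class TestResult:
    """Two-sided Mann-Whitney U test result.

    ``statistic`` is the U statistic of the first sample; ``method`` is
    ``"exact"`` (full enumeration of rank assignments) or
    ``"normal_approx"`` (tie-corrected normal approximation with
    continuity correction).  ``degenerate`` flags the no-information case
    where every observation in both groups is identical.
    """

    statistic: float
    n1: int
    n2: int
    p_two_sided: float
    method: str
    degenerate: bool = False


@dataclass(frozen=True)
class SpearmanResult:
    rho: float
    p: float
    n: int
    approximate: bool = False  # t-approximation at small n
    undefined: bool = False  # zero rank variance in either variable


def rank_with_ties(values) -> np.ndarray:
    """Ranks 1..n with tied values sharing the mean of their covered ranks.

    The rank sum is always n(n+1)/2 regardless of ties.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        x = x.ravel()
    if x.size == 0:
        raise ValueError("cannot rank an empty sequence")
    if not np.all(np.isfinite(x)):
        raise ValueError("cannot rank non-finite values")
    order = np.argsort(x, kind="mergesort")
    ranks = np.empty(x.size, dtype=float)
    sx = x[order]
    i = 0
    n = x.size
    while i < n:
        j = i
        while j + 1 < n and sx[j + 1] == sx[i]:
            j += 1
        # positions i..j (0-based) hold ranks i+1..j+1; ties get the mean
        ranks[order[i : j + 1]] = 0.5 * (i + j) + 1.0
        i = j + 1
    return ranks


def _u_from_ranks(pooled_ranks: np.ndarray, n1: int) -> float:
    r1 = float(pooled_ranks[:n1].sum())
    return r1 - n1 * (n1 + 1) / 2.0


def _exact_two_sided_p(pooled_ranks: np.ndarray, n1: int, u_obs: float) -> float:
    """Exact two-sided p by full enumeration of the C(n, n1) group splits.

    Two-sided p doubles the smaller tail probability (capped at 1); with
    ties the permutation distribution of U need not be symmetric, so both
    tails are evaluated explicitly.
    """
    n = pooled_ranks.size
    offset = n1 * (n1 + 1) / 2.0
    us = np.fromiter(
        (sum(comb) - offset for comb in itertools.combinations(pooled_ranks, n1)),
        dtype=float,
        count=math.comb(n, n1),
    )
    eps = 1e-9
    p_le = float(np.mean(us <= u_obs + eps))
    p_ge = float(np.mean(us >= u_obs - eps))
    return min(1.0, 2.0 * min(p_le, p_ge))


def mann_whitney_u(x, y, mode: str = "auto") -> TestResult:
    """Two-sided Mann-Whitney U test from joint mid-ranks.

    ``mode="auto"`` uses exact enumeration when n1+n2 <= 12 and there are
    no ties, otherwise the normal approximation with tie-corrected
    variance and continuity correction.  ``mode="exact"`` forces
    enumeration (ties handled through mid-ranks); ``mode="normal_approx"``
    forces the approximation.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    n1, n2 = x.size, y.size
    if n1 < 1 or n2 < 1:
        raise ValueError("both samples must be nonempty")
    if mode not in ("auto", "exact", "normal_approx"):
        raise ValueError(f"unknown mode {mode!r}")
    pooled = np.concatenate([x, y])
    if not np.all(np.isfinite(pooled)):
        raise ValueError("non-finite values in input")
    if np.all(pooled == pooled[0]):
        return TestResult(n1 * n2 / 2.0, n1, n2, 1.0, "normal_approx", degenerate=True)

    ranks = rank_with_ties(pooled)
    u = _u_from_ranks(ranks, n1)
    _, tie_counts = np.unique(pooled, return_counts=True)
    has_ties = np.any(tie_counts > 1)

    use_exact = mode == "exact" or (mode == "auto" and n1 + n2 <= 12 and not has_ties)
    if use_exact:
        p = _exact_two_sided_p(ranks, n1, u)
        return TestResult(u, n1, n2, p, "exact")

    n = n1 + n2
    mu = n1 * n2 / 2.0
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (n * (n - 1))
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if sigma2 <= 0:
        return TestResult(u, n1, n2, 1.0, "normal_approx", degenerate=True)
    d = u - mu
    # continuity correction: shrink |d| by 1/2 toward the null mean
    d = math.copysign(max(abs(d) - 0.5, 0.0), d)
    z = d / math.sqrt(sigma2)
    p = min(1.0, 2.0 * float(_norm.sf(abs(z))))
    return TestResult(u, n1, n2, p, "normal_approx")


def spearman(x, y) -> SpearmanResult:
    """Spearman rank correlation with two-sided t-approximation p-value.

    rho is the Pearson correlation of mid-ranks; p uses the
    t = rho*sqrt((n-2)/(1-rho^2)) approximation with n-2 df, flagged
    ``approximate`` when n < 10.  Zero rank variance in either variable
    leaves rho undefined (NaN, flagged).
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError("x and y must be paired")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 pairs")
    rx = rank_with_ties(x)
    ry = rank_with_ties(y)
    sx = rx - rx.mean()
    sy = ry - ry.mean()
    vx = float(np.dot(sx, sx))
    vy = float(np.dot(sy, sy))
    if vx == 0.0 or vy == 0.0:
        return SpearmanResult(float("nan"), float("nan"), n, undefined=True)
    rho = float(np.dot(sx, sy) / math.sqrt(vx * vy))
    rho = max(-1.0, min(1.0, rho))
    if abs(rho) == 1.0:
        p = 0.0
    else:
        t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
        p = min(1.0, 2.0 * float(_t_dist.sf(abs(t), n - 2)))
    return SpearmanResult(rho, p, n, approximate=n < 10)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    q_(i) = p_(i) * m / i on the ascending sort, made monotone
    non-decreasing from the largest rank down and capped at 1.
    """
    p = np.asarray(p_values, dtype=float).ravel()
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    q = p[order] * m / np.arange(1, m + 1)
    q = np.minimum.accumulate(q[::-1])[::-1]
    q = np.minimum(q, 1.0)
    out = np.empty(m, dtype=float)
    out[order] = q
    return out


@dataclass
class CorrelationMatrix:
    """Symmetric Spearman correlation matrix with raw and BH-adjusted p.

    ``rho`` has unit diagonal; BH adjustment is applied across the upper
    triangle (each unordered pair counted once) and mirrored.  Pairs with
    undefined correlation (constant variable) are NaN.
    """

    variables: list[str]
    rho: pd.DataFrame
    p: pd.DataFrame
    p_adjusted: pd.DataFrame
    n: pd.DataFrame

    def to_long(self) -> pd.DataFrame:
        """Long-format (var_a, var_b, rho, p, p_bh, n) over the upper triangle."""
        rows = []
        k = len(self.variables)
        for i in range(k):
            for j in range(i + 1, k):
                a, b = self.variables[i], self.variables[j]
                rows.append(
                    {
                        "var_a": a,
                        "var_b": b,
                        "rho": self.rho.iloc[i, j],
                        "p": self.p.iloc[i, j],
                        "p_bh": self.p_adjusted.iloc[i, j],
                        "n": self.n.iloc[i, j],
                    }
                )
        return pd.DataFrame(rows)


def correlation_matrix(table: pd.DataFrame, variables: list[str] | None = None) -> CorrelationMatrix:
    """Pairwise Spearman correlations over rows of ``table``.

    Rows with a missing value in either variable of a pair are dropped for
    that pair (pairwise-complete); every pair needs >= 3 complete rows.
    """
    if variables is None:
        variables = list(table.columns)
    missing = [v for v in variables if v not in table.columns]
    if missing:
        raise KeyError(f"variables not in table: {missing}")
    k = len(variables)
    rho = np.full((k, k), np.nan)
    p = np.full((k, k), np.nan)
    nmat = np.zeros((k, k), dtype=int)
    np.fill_diagonal(rho, 1.0)
    for i in range(k):
        nmat[i, i] = int(table[variables[i]].notna().sum())
    pairs = []
    for i in range(k):
        for j in range(i + 1, k):
            sub = table[[variables[i], variables[j]]].dropna()
            nmat[i, j] = nmat[j, i] = len(sub)
            if len(sub) < 3:
                raise ValueError(
                    f"pair ({variables[i]}, {variables[j]}) has fewer than 3 complete rows"
                )
            res = spearman(sub[variables[i]].to_numpy(), sub[variables[j]].to_numpy())
            rho[i, j] = rho[j, i] = res.rho
            p[i, j] = p[j, i] = res.p
            pairs.append((i, j, res))
    p_adj = np.full((k, k), np.nan)
    finite = [(i, j) for i, j, r in pairs if np.isfinite(r.p)]
    if finite:
        raw = np.array([max(p[i, j], np.nextafter(0, 1)) for i, j in finite])
        adj = bh_adjust(raw)
        for (i, j), q in zip(finite, adj):
            p_adj[i, j] = p_adj[j, i] = q
    idx = pd.Index(variables)
    return CorrelationMatrix(
        variables=list(variables),
        rho=pd.DataFrame(rho, index=idx, columns=idx),
        p=pd.DataFrame(p, index=idx, columns=idx),
        p_adjusted=pd.DataFrame(p_adj, index=idx, columns=idx),
        n=pd.DataFrame(nmat, index=idx, columns=idx),
    )
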