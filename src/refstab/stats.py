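"""Statistical primitives: t-tests, BH adjustment, exact rank tests.

Every routine here is self-contained (only scipy distribution functions are
used for tail probabilities) so that small-sample exact modes behave
identically across platforms and can be checked against brute-force
enumeration oracles:

* two-sample t (pooled or Welch), with documented degenerate conventions,
* Benjamini-Hochberg step-up FDR adjustment,
* Wilcoxon rank-sum with an exact permutation null (midranks for ties),
* Wilcoxon signed-rank with exact sign-flip enumeration,
* Kruskal-Wallis omnibus with Dunn's post hoc z-tests (tie-corrected).

Two-sided p-values throughout; exact two-sided p is ``min(1, 2 * min(lower
tail, upper tail))`` of the discrete null distribution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats as _sps

__all__ = [
    "TestResult",
    "two_sample_t",
    "bh_adjust",
    "wilcoxon_rank_sum",
    "wilcoxon_signed_rank",
    "kruskal_dunn",
    "pairwise_t_pvalues",
]

#: smallest representable positive double, returned when a zero-variance
#: contrast makes p underflow
TINY_P = float(np.nextafter(0.0, 1.0))


@dataclass
class TestResult:
    statistic: float
    p_value: float
    method: str
    n_per_group: tuple[int, ...]
    df: float | None = None
    flags: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not 0 < self.p_value <= 1:
            raise ValueError(f"p-value {self.p_value} outside (0, 1]")


def _check_groups(*groups: Sequence[float], minimum: int = 1) -> list[np.ndarray]:
    arrs = [np.asarray(g, dtype=float).ravel() for g in groups]
    for i, a in enumerate(arrs):
        if a.size < minimum:
            raise ValueError(f"group {i} needs >= {minimum} values, got {a.size}")
        if np.any(np.isnan(a)):
            raise ValueError(f"group {i} contains NaN")
    return arrs


# ---------------------------------------------------------------------------
# t-tests
# ---------------------------------------------------------------------------

def two_sample_t(x, y, flavor: str = "pooled") -> TestResult:
    """Two-sided two-sample t-test.

    ``pooled`` uses the equal-variance statistic with ``nx + ny - 2``
    degrees of freedom; ``welch`` uses the Welch-Satterthwaite
    approximation. Degenerate conventions: zero variance in both groups
    with equal means gives p = 1 (statistic 0); zero variance with unequal
    means gives the smallest positive double with a ``zero_variance`` flag.
    """
    x, y = _check_groups(x, y, minimum=2)
    nx, ny = x.size, y.size
    mx, my = x.mean(), y.mean()
    vx, vy = x.var(ddof=1), y.var(ddof=1)

    if flavor == "pooled":
        df = nx + ny - 2
        sp2 = ((nx - 1) * vx + (ny - 1) * vy) / df
        se = math.sqrt(sp2 * (1 / nx + 1 / ny))
        method = "pooled_t"
    elif flavor == "welch":
        a, b = vx / nx, vy / ny
        se = math.sqrt(a + b)
        if se > 0:
            df = (a + b) ** 2 / (a**2 / (nx - 1) + b**2 / (ny - 1))
        else:
            df = nx + ny - 2
        method = "welch_t"
    else:
        raise ValueError(f"unknown t-test flavor {flavor!r}")

    if se == 0:
        if mx == my:
            return TestResult(0.0, 1.0, method, (nx, ny), df, {"degenerate"})
        stat = math.copysign(math.inf, mx - my)
        return TestResult(stat, TINY_P, method, (nx, ny), df, {"zero_variance"})

    t = (mx - my) / se
    p = 2 * _sps.t.sf(abs(t), df)
    return TestResult(float(t), float(min(max(p, TINY_P), 1.0)), method, (nx, ny), df)


def pairwise_t_pvalues(
    values: np.ndarray, group_cols: Sequence[np.ndarray], flavor: str = "pooled"
) -> np.ndarray:
    """Vectorized two-sided t-test p-values for every row and group pairing.

    Parameters
    ----------
    values
        Gene x sample array.
    group_cols
        One integer column-index array per group, in canonical order.

    Returns
    -------
    Array of shape (n_rows, n_pairings) with pairings enumerated as
    (0,1), (0,2), ..., (1,2), ... Rows with zero pooled variance follow the
    :func:`two_sample_t` degenerate conventions.
    """
    values = np.asarray(values, dtype=float)
    means = [values[:, c].mean(axis=1) for c in group_cols]
    varis = [values[:, c].var(axis=1, ddof=1) for c in group_cols]
    ns = [len(c) for c in group_cols]
    pairs = [(i, j) for i in range(len(group_cols)) for j in range(i + 1, len(group_cols))]
    out = np.empty((values.shape[0], len(pairs)))
    for k, (i, j) in enumerate(pairs):
        ni, nj = ns[i], ns[j]
        diff = means[i] - means[j]
        if flavor == "pooled":
            df = np.full(values.shape[0], ni + nj - 2, dtype=float)
            sp2 = ((ni - 1) * varis[i] + (nj - 1) * varis[j]) / (ni + nj - 2)
            se2 = sp2 * (1 / ni + 1 / nj)
        elif flavor == "welch":
            a, b = varis[i] / ni, varis[j] / nj
            se2 = a + b
            with np.errstate(divide="ignore", invalid="ignore"):
                df = se2**2 / (a**2 / (ni - 1) + b**2 / (nj - 1))
            df = np.where(np.isfinite(df), df, ni + nj - 2)
        else:
            raise ValueError(f"unknown t-test flavor {flavor!r}")
        with np.errstate(divide="ignore", invalid="ignore"):
            t = diff / np.sqrt(se2)
        p = 2 * _sps.t.sf(np.abs(t), df)
        degenerate = se2 == 0
        p[degenerate & (diff == 0)] = 1.0
        p[degenerate & (diff != 0)] = TINY_P
        out[:, k] = np.clip(p, TINY_P, 1.0)
    return out


# ---------------------------------------------------------------------------
# FDR
# ---------------------------------------------------------------------------

def bh_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adjusted, 1.0)
    return out


# ---------------------------------------------------------------------------
# exact discrete null distributions (shift-algorithm dynamic programs)
# ---------------------------------------------------------------------------

def _subset_sum_distribution(scaled_ranks: np.ndarray, k: int) -> np.ndarray:
    """Count size-``k`` subsets of ``scaled_ranks`` by sum.

    Returns counts[s] = number of k-subsets with sum s, for integer-scaled
    rank values. This is the exact permutation null of the rank-sum
    statistic under random group assignment, valid with midrank ties.
    """
    total = int(scaled_ranks.sum())
    counts = np.zeros((k + 1, total + 1), dtype=float)
    counts[0, 0] = 1.0
    for r in scaled_ranks:
        r = int(r)
        upper = min(k, len(scaled_ranks))
        counts[1 : upper + 1, r:] += counts[0:upper, : total + 1 - r]
    return counts[k]


def _all_subset_sum_distribution(scaled_ranks: np.ndarray) -> np.ndarray:
    """Count subsets (any size) of ``scaled_ranks`` by sum: signed-rank null."""
    total = int(scaled_ranks.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in scaled_ranks:
        r = int(r)
        counts[r:] += counts[: total + 1 - r]
    return counts


def _two_sided_discrete_p(counts: np.ndarray, w_scaled: int) -> float:
    total = counts.sum()
    lower = counts[: w_scaled + 1].sum() / total
    upper = counts[w_scaled:].sum() / total
    return float(min(1.0, 2 * min(lower, upper)))


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum
# ---------------------------------------------------------------------------

def wilcoxon_rank_sum(x, y, mode: str = "auto") -> TestResult:
    """Two-sided Wilcoxon (Mann-Whitney) rank-sum test.

    ``exact`` enumerates the permutation null of the rank-sum of the first
    group over all C(n, nx) group assignments (midranks for ties); ``normal``
    uses the tie-adjusted normal approximation with continuity correction.
    ``auto`` selects exact when both groups have <= 12 values.
    """
    x, y = _check_groups(x, y, minimum=1)
    nx, ny = x.size, y.size
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return TestResult(0.0, 1.0, "wilcoxon_rank_sum_exact", (nx, ny), flags={"degenerate"})
    ranks = _sps.rankdata(pooled)
    w = ranks[:nx].sum()

    if mode == "auto":
        mode = "exact" if max(nx, ny) <= 12 else "normal"
    if mode == "exact":
        scaled = np.round(ranks * 2).astype(int)
        counts = _subset_sum_distribution(scaled, nx)
        p = _two_sided_discrete_p(counts, int(round(w * 2)))
        return TestResult(float(w), p, "wilcoxon_rank_sum_exact", (nx, ny))
    if mode != "normal":
        raise ValueError(f"unknown mode {mode!r}")

    n = nx + ny
    mu = nx * (n + 1) / 2
    _, tie_counts = np.unique(ranks, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum()
    var = nx * ny / 12 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        return TestResult(float(w), 1.0, "wilcoxon_rank_sum_normal", (nx, ny), flags={"degenerate"})
    # continuity correction toward the mean
    z = (w - mu - 0.5 * np.sign(w - mu)) / math.sqrt(var)
    p = 2 * _sps.norm.sf(abs(z))
    return TestResult(float(w), float(min(max(p, TINY_P), 1.0)), "wilcoxon_rank_sum_normal", (nx, ny))


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank
# ---------------------------------------------------------------------------

def wilcoxon_signed_rank(before, after, mode: str = "auto") -> TestResult:
    """Two-sided Wilcoxon signed-rank test on paired vectors.

    Differences are ``after - before``; zero differences are dropped
    (Wilcoxon's original convention). Exact mode enumerates all 2^n sign
    assignments of the midranked absolute differences; used automatically
    for n <= 15.
    """
    before, after = _check_groups(before, after, minimum=1)
    if before.size != after.size:
        raise ValueError("paired vectors must have equal length")
    d = after - before
    d = d[d != 0]
    n = d.size
    if n == 0:
        return TestResult(0.0, 1.0, "signed_rank_exact", (before.size,), flags={"degenerate"})
    ranks = _sps.rankdata(np.abs(d))
    w_pos = ranks[d > 0].sum()

    if mode == "auto":
        mode = "exact" if n <= 15 else "normal"
    if mode == "exact":
        scaled = np.round(ranks * 2).astype(int)
        counts = _all_subset_sum_distribution(scaled)
        p = _two_sided_discrete_p(counts, int(round(w_pos * 2)))
        return TestResult(float(w_pos), p, "signed_rank_exact", (before.size,))
    if mode != "normal":
        raise ValueError(f"unknown mode {mode!r}")

    mu = n * (n + 1) / 4
    _, tie_counts = np.unique(ranks, return_counts=True)
    var = n * (n + 1) * (2 * n + 1) / 24 - (tie_counts**3 - tie_counts).sum() / 48
    if var <= 0:
        return TestResult(float(w_pos), 1.0, "signed_rank_normal", (before.size,), flags={"degenerate"})
    z = (w_pos - mu - 0.5 * np.sign(w_pos - mu)) / math.sqrt(var)
    p = 2 * _sps.norm.sf(abs(z))
    return TestResult(float(w_pos), float(min(max(p, TINY_P), 1.0)), "signed_rank_normal", (before.size,))


# ---------------------------------------------------------------------------
# Kruskal-Wallis + Dunn
# ---------------------------------------------------------------------------

def kruskal_dunn(
    groups: Sequence[Sequence[float]], adjust_dunn: bool = False
) -> tuple[TestResult, dict[tuple[int, int], TestResult]]:
    """Tie-corrected Kruskal-Wallis omnibus test with Dunn's post hoc z-tests.

    Returns the omnibus result (chi-square with g-1 df) and a map from
    group-index pairing to the Dunn pairwise result. Dunn p-values are
    unadjusted by default; ``adjust_dunn`` applies BH across the pairings.
    Fewer than three groups is an error: use :func:`wilcoxon_rank_sum`.
    """
    arrs = _check_groups(*groups, minimum=2)
    g = len(arrs)
    if g < 3:
        raise ValueError("kruskal_dunn needs >= 3 groups; use wilcoxon_rank_sum for two")
    ns = np.array([a.size for a in arrs])
    n = int(ns.sum())
    pooled = np.concatenate(arrs)
    ranks = _sps.rankdata(pooled)
    bounds = np.cumsum(ns)[:-1]
    group_ranks = np.split(ranks, bounds)
    mean_ranks = np.array([r.mean() for r in group_ranks])

    h = 12 / (n * (n + 1)) * (ns * mean_ranks**2).sum() - 3 * (n + 1)
    _, tie_counts = np.unique(ranks, return_counts=True)
    tie_corr = 1 - (tie_counts**3 - tie_counts).sum() / (n**3 - n)
    if tie_corr == 0:
        omnibus = TestResult(0.0, 1.0, "kruskal_wallis", tuple(ns), df=g - 1, flags={"degenerate"})
        return omnibus, {
            (i, j): TestResult(0.0, 1.0, "dunn", (int(ns[i]), int(ns[j])), flags={"degenerate"})
            for i in range(g)
            for j in range(i + 1, g)
        }
    h /= tie_corr
    p_omni = _sps.chi2.sf(h, g - 1)
    omnibus = TestResult(float(h), float(min(max(p_omni, TINY_P), 1.0)), "kruskal_wallis", tuple(ns), df=g - 1)

    sigma2 = n * (n + 1) / 12 - (tie_counts**3 - tie_counts).sum() / (12 * (n - 1))
    pairs = [(i, j) for i in range(g) for j in range(i + 1, g)]
    zs, ps = [], []
    for i, j in pairs:
        se = math.sqrt(sigma2 * (1 / ns[i] + 1 / ns[j]))
        z = (mean_ranks[i] - mean_ranks[j]) / se
        zs.append(z)
        ps.append(2 * _sps.norm.sf(abs(z)))
    if adjust_dunn:
        ps = list(bh_adjust(np.clip(ps, TINY_P, 1.0)))
    pairwise = {
        (i, j): TestResult(
            float(z), float(min(max(p, TINY_P), 1.0)), "dunn", (int(ns[i]), int(ns[j]))
        )
        for (i, j), z, p in zip(pairs, zs, ps)
    }
    return omnibus, pairwise
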