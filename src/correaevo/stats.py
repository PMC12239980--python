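"""Statistical tests used across the pipeline.

Self-contained implementations of the tests the analysis relies on:
two-sided Fisher's exact test (point-probability rule), the Wilcoxon
rank-sum test (exact enumeration for small untied samples, tie- and
continuity-corrected normal approximation otherwise), the Kruskal-Wallis
test with Dunn's post-hoc comparisons, and Cuzick's test for trend across
ordered groups (the Correa order IM < LGIN < HGIN < EGC by default).

Cuzick's trend statistic for groups :math:`g = 1..k` with scores
:math:`z_g` and pooled mid-ranks is

.. math::

    T = \\sum_g z_g R_g, \\qquad
    E[T] = \\frac{N+1}{2} \\sum_g z_g n_g,

with the permutation-null variance

.. math::

    \\mathrm{Var}[T] = \\frac{N+1}{12}
        \\Big( N \\sum_g n_g z_g^2 - \\big(\\sum_g n_g z_g\\big)^2 \\Big)
        \\cdot \\Big( 1 - \\frac{\\sum_t (t^3 - t)}{N^3 - N} \\Big),

where the last factor corrects for ties of multiplicity :math:`t`.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "TrendResult",
    "KruskalDunnResult",
    "fisher_exact",
    "wilcoxon_rank_sum",
    "kruskal_wallis_dunn",
    "cuzick_trend",
]

#: Relative slack when comparing point probabilities in the two-sided
#: Fisher rule, to absorb floating-point noise in the pmf.
_FISHER_SLACK = 1e-7


def fisher_exact(table: Sequence[Sequence[int]]) -> float:
    """Two-sided Fisher's exact test on a 2x2 table.

    Sums the hypergeometric probabilities of every table with the same
    margins whose point probability does not exceed that of the observed
    table (point-probability rule).
    """
    (a, b), (c, d) = table
    cells = (a, b, c, d)
    if any(x < 0 for x in cells):
        raise ValueError(f"negative cell in 2x2 table {table}")
    if all(x == 0 for x in cells):
        raise ValueError("all margins zero")
    n = a + b + c + d
    row1 = a + b
    col1 = a + c
    lo = max(0, col1 - (n - row1))
    hi = min(row1, col1)
    support = np.arange(lo, hi + 1)
    pmf = sps.hypergeom.pmf(support, n, row1, col1)
    p_obs = pmf[a - lo]
    p = float(pmf[pmf <= p_obs * (1.0 + _FISHER_SLACK)].sum())
    if p >= 1.0 - 1e-9:  # full support included; snap summation noise
        return 1.0
    return min(p, 1.0)


def wilcoxon_rank_sum(x: Sequence[float], y: Sequence[float]) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value.

    Uses full enumeration of the rank-sum permutation distribution when the
    smaller group has at most 8 observations and the pooled data are free
    of ties; otherwise a normal approximation with tie and continuity
    corrections. The exact two-sided p is twice the smaller tail, capped
    at 1.
    """
    x = list(map(float, x))
    y = list(map(float, y))
    if not x or not y:
        raise ValueError("both groups must be non-empty")
    pooled = x + y
    n, m = len(x), len(y)
    has_ties = len(set(pooled)) < len(pooled)
    if min(n, m) <= 8 and not has_ties:
        return _exact_rank_sum_p(x, y)
    return _normal_rank_sum_p(x, y)


def _exact_rank_sum_p(x: list[float], y: list[float]) -> float:
    if len(x) > len(y):  # enumerate over the smaller group
        x, y = y, x
    n, m = len(x), len(y)
    ranks = sps.rankdata(x + y)
    w_obs = float(ranks[:n].sum())
    total = math.comb(n + m, n)
    idx = range(n + m)
    lower = higher = 0
    for combo in itertools.combinations(idx, n):
        w = float(ranks[list(combo)].sum())
        if w <= w_obs + 1e-12:
            lower += 1
        if w >= w_obs - 1e-12:
            higher += 1
    p = 2.0 * min(lower, higher) / total
    return min(p, 1.0)


def _normal_rank_sum_p(x: list[float], y: list[float]) -> float:
    n, m = len(x), len(y)
    N = n + m
    pooled = np.asarray(x + y)
    ranks = sps.rankdata(pooled)
    w = ranks[:n].sum()
    mu = n * (N + 1) / 2.0
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = ((counts**3 - counts).sum()) / ((N) * (N - 1)) if N > 1 else 0.0
    var = n * m / 12.0 * ((N + 1) - tie_term)
    if var <= 0:
        return 1.0  # all observations identical
    z = (abs(w - mu) - 0.5) / math.sqrt(var)
    z = max(z, 0.0)
    return float(2.0 * sps.norm.sf(z))


@dataclass
class KruskalDunnResult:
    h: float
    p_global: float
    pairwise: pd.DataFrame  # columns: group_a, group_b, z, p_raw, p_adjusted
    degenerate: bool = False


def kruskal_wallis_dunn(groups: Sequence[Sequence[float]],
                        adjust: str = "none") -> KruskalDunnResult:
    """Kruskal-Wallis H test with Dunn's pairwise post-hoc comparisons.

    H is tie-corrected and referred to a chi-square with k-1 degrees of
    freedom. Dunn z statistics use the pooled-rank variance with tie
    correction. ``adjust`` is one of none | holm | bonferroni.
    """
    if len(groups) < 3:
        raise ValueError("need at least 3 groups")
    if any(len(g) == 0 for g in groups):
        raise ValueError("every group must be non-empty")
    if adjust not in ("none", "holm", "bonferroni"):
        raise ValueError(f"unknown adjustment {adjust!r}")
    sizes = [len(g) for g in groups]
    pooled = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    N = len(pooled)
    ranks = sps.rankdata(pooled)
    _, counts = np.unique(pooled, return_counts=True)
    tie_sum = float((counts**3 - counts).sum())
    degenerate = len(counts) == 1  # every observation identical

    bounds = np.cumsum([0] + sizes)
    rank_sums = [ranks[bounds[i]:bounds[i + 1]].sum() for i in range(len(groups))]
    h = 12.0 / (N * (N + 1)) * sum(r**2 / n for r, n in zip(rank_sums, sizes)) \
        - 3.0 * (N + 1)
    correction = 1.0 - tie_sum / (N**3 - N) if N > 1 else 0.0
    if correction > 0:
        h /= correction
    else:
        h = 0.0
    df = len(groups) - 1
    p_global = 1.0 if degenerate else float(sps.chi2.sf(h, df))

    mean_ranks = [r / n for r, n in zip(rank_sums, sizes)]
    var_base = N * (N + 1) / 12.0 - tie_sum / (12.0 * (N - 1)) if N > 1 else 0.0
    rows = []
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            se2 = var_base * (1.0 / sizes[i] + 1.0 / sizes[j])
            if se2 <= 0:
                z = 0.0
            else:
                z = (mean_ranks[i] - mean_ranks[j]) / math.sqrt(se2)
            rows.append({"group_a": i, "group_b": j, "z": z,
                         "p_raw": float(2.0 * sps.norm.sf(abs(z)))})
    pairwise = pd.DataFrame(rows, columns=["group_a", "group_b", "z", "p_raw"])
    pairwise["p_adjusted"] = _adjust_pvalues(pairwise["p_raw"].to_numpy(), adjust)
    return KruskalDunnResult(h=float(h), p_global=p_global, pairwise=pairwise,
                             degenerate=degenerate)


def _adjust_pvalues(p: np.ndarray, method: str) -> np.ndarray:
    if method == "none":
        return p.copy()
    from statsmodels.stats.multitest import multipletests
    return multipletests(p, method=method)[1]


@dataclass
class TrendResult:
    """Cuzick trend-test result: z statistic, two-sided p, group scores."""

    z: float
    p: float
    group_scores: list[tuple[object, float]] = field(default_factory=list)
    degenerate: bool = False


def cuzick_trend(groups: Sequence[Sequence[float]],
                 scores: Sequence[float] | None = None,
                 labels: Sequence[object] | None = None,
                 method: str = "normal") -> TrendResult:
    """Cuzick's nonparametric test for trend across ordered groups.

    Groups must be supplied in their natural order; scores default to the
    consecutive integers 1..k. With ``method="normal"`` (default) the
    two-sided p comes from the standard normal; ``method="exact"``
    enumerates the full permutation null of T (distance from its mean)
    for small samples, where the discrete null makes the normal
    approximation visibly coarse.
    """
    if len(groups) < 3:
        raise ValueError("need at least 3 ordered groups")
    if any(len(g) == 0 for g in groups):
        raise ValueError("every group must be non-empty")
    k = len(groups)
    z_scores = np.asarray(scores if scores is not None else range(1, k + 1),
                          dtype=float)
    if len(z_scores) != k:
        raise ValueError("one score per group required")
    labels = list(labels) if labels is not None else list(range(1, k + 1))

    sizes = np.array([len(g) for g in groups])
    pooled = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    N = len(pooled)
    ranks = sps.rankdata(pooled)
    _, counts = np.unique(pooled, return_counts=True)
    if len(counts) == 1:
        return TrendResult(z=0.0, p=1.0,
                           group_scores=list(zip(labels, z_scores)),
                           degenerate=True)
    bounds = np.cumsum([0, *sizes])
    rank_sums = np.array([ranks[bounds[i]:bounds[i + 1]].sum()
                          for i in range(k)])
    t_stat = float((z_scores * rank_sums).sum())
    L = float((z_scores * sizes).sum())
    e_t = (N + 1) / 2.0 * L
    tie_correction = 1.0 - float((counts**3 - counts).sum()) / (N**3 - N)
    var_t = (N + 1) / 12.0 * (N * float((sizes * z_scores**2).sum()) - L**2) \
        * tie_correction
    if var_t <= 0:
        return TrendResult(z=0.0, p=1.0,
                           group_scores=list(zip(labels, z_scores)),
                           degenerate=True)
    z = (t_stat - e_t) / math.sqrt(var_t)
    if method == "exact":
        p = _cuzick_exact_p(ranks, sizes, z_scores, t_stat)
    elif method == "normal":
        p = float(2.0 * sps.norm.sf(abs(z)))
    else:
        raise ValueError(f"method must be normal|exact, got {method!r}")
    return TrendResult(z=float(z), p=p,
                       group_scores=list(zip(labels, z_scores)))


_MAX_EXACT_ARRANGEMENTS = 200_000


def _cuzick_exact_p(ranks: np.ndarray, sizes: np.ndarray,
                    z_scores: np.ndarray, t_obs: float) -> float:
    """Exhaustive permutation null of T over all group assignments."""
    N = len(ranks)
    arrangements = math.factorial(N)
    for n in sizes:
        arrangements //= math.factorial(int(n))
    if arrangements > _MAX_EXACT_ARRANGEMENTS:
        raise ValueError(
            f"{arrangements} arrangements exceed the exact-method limit "
            f"({_MAX_EXACT_ARRANGEMENTS}); use method='normal'")

    ranks = np.asarray(ranks, dtype=float)
    t_values: list[float] = []

    def assign(remaining: tuple[int, ...], group: int, acc: float) -> None:
        if group == len(sizes) - 1:
            t_values.append(acc + z_scores[group]
                            * float(ranks[list(remaining)].sum()))
            return
        for combo in itertools.combinations(remaining, int(sizes[group])):
            rest = tuple(i for i in remaining if i not in combo)
            assign(rest, group + 1,
                   acc + z_scores[group] * float(ranks[list(combo)].sum()))

    assign(tuple(range(N)), 0, 0.0)
    ts = np.array(t_values)
    centre = ts.mean()
    return float((np.abs(ts - centre) >= abs(t_obs - centre) - 1e-9).mean())
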