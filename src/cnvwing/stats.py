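"""Nonparametric statistics shared across the pipeline stages.

Thin, defensively-specified wrappers around scipy/statsmodels: the screen
relies on Mann-Whitney U (exact for small tie-free samples, normal
approximation with tie and continuity correction otherwise), two-tailed and
one-tailed Fisher exact tests, Kruskal-Wallis with tie correction and
post-hoc pairwise Wilcoxon tests, Welch's unequal-variance t-test, and
Benjamini-Hochberg step-up FDR control.  Degenerate inputs (identical
samples, empty margins) return p = 1 rather than NaN so that downstream
multiple-testing families stay well formed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "MannWhitneyResult",
    "FisherResult",
    "KruskalResult",
    "WelchResult",
    "mann_whitney",
    "bh_adjust",
    "fisher_2x2",
    "kruskal_wallis",
    "pairwise_wilcoxon",
    "welch_t",
]

# Exact Mann-Whitney enumeration is used at or below this combined n when the
# pooled sample is tie-free; beyond it the normal approximation is accurate.
_EXACT_MAX_N = 12


@dataclass(frozen=True)
class MannWhitneyResult:
    u: float
    p: float
    method: str


@dataclass(frozen=True)
class FisherResult:
    table: tuple[tuple[int, int], tuple[int, int]]
    odds_ratio: float
    p: float


@dataclass(frozen=True)
class KruskalResult:
    h: float
    df: int
    p: float


@dataclass(frozen=True)
class WelchResult:
    t: float
    df: float
    p: float


def mann_whitney(
    a: Sequence[float],
    b: Sequence[float],
    alternative: str = "two-sided",
) -> MannWhitneyResult:
    """Mann-Whitney U test of ``a`` versus ``b``.

    The U statistic uses midranks for ties.  The p-value is exact (full
    enumeration of labelings) when the combined sample size is at most 12
    and tie-free; otherwise the normal approximation with tie and
    continuity correction is used.  Identical constant samples give p = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        # no information in ranks at all
        return MannWhitneyResult(u=a.size * b.size / 2.0, p=1.0, method="degenerate")
    has_ties = np.unique(pooled).size < pooled.size
    if a.size + b.size <= _EXACT_MAX_N and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative=alternative, method=method)
    return MannWhitneyResult(u=float(res.statistic), p=float(res.pvalue), method=method)


def bh_adjust(p_values: Iterable[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values, in input order.

    q_(i) = min_{j>=i} p_(j) * m / j on the sorted p-values, capped at 1.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def fisher_2x2(
    table: Sequence[Sequence[int]],
    alternative: str = "two-sided",
) -> FisherResult:
    """Fisher's exact test on a 2x2 contingency table.

    Two-sided p sums the probabilities of all tables (at fixed margins)
    whose point probability does not exceed that of the observed table.
    An empty margin carries no information: p = 1 with a warning.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if (t < 0).any():
        raise ValueError("table counts must be nonnegative")
    tab = ((int(t[0, 0]), int(t[0, 1])), (int(t[1, 0]), int(t[1, 1])))
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        warnings.warn("empty margin in 2x2 table; p set to 1", stacklevel=2)
        return FisherResult(table=tab, odds_ratio=float("nan"), p=1.0)
    odds, p = sps.fisher_exact(t, alternative=alternative)
    return FisherResult(table=tab, odds_ratio=float(odds), p=float(p))


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> KruskalResult:
    """Tie-corrected Kruskal-Wallis H across two or more groups.

    df = number of groups - 1; p from the chi-square distribution.  When all
    observations across all groups are equal, H = 0 and p = 1 by convention.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("kruskal_wallis needs at least 2 groups")
    if any(g.size == 0 for g in groups):
        raise ValueError("all groups must be nonempty")
    df = len(groups) - 1
    pooled = np.concatenate(groups)
    if np.ptp(pooled) == 0:
        return KruskalResult(h=0.0, df=df, p=1.0)
    h, p = sps.kruskal(*groups)
    return KruskalResult(h=float(h), df=df, p=float(p))


def pairwise_wilcoxon(
    groups: dict[str, Sequence[float]],
) -> list[dict]:
    """Post-hoc pairwise two-tailed Wilcoxon rank-sum tests with BH correction.

    Returns one record per unordered group pair with raw p and BH q over
    all pairs.
    """
    names = list(groups)
    pairs = list(combinations(names, 2))
    raw = [mann_whitney(groups[x], groups[y], "two-sided").p for x, y in pairs]
    qs = bh_adjust(raw) if raw else np.array([])
    return [
        {"group_a": x, "group_b": y, "p": p, "q": float(q)}
        for (x, y), p, q in zip(pairs, raw, qs)
    ]


def welch_t(a: Sequence[float], b: Sequence[float]) -> WelchResult:
    """Two-tailed Welch's t-test (unequal variances, Welch-Satterthwaite df).

    Identical zero-variance groups give t = 0, p = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("welch_t needs at least 2 observations per group")
    if np.var(a) == 0 and np.var(b) == 0:
        if np.mean(a) == np.mean(b):
            return WelchResult(t=0.0, df=float(a.size + b.size - 2), p=1.0)
    res = sps.ttest_ind(a, b, equal_var=False)
    return WelchResult(t=float(res.statistic), df=float(res.df), p=float(res.pvalue))
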