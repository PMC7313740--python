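"""Independent brute-force oracles used to check the statistical wrappers.

Everything here is deliberately naive — full enumeration, no clever
shortcuts — and shares no code path with the package implementation.
"""

from __future__ import annotations

from itertools import combinations
from math import comb, inf

import numpy as np


def mw_u_stat(a, b) -> float:
    """Mann-Whitney U of sample a (pairwise comparison count, midrank ties)."""
    u = 0.0
    for x in a:
        for y in b:
            if x > y:
                u += 1.0
            elif x == y:
                u += 0.5
    return u


def mw_exact_p(a, b, alternative="two-sided") -> float:
    """Exact Mann-Whitney p by enumerating all labelings of the pooled sample."""
    pooled = list(a) + list(b)
    n_a = len(a)
    idx = range(len(pooled))
    u_obs = mw_u_stat(a, b)
    mu = n_a * len(b) / 2.0
    count = 0
    total = 0
    for pick in combinations(idx, n_a):
        sa = [pooled[i] for i in pick]
        sb = [pooled[i] for i in idx if i not in pick]
        u = mw_u_stat(sa, sb)
        if alternative == "two-sided":
            hit = abs(u - mu) >= abs(u_obs - mu) - 1e-12
        elif alternative == "greater":
            hit = u >= u_obs - 1e-12
        else:
            hit = u <= u_obs + 1e-12
        count += hit
        total += 1
    return count / total


def fisher_exact_p(table, alternative="two-sided") -> float:
    """Fisher exact p by hypergeometric enumeration at fixed margins."""
    (a, b), (c, d) = table
    row1, col1, n = a + b, a + c, a + b + c + d

    def point(x):
        return comb(col1, x) * comb(n - col1, row1 - x) / comb(n, row1)

    lo, hi = max(0, row1 + col1 - n), min(row1, col1)
    p_obs = point(a)
    total = 0.0
    for x in range(lo, hi + 1):
        px = point(x)
        if alternative == "two-sided":
            if px <= p_obs * (1 + 1e-9):
                total += px
        elif alternative == "greater":
            if x >= a:
                total += px
        else:
            if x <= a:
                total += px
    return min(total, 1.0)


def bh_stepup(p_values) -> np.ndarray:
    """Textbook BH step-up: q_(i) = min_{j>=i} p_(j) * m / j, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    q_sorted = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def brute_shortest_path(edges: dict, source, target):
    """Minimum-weight simple path by exhaustive DFS enumeration.

    ``edges`` maps frozenset({u, v}) -> weight.  Returns (length, best path
    as node list) or (inf, None) when unreachable.
    """
    adj: dict = {}
    for key, w in edges.items():
        u, v = sorted(key)
        adj.setdefault(u, {})[v] = w
        adj.setdefault(v, {})[u] = w
    found: list[tuple[float, list]] = []

    def dfs(node, length, path):
        if node == target:
            found.append((length, list(path)))
            return
        for nxt, w in sorted(adj.get(node, {}).items()):
            if nxt not in path:
                path.append(nxt)
                dfs(nxt, length + w, path)
                path.pop()

    if source in adj:
        dfs(source, 0.0, [source])
    if not found:
        return inf, None
    mn = min(l for l, _ in found)
    tied = [p for l, p in found if l <= mn + 1e-9 * max(1.0, mn)]
    return mn, min(tied)
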