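"""Independent brute-force oracles used by the test suite.

Everything here is implemented from first principles (enumeration, closed
forms, textbook formulas) and never calls the package code it checks.
"""

from __future__ import annotations

import itertools
from math import comb, sqrt

import numpy as np
from numba import njit


# ---------------------------------------------------------------------------
# exhaustive spin-glass partition oracle
# ---------------------------------------------------------------------------

@njit(cache=False)
def _enumerate_partitions_best(Q, seed_idx):
    """Minimize H = -sum_{i<j same block} Q[i,j] over all set partitions.

    Enumerates restricted growth strings.  Returns (best_H, seed_mask,
    n_ambiguous) where n_ambiguous counts optima whose seed block differs
    from the recorded one.
    """
    n = Q.shape[0]
    a = np.zeros(n, dtype=np.int64)
    m = np.zeros(n, dtype=np.int64)  # running max of a[0..i]
    best_h = 1e300
    best_mask = np.zeros(n, dtype=np.bool_)
    n_amb = 0
    while True:
        h = 0.0
        for i in range(n):
            for j in range(i + 1, n):
                if a[i] == a[j]:
                    h -= Q[i, j]
        if h < best_h - 1e-9:
            best_h = h
            for i in range(n):
                best_mask[i] = a[i] == a[seed_idx]
            n_amb = 0
        elif h <= best_h + 1e-9:
            differs = False
            for i in range(n):
                if best_mask[i] != (a[i] == a[seed_idx]):
                    differs = True
                    break
            if differs:
                n_amb += 1
        # next restricted growth string
        i = n - 1
        while i > 0 and a[i] > m[i - 1]:
            i -= 1
        if i == 0:
            break
        a[i] += 1
        if a[i] > m[i]:
            m[i] = a[i]
        for j in range(i + 1, n):
            a[j] = 0
            m[j] = m[i]
        # recompute running max (a[j] reset to 0 keeps m flat after i)
        for j in range(i + 1, n):
            m[j] = m[j - 1]
        if a[i] > n - 1:
            break
    return best_h, best_mask, n_amb


def exhaustive_seed_community(adj: np.ndarray, gamma: float, seed_idx: int):
    """Best-partition community of ``seed_idx`` by exhaustive enumeration.

    ``adj`` is a dense symmetric weighted adjacency matrix.  The pair
    quality is Q_ij = w_ij - gamma * s_i s_j / (2W) with s the strengths.
    Returns (members_index_set, best_H, n_ambiguous).
    """
    adj = np.asarray(adj, dtype=float)
    s = adj.sum(axis=1)
    two_w = s.sum()
    Q = adj - gamma * np.outer(s, s) / two_w
    best_h, mask, n_amb = _enumerate_partitions_best(Q, seed_idx)
    return set(np.flatnonzero(mask)), float(best_h), int(n_amb)


# ---------------------------------------------------------------------------
# classical statistics oracles
# ---------------------------------------------------------------------------

def pooled_t(case: np.ndarray, control: np.ndarray) -> float:
    """Textbook two-sample pooled-variance t statistic."""
    n1, n2 = len(case), len(control)
    m1, m2 = sum(case) / n1, sum(control) / n2
    ss = sum((v - m1) ** 2 for v in case) + sum((v - m2) ** 2 for v in control)
    sp2 = ss / (n1 + n2 - 2)
    return (m1 - m2) / sqrt(sp2 * (1 / n1 + 1 / n2))


def bh_adjust(p: list[float]) -> list[float]:
    """Benjamini-Hochberg step-up, straight from the definition."""
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q = [0.0] * m
    for pos, i in enumerate(order, start=1):
        # min over all larger-or-equal p of m*p_j/rank_j
        q[i] = min(
            m * p[j] / rank
            for rank, j in enumerate(order, start=1)
            if rank >= pos
        )
        q[i] = min(q[i], 1.0)
    return q


def hypergeom_point(k: int, N: int, K: int, n: int) -> float:
    """P(X = k) for drawing n from N with K marked."""
    if k < 0 or k > min(K, n) or n - k > N - K:
        return 0.0
    return comb(K, k) * comb(N - K, n - k) / comb(N, n)


def hypergeom_upper_tail(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k)."""
    return sum(hypergeom_point(j, N, K, n) for j in range(k, min(K, n) + 1))


def fisher_two_sided(table) -> float:
    """Two-sided Fisher exact p by enumerating all tables with the margins."""
    (a, b), (c, d) = table
    N = a + b + c + d
    K = a + b          # row-1 margin
    n = a + c          # col-1 margin
    p_obs = hypergeom_point(a, N, K, n)
    total = 0.0
    for k in range(0, min(K, n) + 1):
        pk = hypergeom_point(k, N, K, n)
        if pk <= p_obs * (1 + 1e-7):
            total += pk
    return min(total, 1.0)


def exact_permutation_pvalue(adj: np.ndarray, abs_t: np.ndarray, members) -> float:
    """Exact permutation p for module modularity on a tiny graph.

    Enumerates every assignment of the statistic multiset to the nodes and
    counts how often the module's total internal edge weight (recomputed
    as the mean-|t| weighting) is >= the observed one; the observed
    assignment is included in the count (so p is never 0).
    """
    n = len(abs_t)
    members = sorted(members)
    t_max = max(abs_t)
    edges = [(i, j) for i in range(n) for j in range(i + 1, n) if adj[i, j] > 0]
    internal = [(i, j) for i, j in edges if i in members and j in members]

    def modularity(assign):
        return sum((assign[i] + assign[j]) / (2 * t_max) for i, j in internal)

    m_obs = modularity(abs_t)
    hits = 0
    total = 0
    for perm in itertools.permutations(abs_t):
        total += 1
        if modularity(perm) >= m_obs - 1e-12:
            hits += 1
    return hits / total
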