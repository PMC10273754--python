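"""Independent brute-force oracles used to pin down the fast implementations.

Everything here is deliberately naive (triple loops, exhaustive
enumeration, fine-grained sums) and shares no code with the package.
"""

from __future__ import annotations

import itertools

import numpy as np


def clustering_triple_loop(A: np.ndarray) -> float:
    """Directed clustering by explicit triangle-pattern counting.

    For each node i, count closed three-node patterns through i: every
    ordered pair (j, k) of distinct neighbours contributes the product of
    link indicators (either direction) on legs i-j, j-k, i-k; divide by
    the number of possible patterns d(d-1) - 2d_bi evaluated by explicit
    neighbour counting.
    """
    A = np.asarray(A, dtype=int)
    n = A.shape[0]
    cs = []
    for i in range(n):
        t = 0.0
        for j in range(n):
            for k in range(n):
                if len({i, j, k}) < 3:
                    continue
                t += (A[i, j] + A[j, i]) * (A[j, k] + A[k, j]) * (A[i, k] + A[k, i])
        t /= 2.0
        d_tot = sum(A[i, j] + A[j, i] for j in range(n))
        d_bi = sum(A[i, j] * A[j, i] for j in range(n))
        denom = d_tot * (d_tot - 1) - 2 * d_bi
        cs.append(t / denom if denom > 0 else 0.0)
    return float(np.mean(cs)) if cs else 0.0


def efficiency_floyd_warshall(A: np.ndarray) -> float:
    """Global efficiency via an explicit Floyd-Warshall distance pass."""
    A = np.asarray(A, dtype=int)
    n = A.shape[0]
    if n < 2:
        return 0.0
    INF = float("inf")
    dist = [[0 if i == j else (1 if A[i, j] else INF) for j in range(n)] for i in range(n)]
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if dist[i][k] + dist[k][j] < dist[i][j]:
                    dist[i][j] = dist[i][k] + dist[k][j]
    total = 0.0
    for i in range(n):
        for j in range(n):
            if i != j and dist[i][j] < INF:
                total += 1.0 / dist[i][j]
    return total / (n * (n - 1))


def bh_step_up(p_values: np.ndarray, q: float) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg by the textbook step-up recipe."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    sorted_p = p[order]
    k_max = 0
    for k in range(1, m + 1):
        if sorted_p[k - 1] <= k * q / m:
            k_max = k
    rejected = np.zeros(m, dtype=bool)
    rejected[order[:k_max]] = True
    adj_sorted = np.minimum.accumulate((sorted_p * m / np.arange(1, m + 1))[::-1])[::-1]
    adj_sorted = np.minimum(adj_sorted, 1.0)
    adjusted = np.empty(m)
    adjusted[order] = adj_sorted
    return rejected, adjusted


def exact_mean_diff_pvalue(a: np.ndarray, b: np.ndarray) -> float:
    """Two-tailed permutation p by exhaustive enumeration of label splits."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    pooled = np.concatenate([a, b])
    n_a, n = a.size, a.size + b.size
    obs = abs(a.mean() - b.mean())
    count = total = 0
    for combo in itertools.combinations(range(n), n_a):
        sel = np.zeros(n, dtype=bool)
        sel[list(combo)] = True
        diff = abs(pooled[sel].mean() - pooled[~sel].mean())
        count += diff >= obs - 1e-12
        total += 1
    return count / total


def riemann_integral_on_knots(x: np.ndarray, y: np.ndarray, n_sub: int = 1000) -> float:
    """Fine midpoint Riemann sum of the piecewise-linear interpolant.

    Midpoints never cross knots, and the midpoint rule is exact for
    linear pieces, so this equals the trapezoidal integral to floating
    precision while being computed entirely differently.
    """
    total = 0.0
    for i in range(len(x) - 1):
        h = (x[i + 1] - x[i]) / n_sub
        mids = x[i] + h * (np.arange(n_sub) + 0.5)
        vals = y[i] + (y[i + 1] - y[i]) * (mids - x[i]) / (x[i + 1] - x[i])
        total += float(vals.sum() * h)
    return total


def lagged_pearson(x: np.ndarray, y: np.ndarray, d: int) -> float:
    """Definitional lagged Pearson correlation: x leads, y follows by d."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    xs = x[: len(x) - d] if d else x
    ys = y[d:]
    return float(np.corrcoef(xs, ys)[0, 1])
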