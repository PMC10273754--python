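"""Density thresholding and binary directed graph measures.

Weighted directed networks are binarised at a *proportional* threshold:
at density ``D`` the ``m = round(D · n(n−1))`` largest positive weights
become directed edges.  Because rank thresholding is nested, the edge set
at a lower density is always a subset of the edge set at a higher one.
Each measure is evaluated along a density sweep (default 5%..50% in 1%
steps, 46 points) and summarised by the trapezoidal area under the curve,
removing the dependence on any single threshold.

Measures (binary, directed):

* clustering coefficient — Fagiolo's directed generalisation of the
  fraction of closed triangles around a node, averaged over nodes;
* global efficiency — mean inverse shortest-path length over ordered
  node pairs, with unreachable pairs contributing 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

from .connectivity import DirectedWeightedNetwork

logger = logging.getLogger(__name__)

MEASURES = ("clustering", "global_efficiency")


@dataclass(frozen=True)
class BinaryDirectedGraph:
    """Unweighted directed graph from proportional thresholding.

    ``density`` is the requested fraction of the ``n(n−1)`` possible
    directed edges; ``achieved_density`` records what was actually kept
    (smaller when the weighted network had too few positive weights).
    """

    adjacency: np.ndarray
    density: float
    achieved_density: float

    def __post_init__(self) -> None:
        A = np.asarray(self.adjacency)
        if A.ndim != 2 or A.shape[0] != A.shape[1]:
            raise ValueError("adjacency must be square")
        if not np.isin(A, (0, 1)).all():
            raise ValueError("adjacency must be binary")
        if np.any(np.diag(A) != 0):
            raise ValueError("adjacency diagonal must be zero")
        object.__setattr__(self, "adjacency", A.astype(np.int8))

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum())


@dataclass(frozen=True)
class MeasureCurve:
    """One graph measure evaluated across the density sweep."""

    measure_name: str
    delay: int
    densities: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.densities, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if d.shape != v.shape or d.ndim != 1:
            raise ValueError("densities and values must be equal-length vectors")
        if d.size >= 2 and not np.all(np.diff(d) > 0):
            raise ValueError("densities must be strictly increasing")
        object.__setattr__(self, "densities", d)
        object.__setattr__(self, "values", v)


@dataclass(frozen=True)
class AUCValue:
    """Scalar summary of a measure curve: area under the density sweep."""

    measure_name: str
    delay: int
    value: float
    subject_id: str | None = None


def threshold_by_density(
    W: DirectedWeightedNetwork | np.ndarray, density: float
) -> BinaryDirectedGraph:
    """Keep the ``round(density · n(n−1))`` largest positive weights as edges.

    Ties at the cut are broken deterministically by ascending (row, column)
    index.  If fewer positive weights exist than requested, all are kept
    and the achieved density is recorded with a warning.
    """
    if not 0 < density <= 1:
        raise ValueError(f"density must be in (0, 1], got {density}")
    weights = W.weights if isinstance(W, DirectedWeightedNetwork) else np.asarray(W, float)
    n = weights.shape[0]
    if n < 2:
        raise ValueError("need at least 2 nodes")
    m_target = int(np.rint(density * n * (n - 1)))
    rows, cols = np.nonzero(weights > 0)
    vals = weights[rows, cols]
    # sort by weight descending, then (row, col) ascending for determinism
    order = np.lexsort((cols, rows, -vals))
    m = min(m_target, vals.size)
    if vals.size < m_target:
        logger.warning(
            "requested %d edges at density %.3f but only %d positive weights exist",
            m_target,
            density,
            vals.size,
        )
    A = np.zeros((n, n), dtype=np.int8)
    keep = order[:m]
    A[rows[keep], cols[keep]] = 1
    achieved = m / (n * (n - 1))
    return BinaryDirectedGraph(adjacency=A, density=density, achieved_density=achieved)


def clustering_coefficient(G: BinaryDirectedGraph | np.ndarray) -> float:
    """Mean directed clustering coefficient (Fagiolo's generalisation).

    Per node ``i``, with ``A`` the binary adjacency:

    * triangles ``t_i = ½ [(A + Aᵀ)³]_ii`` — closed three-node patterns of
      any edge orientation through ``i``;
    * total degree ``d_i = Σ_j (A_ij + A_ji)``;
    * bilateral degree ``d_i↔ = Σ_j A_ij A_ji`` (reciprocated links);
    * ``C_i = t_i / (d_i (d_i − 1) − 2 d_i↔)`` when the denominator is
      positive, else 0.

    Returns the mean of ``C_i`` over all nodes, in [0, 1].  On networks
    with anti-symmetric support ``d_i↔`` is always 0, but reciprocal
    edges are handled for generality.
    """
    A = _adjacency(G)
    n = A.shape[0]
    if n == 0:
        return 0.0
    Asym = A + A.T
    t = np.diag(np.linalg.matrix_power(Asym, 3)) / 2.0
    d_tot = A.sum(axis=1) + A.sum(axis=0)
    d_bi = np.diag(A @ A)
    denom = d_tot * (d_tot - 1) - 2 * d_bi
    with np.errstate(divide="ignore", invalid="ignore"):
        C = np.where(denom > 0, t / np.where(denom > 0, denom, 1), 0.0)
    return float(C.mean())


def global_efficiency(G: BinaryDirectedGraph | np.ndarray) -> float:
    """Mean inverse directed shortest-path length over ordered node pairs.

    Path lengths are hop counts (unit edge cost); unreachable ordered
    pairs contribute ``1/∞ = 0``.  Returns a value in [0, 1]; the empty
    graph scores 0 and the complete directed graph scores 1.
    """
    A = _adjacency(G)
    n = A.shape[0]
    if n < 2:
        return 0.0
    dist = shortest_path(csr_matrix(A), method="D", unweighted=True, directed=True)
    with np.errstate(divide="ignore"):
        inv = 1.0 / dist
    np.fill_diagonal(inv, 0.0)
    inv[~np.isfinite(inv)] = 0.0
    return float(inv.sum() / (n * (n - 1)))


_MEASURE_FUNCS = {
    "clustering": clustering_coefficient,
    "global_efficiency": global_efficiency,
}


def density_grid(d_min: float, d_max: float, step: float) -> np.ndarray:
    """Densities ``d_min, d_min+step, …, d_max`` inclusive (fp-safe)."""
    if not 0 < d_min < d_max <= 1:
        raise ValueError("require 0 < d_min < d_max <= 1")
    if step <= 0:
        raise ValueError("step must be positive")
    n_steps = int(np.floor((d_max - d_min) / step + 1e-9))
    return d_min + step * np.arange(n_steps + 1)


def density_sweep(
    W: DirectedWeightedNetwork | np.ndarray,
    d_min: float = 0.05,
    d_max: float = 0.50,
    step: float = 0.01,
    measure: str = "global_efficiency",
    delay: int | None = None,
) -> MeasureCurve:
    """Evaluate one graph measure on thresholded graphs across densities.

    The defaults give the 46-point sweep from 5% to 50% in 1% steps.
    """
    if measure not in _MEASURE_FUNCS:
        raise ValueError(f"unknown measure {measure!r}; choose from {MEASURES}")
    densities = density_grid(d_min, d_max, step)
    func = _MEASURE_FUNCS[measure]
    values = np.array([func(threshold_by_density(W, d)) for d in densities])
    if delay is None:
        delay = W.delay if isinstance(W, DirectedWeightedNetwork) else -1
    return MeasureCurve(measure_name=measure, delay=delay, densities=densities, values=values)


def auc(curve: MeasureCurve, subject_id: str | None = None) -> AUCValue:
    """Trapezoidal integral of the measure values over density (as fraction)."""
    if curve.densities.size < 2:
        raise ValueError("AUC needs at least 2 curve points")
    value = float(np.trapezoid(curve.values, curve.densities))
    return AUCValue(
        measure_name=curve.measure_name,
        delay=curve.delay,
        value=value,
        subject_id=subject_id,
    )


def _adjacency(G: BinaryDirectedGraph | np.ndarray) -> np.ndarray:
    if isinstance(G, BinaryDirectedGraph):
        return G.adjacency.astype(float)
    A = np.asarray(G, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("adjacency must be square")
    if np.any(np.diag(A) != 0):
        raise ValueError("adjacency diagonal must be zero")
    return A
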