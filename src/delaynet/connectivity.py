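"""Delayed correlation matrices and anti-symmetric directed networks.

A delayed correlation matrix at lag ``d`` holds, in entry ``(i, j)``, the
Pearson correlation between region ``i``'s series over timepoints
``1..T-d`` and region ``j``'s series over timepoints ``1+d..T``: the row
region *leads*, the column region *follows*.  One lag step corresponds to
one repetition time (TR) of the acquisition.

Any square matrix splits uniquely into a symmetric part ``S = (C + Cᵀ)/2``
and an anti-symmetric part ``K = (C − Cᵀ)/2``.  ``S`` carries the
instantaneous (undirected) co-fluctuation; ``K`` carries the directional
excess: ``K[i, j] > 0`` means region ``i`` predicts region ``j`` at this
lag more than the reverse.  Zeroing the negative entries of ``K`` yields a
nonnegative directed weight matrix whose support is anti-symmetric — at
most one of ``(i, j)``/``(j, i)`` can carry weight.

Conventions fixed here and used by every writer:

* overlap after a shift of ``d`` is the ``T − d`` common samples
  (truncation; no padding or wrap-around);
* a zero-variance overlap segment yields correlation 0 with a logged
  warning instead of an error, so one flat region cannot abort a run;
* direction is row = source (earlier), column = target (later).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: |K + Kᵀ| above this is rejected as "not anti-symmetric".
ANTISYMMETRY_TOL = 1e-8


@dataclass(frozen=True)
class TimeSeriesMatrix:
    """One subject's parcellated signal: regions x timepoints.

    Parameters
    ----------
    region_labels:
        Ordered region names; length must equal the number of rows.
    data:
        Real matrix ``(n_regions, n_timepoints)`` with no missing values.
    tr_seconds:
        Sampling interval (repetition time) in seconds; one lag step of
        the delayed-correlation analysis equals one TR.
    """

    region_labels: tuple[str, ...]
    data: np.ndarray
    tr_seconds: float = 3.0

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        if data.ndim != 2:
            raise ValueError("time-series data must be 2-D (regions x timepoints)")
        if len(self.region_labels) != data.shape[0]:
            raise ValueError(
                f"{len(self.region_labels)} labels for {data.shape[0]} regions"
            )
        if not np.all(np.isfinite(data)):
            raise ValueError("time-series data contains non-finite values")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "region_labels", tuple(self.region_labels))
        flat = np.where(data.std(axis=1) == 0)[0]
        if flat.size:
            logger.warning(
                "zero-variance region(s): %s",
                ", ".join(self.region_labels[i] for i in flat),
            )

    @property
    def n_regions(self) -> int:
        return self.data.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[1]


@dataclass(frozen=True)
class DelayedCorrelationMatrix:
    """Pearson correlations of leader vs follower segments at one lag."""

    delay: int
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if self.delay < 0:
            raise ValueError("delay must be nonnegative")
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("correlation matrix must be square")
        object.__setattr__(self, "matrix", m)


@dataclass(frozen=True)
class DirectedWeightedNetwork:
    """Nonnegative directed weights with anti-symmetric support.

    ``weights[i, j] > 0`` encodes a directed connection i -> j (row =
    source, column = target); the diagonal is zero and at most one of a
    reciprocal pair is positive.
    """

    delay: int
    weights: np.ndarray
    region_labels: tuple[str, ...] | None = field(default=None)

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("weight matrix must be square")
        if np.any(w < 0):
            raise ValueError("weights must be nonnegative")
        if np.any(np.diag(w) != 0):
            raise ValueError("diagonal weights must be zero")
        if np.any((w > 0) & (w.T > 0)):
            raise ValueError("reciprocal positive weights violate anti-symmetric support")
        object.__setattr__(self, "weights", w)
        if self.region_labels is not None:
            object.__setattr__(self, "region_labels", tuple(self.region_labels))

    @property
    def n_regions(self) -> int:
        return self.weights.shape[0]


def delayed_correlation(ts: TimeSeriesMatrix, delay: int) -> DelayedCorrelationMatrix:
    """Correlate every region pair after shifting the follower by ``delay``.

    ``C_d[i, j]`` is the Pearson correlation of ``x_i`` over timepoints
    ``1..T-d`` with ``x_j`` over ``1+d..T``.  At ``delay = 0`` this is the
    ordinary correlation matrix (symmetric, unit diagonal).  Entries are
    clipped to ``[-1, 1]`` only to absorb floating-point rounding.

    Raises
    ------
    ValueError
        If fewer than 3 overlapping samples would remain.
    """
    if delay < 0:
        raise ValueError("delay must be nonnegative")
    T = ts.n_timepoints
    if delay > T - 3:
        raise ValueError(
            f"delay {delay} leaves fewer than 3 overlapping samples (T={T})"
        )
    lead = ts.data[:, : T - delay] if delay else ts.data
    follow = ts.data[:, delay:]
    lead_c = lead - lead.mean(axis=1, keepdims=True)
    follow_c = follow - follow.mean(axis=1, keepdims=True)
    lead_n = np.linalg.norm(lead_c, axis=1)
    follow_n = np.linalg.norm(follow_c, axis=1)
    bad_lead = lead_n == 0
    bad_follow = follow_n == 0
    if np.any(bad_lead) or np.any(bad_follow):
        logger.warning(
            "zero-variance overlap segment(s) at delay %d; correlations set to 0",
            delay,
        )
    denom = np.outer(np.where(bad_lead, 1.0, lead_n), np.where(bad_follow, 1.0, follow_n))
    C = (lead_c @ follow_c.T) / denom
    C[bad_lead, :] = 0.0
    C[:, bad_follow] = 0.0
    np.clip(C, -1.0, 1.0, out=C)
    return DelayedCorrelationMatrix(delay=delay, matrix=C)


def antisymmetric_decomposition(C: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Split a square matrix into its symmetric and anti-symmetric parts.

    Returns ``(S, K)`` with ``S = (C + Cᵀ)/2`` and ``K = (C − Cᵀ)/2``;
    this is the unique pair with ``S = Sᵀ``, ``K = −Kᵀ`` and
    ``S + K = C``.
    """
    C = np.asarray(C, dtype=float)
    if C.ndim != 2 or C.shape[0] != C.shape[1]:
        raise ValueError("input must be a square matrix")
    S = (C + C.T) / 2.0
    K = (C - C.T) / 2.0
    return S, K


def build_directed_network(
    K: np.ndarray,
    delay: int,
    region_labels: Sequence[str] | None = None,
) -> DirectedWeightedNetwork:
    """Turn an anti-symmetric matrix into nonnegative directed weights.

    Negative entries are set to zero, so exactly one of each reciprocal
    pair can carry weight and ``W − Wᵀ`` reconstructs ``K``.
    """
    K = np.asarray(K, dtype=float)
    if K.ndim != 2 or K.shape[0] != K.shape[1]:
        raise ValueError("input must be a square matrix")
    dev = np.max(np.abs(K + K.T)) if K.size else 0.0
    if dev > ANTISYMMETRY_TOL:
        raise ValueError(
            f"matrix is not anti-symmetric: max|K + K^T| = {dev:.3g} "
            f"exceeds tolerance {ANTISYMMETRY_TOL:g}"
        )
    W = np.maximum(K, 0.0)
    np.fill_diagonal(W, 0.0)
    labels = tuple(region_labels) if region_labels is not None else None
    return DirectedWeightedNetwork(delay=delay, weights=W, region_labels=labels)


def group_average_network(
    networks: Sequence[DirectedWeightedNetwork],
) -> np.ndarray:
    """Element-wise mean of individual weight matrices (representative network).

    The average of support-disjoint matrices may carry weight on both
    ``(i, j)`` and ``(j, i)``, so the result is returned as a plain matrix
    rather than a :class:`DirectedWeightedNetwork`.
    """
    if len(networks) == 0:
        raise ValueError("cannot average an empty collection of networks")
    shape = networks[0].weights.shape
    delay = networks[0].delay
    for net in networks[1:]:
        if net.weights.shape != shape:
            raise ValueError("all networks must share the same shape")
        if net.delay != delay:
            raise ValueError("all networks must share the same delay")
    return np.mean([net.weights for net in networks], axis=0)


def weight_histogram(
    matrix: np.ndarray,
    n_bins: int,
    value_range: tuple[float, float] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of the nonzero off-diagonal connectivity weights.

    Exact zeros are structural absences created by negativity-zeroing,
    not weights, and are excluded; counts therefore sum to the number of
    nonzero off-diagonal entries.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    matrix = np.asarray(matrix, dtype=float)
    mask = ~np.eye(matrix.shape[0], dtype=bool)
    values = matrix[mask]
    values = values[values != 0]
    if values.size == 0:
        edges = np.linspace(0.0, 1.0, n_bins + 1) if value_range is None else np.linspace(
            value_range[0], value_range[1], n_bins + 1
        )
        return edges, np.zeros(n_bins, dtype=int)
    counts, edges = np.histogram(values, bins=n_bins, range=value_range)
    return edges, counts


def positive_weight_iqr(matrix: np.ndarray) -> float:
    """Interquartile range of the strictly positive off-diagonal weights."""
    matrix = np.asarray(matrix, dtype=float)
    mask = ~np.eye(matrix.shape[0], dtype=bool)
    values = matrix[mask]
    values = values[values > 0]
    if values.size == 0:
        return 0.0
    q1, q3 = np.percentile(values, [25, 75])
    return float(q3 - q1)


def write_matrix(
    matrix: np.ndarray,
    labels: Sequence[str],
    path: str | Path,
    *,
    delay: int | None = None,
    tr_seconds: float | None = None,
) -> None:
    """Write a labelled matrix as TSV plus a JSON sidecar with conventions."""
    path = Path(path)
    df = pd.DataFrame(np.asarray(matrix, dtype=float), index=list(labels), columns=list(labels))
    df.to_csv(path, sep="\t", index_label="region")
    sidecar = {
        "delay": delay,
        "tr_seconds": tr_seconds,
        "direction_convention": "row = earlier/source region, column = later/target region",
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))


def read_matrix(path: str | Path) -> tuple[np.ndarray, tuple[str, ...]]:
    """Read a labelled matrix TSV written by :func:`write_matrix`."""
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    return df.to_numpy(dtype=float), tuple(str(c) for c in df.columns)
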