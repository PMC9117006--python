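"""Edge time series, cross-subject edge clustering, and eFC matrices.

The edge-centric view lifts an R-region BOLD dataset to its E = R(R-1)/2
connections: each edge's "time series" is the sequence of sliding-window
Pearson correlations between its two regions (window step fixed at 1 TR).
Edges with synchronized co-fluctuation across the whole cohort are grouped by
k-means into clusters; averaging member edges yields one time series per
cluster and per subject, and the correlations among those averages form the
subject's edge-centric functional connectivity (eFC) matrix, whose nodes are
edge clusters rather than regions.

Edge ordering is fixed as row-major over pairs (i < j), i ascending then j
ascending, 0-based internally and 1-based in written reports.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans

from .errors import ParameterError, StructuralError

logger = logging.getLogger(__name__)

__all__ = [
    "WindowSpec",
    "EdgeClustering",
    "num_edges",
    "edge_pairs",
    "edge_id",
    "edge_endpoints",
    "windowed_edge_series",
    "concatenate_edge_series",
    "cluster_edges",
    "cluster_mean_series",
    "efc_matrix",
]


def num_edges(R: int) -> int:
    """Number of unordered ROI pairs, R(R-1)/2 (6216 for 112 regions)."""
    if R < 2:
        raise ParameterError(f"need at least 2 ROIs, got {R}")
    return R * (R - 1) // 2


def edge_pairs(R: int) -> tuple[np.ndarray, np.ndarray]:
    """Arrays (i, j) of the edge endpoints in canonical edge order."""
    return np.triu_indices(R, k=1)


def edge_id(i: int, j: int, R: int) -> int:
    """Canonical edge id of ROI pair (i, j), i < j, 0-based."""
    if not (0 <= i < j < R):
        raise ParameterError(f"invalid pair ({i},{j}) for R={R}")
    # edges with first endpoint < i, plus offset within row i
    return i * (2 * R - i - 1) // 2 + (j - i - 1)


def edge_endpoints(eid: int, R: int) -> tuple[int, int]:
    """Inverse of :func:`edge_id`."""
    E = num_edges(R)
    if not (0 <= eid < E):
        raise ParameterError(f"edge id {eid} out of range for R={R}")
    i = 0
    remaining = eid
    while remaining >= R - i - 1:
        remaining -= R - i - 1
        i += 1
    return i, i + 1 + remaining


@dataclass(frozen=True)
class WindowSpec:
    """Sliding-window specification: length in TRs, step fixed at 1 TR."""

    length: int
    step: int = 1

    def n_windows(self, T: int) -> int:
        if not (2 <= self.length <= T):
            raise ParameterError(f"window length {self.length} invalid for T={T}")
        if self.step != 1:
            raise ParameterError("window step is fixed at 1 TR")
        return T - self.length + 1


def windowed_edge_series(ts: np.ndarray, spec: WindowSpec) -> np.ndarray:
    """E x N_window matrix of sliding-window edge correlations.

    Column n holds the lower-triangle Pearson correlations of the half-open
    window [n, n+length).  Computed from cumulative first and second moments,
    identical (to ~1e-12) to recomputing a full correlation matrix per window.
    Zero-variance windows yield 0 for their affected edges, with a warning.
    """
    ts = np.asarray(ts, dtype=float)
    if ts.ndim != 2:
        raise ParameterError("time series must be a T x R matrix")
    T, R = ts.shape
    w = spec.length
    n_win = spec.n_windows(T)
    iu, ju = edge_pairs(R)

    def win_sum(x: np.ndarray) -> np.ndarray:
        c = np.cumsum(x, axis=0)
        c = np.vstack([np.zeros((1, x.shape[1])), c])
        return c[w:] - c[:-w]  # (n_win, cols)

    s1 = win_sum(ts)  # sums per ROI
    s2 = win_sum(ts**2)  # sums of squares per ROI
    sxy = win_sum(ts[:, iu] * ts[:, ju])  # cross sums per edge

    mean = s1 / w
    var = s2 / w - mean**2
    var = np.maximum(var, 0.0)
    sd = np.sqrt(var)
    cov = sxy / w - mean[:, iu] * mean[:, ju]
    denom = sd[:, iu] * sd[:, ju]
    bad = denom <= 1e-14
    if bad.any():
        logger.warning(
            "%d window/edge combinations had zero variance; correlations set to 0",
            int(bad.sum()),
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.where(bad, 0.0, cov / np.where(bad, 1.0, denom))
    np.clip(corr, -1.0, 1.0, out=corr)
    return np.ascontiguousarray(corr.T)  # E x N_window


def concatenate_edge_series(
    series_list: list[np.ndarray], zscore_rows: bool = True
) -> np.ndarray:
    """Concatenate per-subject E x N_window edge series along windows.

    Subject blocks appear in the given (manifest) order.  By default each edge
    row is z-scored within its subject block first, so that between-subject
    level differences do not dominate the Euclidean geometry of the subsequent
    clustering; rows with zero variance are left centered at 0.
    """
    if not series_list:
        raise StructuralError("no edge series to concatenate")
    E = series_list[0].shape[0]
    blocks = []
    for k, ets in enumerate(series_list):
        if ets.shape[0] != E:
            raise StructuralError(
                f"subject block {k} has {ets.shape[0]} edges, expected {E}"
            )
        if zscore_rows:
            mu = ets.mean(axis=1, keepdims=True)
            sd = ets.std(axis=1, keepdims=True)
            sd = np.where(sd <= 1e-14, 1.0, sd)
            blocks.append((ets - mu) / sd)
        else:
            blocks.append(ets)
    return np.hstack(blocks)


@dataclass(frozen=True)
class EdgeClustering:
    """Partition of the E edges into clusters fitted on concatenated series.

    ``assignment`` holds 0-based cluster ids (1-based only in written
    reports); every id in ``range(n_clusters)`` is non-empty.
    """

    assignment: np.ndarray  # (E,) ints in [0, n_clusters)
    n_clusters: int
    requested_k: int
    seed: int

    def members(self, cluster: int) -> np.ndarray:
        return np.flatnonzero(self.assignment == cluster)

    def __post_init__(self):
        uniq = np.unique(self.assignment)
        if not np.array_equal(uniq, np.arange(self.n_clusters)):
            raise StructuralError("cluster ids must be exactly 0..n_clusters-1")


def cluster_edges(
    concat: np.ndarray, K: int, seed: int, n_init: int = 10
) -> EdgeClustering:
    """k-means partition of edge rows (Euclidean, k-means++, seeded restarts).

    Empty clusters, should k-means produce any, are dropped and ids compacted
    (in order of first appearance), so the realized cluster count may be < K.
    Deterministic given the seed.
    """
    E = concat.shape[0]
    if K >= E:
        raise ParameterError(f"K={K} must be smaller than the edge count E={E}")
    if K < 1:
        raise ParameterError("K must be >= 1")
    km = KMeans(n_clusters=K, n_init=n_init, random_state=seed)
    raw = km.fit_predict(concat)
    # compact labels by first appearance to make the relabeling deterministic
    order: dict[int, int] = {}
    for lab in raw:
        if lab not in order:
            order[lab] = len(order)
    assignment = np.array([order[lab] for lab in raw], dtype=int)
    realized = len(order)
    if realized < K:
        logger.warning("k-means produced %d empty clusters; K adjusted to %d",
                       K - realized, realized)
    return EdgeClustering(assignment, realized, K, seed)


def cluster_mean_series(ets: np.ndarray, clustering: EdgeClustering) -> np.ndarray:
    """K x N_window matrix; row k is the mean of the member-edge rows."""
    if ets.shape[0] != clustering.assignment.shape[0]:
        raise StructuralError(
            f"clustering covers {clustering.assignment.shape[0]} edges but the "
            f"series has {ets.shape[0]}"
        )
    K = clustering.n_clusters
    sums = np.zeros((K, ets.shape[1]))
    np.add.at(sums, clustering.assignment, ets)
    counts = np.bincount(clustering.assignment, minlength=K).astype(float)
    return sums / counts[:, None]


def efc_matrix(cluster_series: np.ndarray) -> np.ndarray:
    """K x K Pearson correlations among cluster-mean series (diagonal 1).

    Rows with zero variance get zero correlations (diagonal stays 1), with a
    warning; this is the degenerate-input policy, not an estimate.
    """
    K, n_win = cluster_series.shape
    if n_win < 3:
        raise ParameterError("need at least 3 windows to correlate cluster series")
    x = cluster_series - cluster_series.mean(axis=1, keepdims=True)
    sd = x.std(axis=1)
    zero = sd <= 1e-14
    if zero.any():
        logger.warning("%d cluster series have zero variance; correlations set to 0",
                       int(zero.sum()))
    safe_sd = np.where(zero, 1.0, sd)
    xn = x / safe_sd[:, None]
    efc = xn @ xn.T / n_win
    efc[zero, :] = 0.0
    efc[:, zero] = 0.0
    np.clip(efc, -1.0, 1.0, out=efc)
    efc = (efc + efc.T) / 2.0
    np.fill_diagonal(efc, 1.0)
    return efc
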