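"""Weighted-graph features of eFC and static FC networks.

The classifier input is one weighted local clustering coefficient (WLCC) per
node — the Onnela geometric-mean-of-triangles form, computed on weights
normalized by the largest off-diagonal magnitude so every coefficient lies in
[0, 1].  For a node i with degree k_i (neighbors with nonzero weight),

    C_i = 1 / (k_i (k_i - 1)) * sum_{j != h} (w~_ij w~_jh w~_hi)^(1/3)

with C_i = 0 when k_i < 2.  Correlation networks carry negative weights;
by default their absolute value is used (``negatives="abs"``), or they can be
zeroed (``negatives="zero"``).
"""

from __future__ import annotations

import logging

import numpy as np

from .edges import WindowSpec, edge_pairs, windowed_edge_series
from .errors import ParameterError

logger = logging.getLogger(__name__)

__all__ = ["weighted_local_clustering", "static_fc", "static_fc_wlcc"]


def weighted_local_clustering(
    W: np.ndarray, negatives: str = "abs"
) -> np.ndarray:
    """Onnela weighted local clustering coefficient per node, in [0, 1].

    The diagonal is ignored.  Weights are mapped to [0, 1] by ``|W| / max|W|``
    (off-diagonal maximum), which makes the coefficient invariant under global
    positive rescaling of W.
    """
    W = np.asarray(W, dtype=float)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise ParameterError("W must be square")
    if not np.allclose(W, W.T, atol=1e-10):
        raise ParameterError("W must be symmetric")
    if negatives not in ("abs", "zero"):
        raise ParameterError("negatives must be 'abs' or 'zero'")
    n = W.shape[0]
    A = np.abs(W.copy()) if negatives == "abs" else np.maximum(W, 0.0)
    np.fill_diagonal(A, 0.0)
    wmax = A.max()
    if wmax <= 0:
        logger.warning("no nonzero off-diagonal weights; WLCC is all-zero")
        return np.zeros(n)
    A = A / wmax
    M = np.cbrt(A)
    # (M^3)_ii sums (w~_ij w~_jh w~_hi)^{1/3} over ordered pairs j != h
    # (the j == h term vanishes because M_jj = 0)
    tri = np.einsum("ij,jh,hi->i", M, M, M)
    k = (A > 0).sum(axis=1)
    denom = k * (k - 1)
    out = np.zeros(n)
    valid = denom > 0
    out[valid] = tri[valid] / denom[valid]
    return np.clip(out, 0.0, 1.0)


def static_fc(ts: np.ndarray) -> np.ndarray:
    """Length-E vector of full-scan Pearson correlations, canonical edge order.

    Identical to the single column of :func:`windowed_edge_series` with the
    window spanning the whole scan.  Zero-variance columns yield 0 for their
    edges, with a warning.
    """
    ts = np.asarray(ts, dtype=float)
    if ts.ndim != 2:
        raise ParameterError("time series must be T x R")
    T, R = ts.shape
    x = ts - ts.mean(axis=0)
    sd = x.std(axis=0)
    zero = sd <= 1e-14
    if zero.any():
        logger.warning("%d zero-variance columns; their edges set to 0", int(zero.sum()))
    xn = x / np.where(zero, 1.0, sd)
    corr = xn.T @ xn / T
    corr[zero, :] = 0.0
    corr[:, zero] = 0.0
    iu, ju = edge_pairs(R)
    return np.clip(corr[iu, ju], -1.0, 1.0)


def static_fc_wlcc(ts: np.ndarray, negatives: str = "abs") -> np.ndarray:
    """Length-R WLCC vector of the full-scan R x R correlation network."""
    ts = np.asarray(ts, dtype=float)
    T, R = ts.shape
    vec = static_fc(ts)
    W = np.zeros((R, R))
    iu, ju = edge_pairs(R)
    W[iu, ju] = vec
    W = W + W.T
    return weighted_local_clustering(W, negatives=negatives)


def _consistency_check(ts: np.ndarray) -> bool:  # pragma: no cover - debug aid
    """static_fc equals the one-window edge series; used in tests."""
    vec = static_fc(ts)
    ets = windowed_edge_series(ts, WindowSpec(length=ts.shape[0]))
    return bool(np.allclose(vec, ets[:, 0], atol=1e-12))
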