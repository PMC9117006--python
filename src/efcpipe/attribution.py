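"""Tracing discriminative SVM weights back to edges, regions, and networks.

Each eFC feature is an edge cluster.  Over the repetitions x outer-folds
trained models (100 by default), a cluster's *occurrence rate* is the fraction
of fits in which the LASSO selected it, and its *normalized weight* is its
mean SVM weight (over the fits where selected) multiplied by that occurrence
rate.  Tracing back distributes |normalized weight| to every member edge of
the cluster ("connection-wise contribution"), sums incident-edge
contributions per region, and projects edge contributions onto canonical
networks through a fractional ROI->network affiliation table, with the mass
of a between-network edge split half-and-half between its two networks for
the per-network inter index.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .classify import TrainedFold
from .edges import EdgeClustering, edge_pairs, num_edges
from .errors import ParameterError, StructuralError

logger = logging.getLogger(__name__)

__all__ = [
    "ClusterWeightRecord",
    "NetworkContributions",
    "cluster_weights",
    "connection_contributions",
    "region_contributions",
    "network_indices",
    "top_fraction_edges",
    "load_affiliation",
]


@dataclass(frozen=True)
class ClusterWeightRecord:
    """Selection bookkeeping for one cluster under one configuration."""

    key: tuple  # (window, requested K)
    cluster: int  # 0-based cluster id
    appearances: int
    occurrence_rate: float
    mean_svm_weight: float  # signed mean over the fits where selected
    normalized_weight: float  # mean_svm_weight * occurrence_rate (signed)


@dataclass(frozen=True)
class NetworkContributions:
    """Intra-, inter-, and pairwise network contribution indices."""

    intra: np.ndarray  # (M,)
    inter: np.ndarray  # (M,)
    pairwise: np.ndarray  # (M, M) symmetric
    networks: tuple[str, ...]


def cluster_weights(
    folds: list[TrainedFold], n_fits: int | None = None
) -> list[ClusterWeightRecord]:
    """Aggregate fold records into per-(configuration, cluster) weights.

    ``n_fits`` is the occurrence-rate denominator (repetitions x outer folds);
    by default it is inferred from the fold records, which must be complete.
    """
    if not folds:
        raise StructuralError("no trained folds")
    expected = (max(f.repetition for f in folds) + 1) * (
        max(f.fold for f in folds) + 1
    )
    if len(folds) != expected:
        raise StructuralError(
            f"incomplete fold records: got {len(folds)}, expected {expected}"
        )
    if n_fits is None:
        n_fits = expected
    acc: dict[tuple, list[float]] = {}
    for f in folds:
        for local_idx, cluster in enumerate(f.selected):
            acc.setdefault((f.key, int(cluster)), []).append(
                float(f.weights[local_idx])
            )
    records = []
    for (key, cluster), ws in sorted(acc.items(), key=lambda kv: (str(kv[0][0]), kv[0][1])):
        appearances = len(ws)
        occurrence = appearances / n_fits
        mean_w = float(np.mean(ws))
        records.append(
            ClusterWeightRecord(
                key, cluster, appearances, occurrence, mean_w, mean_w * occurrence
            )
        )
    return records


def connection_contributions(
    records: list[ClusterWeightRecord],
    clusterings: dict,
    E: int,
    size_normalized: bool = False,
) -> np.ndarray:
    """Length-E edge contributions: each edge accumulates |normalized weight|
    of every selected cluster containing it, across configurations.

    ``clusterings`` maps each record's configuration key to its
    :class:`EdgeClustering`.  By default the full cluster weight goes to every
    member edge; ``size_normalized=True`` divides it by the cluster size.
    """
    contrib = np.zeros(E)
    for rec in records:
        if rec.key not in clusterings:
            raise StructuralError(f"no clustering available for configuration {rec.key}")
        clustering: EdgeClustering = clusterings[rec.key]
        if clustering.assignment.shape[0] != E:
            raise StructuralError(
                f"clustering for {rec.key} covers {clustering.assignment.shape[0]} "
                f"edges, expected {E}"
            )
        members = clustering.members(rec.cluster)
        if members.size == 0:
            raise StructuralError(
                f"cluster {rec.cluster} of configuration {rec.key} has no edges"
            )
        w = abs(rec.normalized_weight)
        if size_normalized:
            w /= members.size
        contrib[members] += w
    return contrib


def contributions_from_folds(
    folds: list[TrainedFold], E: int, size_normalized: bool = False
) -> tuple[list[ClusterWeightRecord], np.ndarray]:
    """Convenience: cluster weights + edge contributions from fold records,
    using each configuration's clustering carried on the folds."""
    records = cluster_weights(folds)
    clusterings = {}
    for f in folds:
        if f.clustering is None:
            raise StructuralError("fold records carry no clusterings (static kind?)")
        clusterings.setdefault(f.key, f.clustering)
    return records, connection_contributions(records, clusterings, E, size_normalized)


def region_contributions(edge_contrib: np.ndarray, R: int) -> np.ndarray:
    """Length-R vector: each ROI sums |contribution| over incident edges."""
    E = num_edges(R)
    edge_contrib = np.asarray(edge_contrib, dtype=float)
    if edge_contrib.shape[0] != E:
        raise StructuralError(f"expected {E} edge contributions, got {edge_contrib.shape[0]}")
    iu, ju = edge_pairs(R)
    out = np.zeros(R)
    mag = np.abs(edge_contrib)
    np.add.at(out, iu, mag)
    np.add.at(out, ju, mag)
    return out


def network_indices(
    edge_contrib: np.ndarray,
    affiliation: pd.DataFrame,
    mode: str = "soft",
) -> NetworkContributions:
    """Project edge contributions onto networks via fractional affiliation.

    For an edge (i, j) with contribution c >= 0, mass c * p_i(a) * p_j(b) goes
    to the ordered network pair (a, b).  Diagonal mass (a == b) is the intra-
    network index; off-diagonal mass enters the symmetric pairwise matrix and,
    halved, each endpoint network's inter-network index (a between-network
    edge is "divided by two for each network").

    ``mode="hard"`` first collapses each ROI to its maximum-affiliation
    network (one-hot); ``"soft"`` uses the fractions as given.
    """
    aff = np.asarray(affiliation, dtype=float)
    R, M = aff.shape
    E = num_edges(R)
    edge_contrib = np.abs(np.asarray(edge_contrib, dtype=float))
    if edge_contrib.shape[0] != E:
        raise StructuralError(
            f"affiliation has {R} ROIs ({E} edges) but got {edge_contrib.shape[0]} contributions"
        )
    if (aff < 0).any():
        raise ParameterError("affiliation proportions must be nonnegative")
    rowsums = aff.sum(axis=1)
    if np.any(np.abs(rowsums - 1.0) > 1e-8):
        logger.warning("affiliation rows renormalized to sum to 1")
    aff = aff / rowsums[:, None]
    if mode == "hard":
        hard = np.zeros_like(aff)
        hard[np.arange(R), aff.argmax(axis=1)] = 1.0
        aff = hard
    elif mode != "soft":
        raise ParameterError("mode must be 'soft' or 'hard'")

    iu, ju = edge_pairs(R)
    # P[a, b] = sum_e c_e p_i(a) p_j(b) over ordered (i, j) with i < j
    P = (aff[iu] * edge_contrib[:, None]).T @ aff[ju]
    pairwise = P + P.T
    np.fill_diagonal(pairwise, np.diag(P))
    intra = np.diag(pairwise).copy()
    off = pairwise - np.diag(np.diag(pairwise))
    inter = off.sum(axis=1) / 2.0
    names = tuple(str(c) for c in affiliation.columns) if isinstance(
        affiliation, pd.DataFrame
    ) else tuple(f"NET{m + 1}" for m in range(M))
    return NetworkContributions(intra, inter, pairwise, names)


def top_fraction_edges(
    edge_contrib: np.ndarray, fraction: float
) -> pd.DataFrame:
    """Top-|fraction| edges among those with nonzero contribution.

    Returns floor(fraction * n_nonzero) rows ranked by |contribution|
    descending, ties broken by ascending edge id.  Columns: edge_id (0-based),
    contribution.
    """
    if not (0 < fraction <= 1):
        raise ParameterError("fraction must be in (0, 1]")
    edge_contrib = np.asarray(edge_contrib, dtype=float)
    mag = np.abs(edge_contrib)
    nonzero = np.flatnonzero(mag > 0)
    if nonzero.size == 0:
        logger.warning("no nonzero contributions; top-fraction list is empty")
        return pd.DataFrame(columns=["edge_id", "contribution"])
    k = int(np.floor(fraction * nonzero.size))
    order = nonzero[np.lexsort((nonzero, -mag[nonzero]))]
    top = order[:k]
    return pd.DataFrame({"edge_id": top, "contribution": mag[top]})


def load_affiliation(path) -> pd.DataFrame:
    """Read an ROI x network affiliation TSV; rows renormalized to sum to 1."""
    aff = pd.read_csv(path, sep="\t", index_col=0)
    vals = aff.to_numpy(dtype=float)
    if (vals < 0).any():
        raise ParameterError("affiliation proportions must be nonnegative")
    sums = vals.sum(axis=1)
    if (sums <= 0).any():
        raise ParameterError("every ROI needs positive total affiliation")
    if np.any(np.abs(sums - 1.0) > 1e-8):
        logger.warning("affiliation rows renormalized on load")
    aff.iloc[:, :] = vals / sums[:, None]
    return aff
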