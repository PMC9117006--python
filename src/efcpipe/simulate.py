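"""Synthetic rs-fMRI cohorts with group differences planted only in dynamics.

The generator emulates the setting of an infant resting-state study in which
two groups (an exposed-analogue "positive" group and a control-analogue group)
cannot be told apart by static functional connectivity but differ in how
selected inter-network connections co-fluctuate over time.

Model
-----
Each subject's regional BOLD-like signal is drawn from a zero-mean Gaussian
process with a time-varying covariance

    Sigma(t) = Sigma_base + g * delta_eff * s(t) * Delta

where ``Sigma_base`` is a block covariance (``rho_within`` inside each of M
contiguous network blocks, ``rho_between`` across blocks, unit diagonal),
``s(t)`` is a smooth standardized latent signal, ``Delta`` carries +/-1 entries
only at the planted ROI pairs (symmetrized), and the gate ``g`` is 1 for group
A ("positive", label +1) and 0 for group B (label -1).  Because ``s(t)`` is
standardized to mean zero within each subject, the expected static covariance
is exactly ``Sigma_base`` in both groups: only the co-fluctuation of the
planted edges distinguishes them.

``delta_eff`` is the largest amplitude <= ``delta`` for which ``Sigma(t)``
stays positive semidefinite across all realized values of ``s(t)`` (the PSD
cone is convex and ``Sigma`` is linear in ``s``, so checking the two extremes
of ``s`` suffices); it is found by geometric shrinkage with factor 0.9 and
recorded in the ground truth.

After sampling, an AR(1) filter with coefficient ``ar_coeff`` adds temporal
autocorrelation, and each column is re-standardized.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d
from scipy.signal import lfilter

from .errors import GenerationError, ParameterError

logger = logging.getLogger(__name__)

__all__ = [
    "SimParams",
    "GroundTruth",
    "CohortTimeSeries",
    "default_planted_edges",
    "make_base_covariance",
    "generate_cohort",
    "make_toy_affiliation",
    "write_cohort",
]

#: tolerance on the smallest eigenvalue when declaring a matrix PSD
_PSD_TOL = -1e-10


@dataclass(frozen=True)
class CohortTimeSeries:
    """A cohort of per-subject T x R time-series matrices with group labels."""

    subject_ids: tuple[str, ...]
    data: np.ndarray  # (n_subjects, T, R)
    labels: np.ndarray  # (n_subjects,) values in {+1, -1}
    roi_labels: tuple[str, ...]

    @property
    def n_subjects(self) -> int:
        return self.data.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[1]

    @property
    def n_rois(self) -> int:
        return self.data.shape[2]

    def subjects(self):
        """Iterate over (subject_id, T x R matrix, label)."""
        for sid, mat, lab in zip(self.subject_ids, self.data, self.labels):
            yield sid, mat, int(lab)

    def __post_init__(self):
        if self.data.ndim != 3:
            raise ParameterError("cohort data must be (n_subjects, T, R)")
        if len(self.subject_ids) != self.data.shape[0]:
            raise ParameterError("subject_ids length does not match data")
        if len(self.labels) != self.data.shape[0]:
            raise ParameterError("labels length does not match data")
        if len(self.roi_labels) != self.data.shape[2]:
            raise ParameterError("roi_labels length does not match data")
        if not np.isfinite(self.data).all():
            raise ParameterError("cohort data contains non-finite values")


@dataclass(frozen=True)
class SimParams:
    """Parameters of the synthetic cohort; defaults are the desk-scale study.

    The desk-scale cohort (R=30 ROIs in M=4 networks, T=240 time points,
    20+20 subjects, 12 planted inter-network edges with delta=0.4 and AR(1)
    noise 0.3) is small enough for minutes-scale cross-validation while
    retaining the structure of the full-size problem (112 ROIs, 8 networks,
    ~500 volumes, 15 vs 24 subjects).
    """

    n_group_a: int = 20
    n_group_b: int = 20
    T: int = 240
    R: int = 30
    M: int = 4
    rho_within: float = 0.4
    rho_between: float = 0.1
    planted_edges: tuple[tuple[int, int], ...] | None = None
    delta: float = 0.4
    modulation_timescale: float = 30.0
    ar_coeff: float = 0.3
    seed: int = 0

    def resolved_planted_edges(self) -> tuple[tuple[int, int], ...]:
        if self.planted_edges is None:
            return default_planted_edges(self.R, self.M)
        return tuple((int(i), int(j)) for i, j in self.planted_edges)

    def validate(self) -> None:
        if self.n_group_a < 1 or self.n_group_b < 1:
            raise ParameterError("both groups need at least one subject")
        if self.T < 4:
            raise ParameterError("T too small")
        if self.R < 2 or self.M < 1 or self.M > self.R:
            raise ParameterError(f"invalid (R={self.R}, M={self.M})")
        if not (0.0 <= self.rho_between < self.rho_within < 1.0):
            raise ParameterError(
                "require 0 <= rho_between < rho_within < 1, got "
                f"rho_between={self.rho_between}, rho_within={self.rho_within}"
            )
        if self.delta < 0:
            raise ParameterError("delta must be >= 0")
        if not (0.0 <= self.ar_coeff < 1.0):
            raise ParameterError("ar_coeff must be in [0, 1)")
        if self.modulation_timescale <= 0:
            raise ParameterError("modulation_timescale must be positive")
        edges = self.resolved_planted_edges()
        seen = set()
        for i, j in edges:
            if not (0 <= i < j < self.R):
                raise ParameterError(f"planted edge ({i},{j}) invalid for R={self.R}")
            if (i, j) in seen:
                raise ParameterError(f"planted edge ({i},{j}) duplicated")
            seen.add((i, j))


@dataclass(frozen=True)
class GroundTruth:
    """What was actually planted, for downstream recovery checks."""

    planted_edges: tuple[tuple[int, int], ...]
    planted_signs: tuple[int, ...]
    group_labels: np.ndarray
    effective_delta: float
    seed: int


def network_blocks(R: int, M: int) -> list[np.ndarray]:
    """Contiguous ROI index blocks per network; the remainder joins the last."""
    size = R // M
    blocks = [np.arange(m * size, (m + 1) * size) for m in range(M - 1)]
    blocks.append(np.arange((M - 1) * size, R))
    return blocks


def default_planted_edges(R: int, M: int, n_edges: int = 12) -> tuple[tuple[int, int], ...]:
    """Deterministic ROI-disjoint inter-network pairs.

    Pairs are taken between consecutive network blocks (block 0 with block 1,
    block 2 with block 3, ...), matching members positionally, so every ROI
    participates in at most one planted edge and every pair bridges two
    networks.  Disjointness keeps the spectral norm of the planted +/-1
    perturbation matrix at 1, which minimizes the PSD-driven shrinkage of the
    modulation amplitude.
    """
    if M < 2:
        raise ParameterError("planted inter-network edges require M >= 2")
    blocks = network_blocks(R, M)
    pairs: list[tuple[int, int]] = []
    for a in range(0, M - 1, 2):
        for i, j in zip(blocks[a], blocks[a + 1]):
            pairs.append((int(i), int(j)))
    if M % 2 == 1 and M >= 3:  # odd block count: also pair last two blocks
        used = {r for p in pairs for r in p}
        for i, j in zip(blocks[M - 2], blocks[M - 1]):
            if i not in used and j not in used:
                pairs.append((int(i), int(j)))
    if len(pairs) < n_edges:
        raise ParameterError(
            f"cannot place {n_edges} disjoint inter-network edges with R={R}, M={M}"
        )
    return tuple(pairs[:n_edges])


def planted_signs(n_edges: int) -> tuple[int, ...]:
    """Alternating +1/-1 signs (half positive for even counts)."""
    return tuple(1 if k % 2 == 0 else -1 for k in range(n_edges))


def make_base_covariance(
    R: int, M: int, rho_within: float, rho_between: float
) -> np.ndarray:
    """Block covariance: unit diagonal, ``rho_within`` inside each of M
    contiguous network blocks, ``rho_between`` elsewhere.

    Raises
    ------
    ParameterError
        If the block values do not define a positive semidefinite matrix.
    """
    if R < 1 or M < 1 or M > R:
        raise ParameterError(f"invalid (R={R}, M={M})")
    if not (0.0 <= rho_between <= rho_within < 1.0) and not (
        0.0 <= rho_between < 1.0 and 0.0 <= rho_within < 1.0
    ):
        raise ParameterError(
            f"invalid correlations rho_within={rho_within}, rho_between={rho_between}"
        )
    sigma = np.full((R, R), float(rho_between))
    for block in network_blocks(R, M):
        sigma[np.ix_(block, block)] = rho_within
    np.fill_diagonal(sigma, 1.0)
    min_eig = float(np.linalg.eigvalsh(sigma)[0])
    if min_eig < _PSD_TOL:
        raise ParameterError(
            "base covariance is not positive semidefinite for "
            f"(rho_within={rho_within}, rho_between={rho_between}); "
            f"min eigenvalue {min_eig:.3e}"
        )
    return sigma


def _smooth_latent(rng: np.random.Generator, T: int, timescale: float) -> np.ndarray:
    """White noise smoothed over ``timescale`` points, standardized exactly."""
    w = rng.standard_normal(T)
    # sigma = timescale/2 gives an effective averaging span ~ timescale points
    s = gaussian_filter1d(w, sigma=timescale / 2.0, mode="reflect")
    s = s - s.mean()
    sd = s.std()
    if sd < 1e-12:  # pathological draw; fall back to unsmoothed noise
        s = w - w.mean()
        sd = s.std()
    return s / sd


def _delta_matrix(
    R: int, edges: tuple[tuple[int, int], ...], signs: tuple[int, ...]
) -> np.ndarray:
    delta = np.zeros((R, R))
    for (i, j), sg in zip(edges, signs):
        delta[i, j] = delta[j, i] = float(sg)
    return delta


def _shrink_to_psd(
    sigma_base: np.ndarray, delta_mat: np.ndarray, delta: float, s_extremes: tuple[float, float]
) -> float:
    """Largest amplitude <= delta keeping Sigma(t) PSD at both s extremes.

    Sigma is linear in s and the PSD cone is convex, so PSD at the realized
    extremes implies PSD everywhere in between.  Shrinks geometrically by 0.9.
    """
    if delta == 0 or not np.any(delta_mat):
        return 0.0
    eff = float(delta)
    floor = 1e-3 * delta
    while True:
        ok = all(
            float(np.linalg.eigvalsh(sigma_base + eff * s * delta_mat)[0]) >= _PSD_TOL
            for s in s_extremes
        )
        if ok:
            return eff
        eff *= 0.9
        if eff < floor:
            raise GenerationError(
                "planted effect unrealizable: effective delta shrank below "
                f"{floor:.3e} (requested delta={delta})"
            )


def generate_cohort(params: SimParams) -> tuple[CohortTimeSeries, GroundTruth]:
    """Draw a two-group cohort with a dynamic-only group difference.

    Deterministic given ``params.seed``; subjects are mutually independent
    (each consumes its own child seed sequence).
    """
    params.validate()
    edges = params.resolved_planted_edges()
    signs = planted_signs(len(edges))
    sigma_base = make_base_covariance(
        params.R, params.M, params.rho_within, params.rho_between
    )
    delta_mat = _delta_matrix(params.R, edges, signs)

    n = params.n_group_a + params.n_group_b
    labels = np.concatenate(
        [np.ones(params.n_group_a, dtype=int), -np.ones(params.n_group_b, dtype=int)]
    )
    child_seqs = np.random.SeedSequence(params.seed).spawn(n)
    rngs = [np.random.default_rng(sq) for sq in child_seqs]

    # pass 1: latent signals, so the PSD bound sees all realized s(t)
    latents = [
        _smooth_latent(rng, params.T, params.modulation_timescale) for rng in rngs
    ]
    gated = [s for s, lab in zip(latents, labels) if lab == 1]
    if gated and params.delta > 0:
        s_min = min(float(s.min()) for s in gated)
        s_max = max(float(s.max()) for s in gated)
        eff_delta = _shrink_to_psd(sigma_base, delta_mat, params.delta, (s_min, s_max))
    else:
        eff_delta = 0.0

    chol_base = np.linalg.cholesky(sigma_base + 1e-12 * np.eye(params.R))
    data = np.empty((n, params.T, params.R))
    for k, (rng, s, lab) in enumerate(zip(rngs, latents, labels)):
        z = rng.standard_normal((params.T, params.R))
        if lab == 1 and eff_delta > 0:
            x = np.empty_like(z)
            for t in range(params.T):
                sig_t = sigma_base + eff_delta * s[t] * delta_mat
                lt = np.linalg.cholesky(sig_t + 1e-12 * np.eye(params.R))
                x[t] = lt @ z[t]
        else:
            x = z @ chol_base.T
        if params.ar_coeff > 0:
            x = lfilter([1.0], [1.0, -params.ar_coeff], x, axis=0)
        x = x - x.mean(axis=0)
        x = x / x.std(axis=0)
        data[k] = x

    ids = tuple(f"sub-{k + 1:03d}" for k in range(n))
    rois = tuple(f"ROI{r + 1:03d}" for r in range(params.R))
    cohort = CohortTimeSeries(ids, data, labels, rois)
    truth = GroundTruth(edges, signs, labels.copy(), eff_delta, params.seed)
    if eff_delta < params.delta and params.delta > 0:
        logger.info(
            "planted amplitude shrunk for positive semidefiniteness: "
            "delta=%.3g -> effective %.3g", params.delta, eff_delta
        )
    return cohort, truth


def make_toy_affiliation(R: int, M: int, overlap_fraction: float) -> pd.DataFrame:
    """ROI x network membership proportions, with a fraction of split ROIs.

    Each row sums to 1.  Single-membership ROIs carry 1.0 in their own
    network's column; split ROIs carry 0.6 in their own network and 0.4 in the
    next one (cyclically), emulating parcels whose voxels overlap two
    canonical networks.
    """
    if M > R:
        raise ParameterError(f"more networks ({M}) than ROIs ({R})")
    if not (0.0 <= overlap_fraction <= 0.5):
        raise ParameterError("overlap_fraction must be in [0, 0.5]")
    blocks = network_blocks(R, M)
    primary = np.empty(R, dtype=int)
    for m, block in enumerate(blocks):
        primary[block] = m
    n_split = int(round(overlap_fraction * R))
    table = np.zeros((R, M))
    for r in range(R):
        m = primary[r]
        if r < n_split and M > 1:
            table[r, m] = 0.6
            table[r, (m + 1) % M] = 0.4
        else:
            table[r, m] = 1.0
    return pd.DataFrame(
        table,
        index=[f"ROI{r + 1:03d}" for r in range(R)],
        columns=[f"NET{m + 1}" for m in range(M)],
    )


def write_cohort(
    cohort: CohortTimeSeries,
    truth: GroundTruth | None,
    outdir: str | Path,
    affiliation: pd.DataFrame | None = None,
) -> Path:
    """Write per-subject TSVs, a manifest CSV, ground truth JSON, and the
    affiliation TSV under ``outdir``; returns the manifest path."""
    outdir = Path(outdir)
    (outdir / "timeseries").mkdir(parents=True, exist_ok=True)
    rows = []
    for sid, mat, lab in cohort.subjects():
        path = outdir / "timeseries" / f"{sid}.tsv"
        pd.DataFrame(mat, columns=list(cohort.roi_labels)).to_csv(
            path, sep="\t", index=False, float_format="%.17g"
        )
        rows.append({"subject_id": sid, "path": str(path.relative_to(outdir)), "group": lab})
    manifest = outdir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    if truth is not None:
        payload = {
            "planted_edges": [list(e) for e in truth.planted_edges],
            "planted_signs": list(truth.planted_signs),
            "group_labels": [int(v) for v in truth.group_labels],
            "effective_delta": truth.effective_delta,
            "seed": truth.seed,
        }
        (outdir / "ground_truth.json").write_text(json.dumps(payload, indent=2))
    if affiliation is not None:
        affiliation.to_csv(outdir / "affiliation.tsv", sep="\t", index=True)
    return manifest
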