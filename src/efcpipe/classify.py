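"""Nested cross-validated LASSO + linear-SVM classification of eFC features.

Protocol
--------
Outer stratified 10-fold CV, repeated (default 10 times, 100 outer fits in
total).  For every outer training set, an inner stratified CV picks the best
(window length, cluster count) configuration by mean inner accuracy — LASSO
feature selection followed by a soft-margin linear SVM (C = 1) inside every
inner split — with ties broken toward fewer clusters, then shorter windows.
The winning configuration is refit on the full outer training set and scored
on the held-out fold.  Accuracy, sensitivity, specificity and F1 are pooled
over the outer folds of each repetition, AUC is computed from the pooled
decision scores of each repetition, and means over repetitions are reported.

Features are built once per configuration in a *feature bank*.  Under the
default ``cluster_scope="all"`` the edge clustering is fitted on the
concatenated edge series of every subject (the protocol of the source
analyses); ``cluster_scope="train"`` refits the clustering on the outer
training subjects only and carries the edge->cluster map (a function of edges,
not subjects) over to the held-out subjects.

Label-permutation validation reruns the entire nested CV on shuffled labels;
since the feature bank is label-free it is reused across permutations.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats
from sklearn.cluster import KMeans  # noqa: F401  (re-exported path for users)
from sklearn.linear_model import lasso_path
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.svm import SVC

from .edges import (
    EdgeClustering,
    WindowSpec,
    cluster_edges,
    cluster_mean_series,
    concatenate_edge_series,
    efc_matrix,
    windowed_edge_series,
)
from .errors import ParameterError, StructuralError
from .graph import static_fc, static_fc_wlcc, weighted_local_clustering
from .simulate import CohortTimeSeries

logger = logging.getLogger(__name__)

__all__ = [
    "CVConfig",
    "full_scale_protocol",
    "TrainedFold",
    "ClassificationReport",
    "PermutationResult",
    "FeatureSet",
    "FeatureBankBuilder",
    "stratified_folds",
    "lasso_select",
    "train_linear_svm",
    "classification_metrics",
    "inner_model_selection",
    "nested_cv",
    "nested_cv_on_bank",
    "permutation_test",
]

METRIC_NAMES = ("ACC", "SEN", "SPE", "F1", "AUC")


@dataclass(frozen=True)
class CVConfig:
    """Cross-validation protocol parameters (desk-scale defaults).

    The desk-scale grids (windows 20/30/40 TRs, 8/16/32 clusters) suit the
    default synthetic cohorts (R=30, T=240); :func:`full_scale_protocol` returns
    the full-size protocol (windows 50-120 step 10, clusters 100-800 step
    100) used with 112-region, ~500-volume cohorts.
    """

    outer_folds: int = 10
    inner_folds: int = 10
    repetitions: int = 10
    window_grid: tuple[int, ...] = (20, 30, 40)
    cluster_grid: tuple[int, ...] = (8, 16, 32)
    svm_C: float = 1.0
    positive_label: int = 1
    seed: int = 0
    cluster_scope: str = "all"  # "all" | "train"
    zscore_rows: bool = True
    fisher_z: bool = False
    negatives: str = "abs"
    lasso_alphas: int = 12
    lasso_cv: int = 3
    kmeans_restarts: int = 10

    def validate(self, T: int | None = None, E: int | None = None) -> "CVConfig":
        if self.outer_folds < 2 or self.inner_folds < 2:
            raise ParameterError("outer and inner folds must be >= 2")
        if self.repetitions < 1:
            raise ParameterError("repetitions must be >= 1")
        if not self.window_grid or not self.cluster_grid:
            raise ParameterError("window and cluster grids must be non-empty")
        if self.cluster_scope not in ("all", "train"):
            raise ParameterError("cluster_scope must be 'all' or 'train'")
        cfg = self
        if T is not None:
            wg = tuple(w for w in self.window_grid if 2 <= w < T)
            if not wg:
                raise ParameterError(f"no window length in grid fits T={T}")
            if wg != self.window_grid:
                logger.warning("window grid truncated to %s for T=%d", wg, T)
                cfg = replace(cfg, window_grid=wg)
        if E is not None:
            kg = tuple(k for k in self.cluster_grid if k < E)
            if not kg:
                raise ParameterError(f"no cluster count in grid is below E={E}")
            if kg != self.cluster_grid:
                logger.warning("cluster grid truncated to %s for E=%d", kg, E)
                cfg = replace(cfg, cluster_grid=kg)
        return cfg


def full_scale_protocol(seed: int = 0) -> CVConfig:
    """The full-size protocol: windows 50-120 TRs (step 10), 100-800 clusters
    (step 100), 10x10 nested CV."""
    return CVConfig(
        window_grid=tuple(range(50, 121, 10)),
        cluster_grid=tuple(range(100, 801, 100)),
        seed=seed,
    )


@dataclass(frozen=True)
class FeatureSet:
    """Per-configuration features: one row per subject in cohort order."""

    X: np.ndarray  # (n_subjects, n_features)
    window: int | None
    requested_k: int | None
    clustering: EdgeClustering | None
    kind: str  # "eFC-WLCC" | "sFC" | "sFC-WLCC"


def _sort_key(key):
    # tie-break order for inner selection: smaller K first, then smaller w
    w, k = key
    return (k if k is not None else -1, w if w is not None else -1)


class FeatureBankBuilder:
    """Builds eFC-WLCC feature banks, caching windowed edge series per window.

    A bank maps (window, requested K) -> :class:`FeatureSet` covering every
    subject.  ``fit_idx`` restricts the subjects whose concatenated edge
    series the clustering is fitted on (outer-training subjects under
    ``cluster_scope="train"``); features are always produced for all subjects
    by applying the fitted edge->cluster map.
    """

    def __init__(self, cohort: CohortTimeSeries, config: CVConfig):
        self.cohort = cohort
        self.config = config.validate(T=cohort.n_timepoints)
        self._ets_cache: dict[int, list[np.ndarray]] = {}

    def edge_series(self, window: int) -> list[np.ndarray]:
        if window not in self._ets_cache:
            spec = WindowSpec(length=window)
            series = [
                windowed_edge_series(mat, spec) for mat in self.cohort.data
            ]
            if self.config.fisher_z:
                series = [np.arctanh(np.clip(s, -0.999999, 0.999999)) for s in series]
            self._ets_cache[window] = series
        return self._ets_cache[window]

    def build(self, fit_idx: np.ndarray | None = None) -> dict:
        cfg = self.config
        bank = {}
        for w in cfg.window_grid:
            series = self.edge_series(w)
            fit_series = (
                series if fit_idx is None else [series[i] for i in fit_idx]
            )
            concat = concatenate_edge_series(fit_series, zscore_rows=cfg.zscore_rows)
            for K in cfg.cluster_grid:
                if K >= concat.shape[0]:
                    continue
                clustering = cluster_edges(
                    concat, K, seed=cfg.seed, n_init=cfg.kmeans_restarts
                )
                X = np.stack(
                    [
                        weighted_local_clustering(
                            efc_matrix(cluster_mean_series(ets, clustering)),
                            negatives=cfg.negatives,
                        )
                        for ets in series
                    ]
                )
                bank[(w, K)] = FeatureSet(X, w, K, clustering, "eFC-WLCC")
        if not bank:
            raise ParameterError("no valid (window, K) configuration")
        return bank


def static_feature_bank(cohort: CohortTimeSeries, kind: str, negatives: str = "abs") -> dict:
    """Single-entry bank of static features (kind 'sFC' or 'sFC-WLCC')."""
    if kind == "sFC":
        X = np.stack([static_fc(mat) for mat in cohort.data])
    elif kind == "sFC-WLCC":
        X = np.stack([static_fc_wlcc(mat, negatives=negatives) for mat in cohort.data])
    else:
        raise ParameterError(f"unknown static feature kind {kind!r}")
    return {(None, None): FeatureSet(X, None, None, None, kind)}


def stratified_folds(labels: np.ndarray, n_folds: int, seed: int) -> np.ndarray:
    """Stratified fold assignment (0..n_folds-1) per subject, seeded.

    Within each class, fold sizes differ by at most one.
    """
    labels = np.asarray(labels)
    for cls in np.unique(labels):
        n_cls = int((labels == cls).sum())
        if n_cls < n_folds:
            raise ParameterError(
                f"class {cls} has only {n_cls} members for {n_folds} folds"
            )
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=int(seed))
    assignment = np.empty(len(labels), dtype=int)
    for fold, (_, test_idx) in enumerate(skf.split(np.zeros(len(labels)), labels)):
        assignment[test_idx] = fold
    return assignment


def _standardize_train(X: np.ndarray):
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    constant = sd <= 1e-12
    if constant.any():
        logger.debug("%d constant features neutralized before fitting",
                     int(constant.sum()))
    sd = np.where(constant, 1.0, sd)
    return mu, sd, constant


def lasso_select(
    X: np.ndarray,
    y: np.ndarray,
    seed: int,
    n_alphas: int = 12,
    cv: int = 3,
) -> np.ndarray:
    """Indices of features with nonzero LASSO coefficients.

    L1-penalized linear regression on the +/-1 labels; the penalty is chosen
    by internal K-fold CV over a two-decade logarithmic path below the
    smallest penalty that zeroes every coefficient.  ``X`` must already be
    column-standardized on the training data.  If the selected model is empty,
    falls back to the single feature with the largest absolute two-sample t
    statistic.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    sd = X.std(axis=0)
    usable = sd > 1e-12
    if not usable.any():
        raise ParameterError("no valid feature: all columns are constant")
    yc = y - y.mean()
    alpha_max = np.abs(X.T @ yc).max() / n
    if alpha_max <= 1e-12:
        return np.array([_t_stat_fallback(X, y, usable)])
    alphas = np.logspace(np.log10(alpha_max), np.log10(alpha_max) - 2, n_alphas)
    folds = KFold(n_splits=cv, shuffle=True, random_state=int(seed))
    mse = np.zeros(n_alphas)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for tr, va in folds.split(X):
            ytr = y[tr] - y[tr].mean()
            _, coefs, _ = lasso_path(X[tr], ytr, alphas=alphas, tol=1e-3, max_iter=1000)
            resid = X[va] @ coefs + y[tr].mean() - y[va][:, None]
            mse += (resid**2).mean(axis=0)
        best = int(np.argmin(mse))
        _, coefs, _ = lasso_path(X, yc, alphas=alphas[: best + 1], tol=1e-4,
                                 max_iter=2000)
    selected = np.flatnonzero(np.abs(coefs[:, -1]) > 1e-10)
    if selected.size == 0:
        selected = np.array([_t_stat_fallback(X, y, usable)])
    return selected


def _t_stat_fallback(X: np.ndarray, y: np.ndarray, usable: np.ndarray) -> int:
    pos = y > 0
    if pos.all() or (~pos).all():
        # single-class training data: largest-variance usable feature
        return int(np.flatnonzero(usable)[np.argmax(X.std(axis=0)[usable])])
    with np.errstate(divide="ignore", invalid="ignore"):
        t, _ = stats.ttest_ind(X[pos], X[~pos])
    t = np.where(np.isfinite(t) & usable, np.abs(t), -np.inf)
    return int(np.argmax(t))


def train_linear_svm(
    X: np.ndarray, y: np.ndarray, C: float = 1.0
) -> tuple[np.ndarray, float]:
    """Soft-margin linear SVM; returns (weights, bias) of w.x + b."""
    if len(np.unique(y)) < 2:
        raise ParameterError("SVM training requires both classes")
    clf = SVC(kernel="linear", C=C)
    clf.fit(X, y)
    return clf.coef_[0].copy(), float(clf.intercept_[0])


def classification_metrics(
    y_true: np.ndarray,
    y_pred: np.ndarray,
    scores: np.ndarray,
    positive_label: int = 1,
) -> dict:
    """ACC/SEN/SPE/F1 in percent and AUC in [0, 1].

    Sensitivity, specificity and F1 anchor on the positive (exposed-analogue)
    class; AUC is the rank statistic of the decision scores.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.size == 0:
        raise ParameterError("empty predictions")
    pos = y_true == positive_label
    if pos.all() or (~pos).all():
        raise ParameterError("AUC undefined: only one class present in y_true")
    pred_pos = y_pred == positive_label
    tp = int((pos & pred_pos).sum())
    fn = int((pos & ~pred_pos).sum())
    tn = int((~pos & ~pred_pos).sum())
    fp = int((~pos & pred_pos).sum())
    acc = (tp + tn) / y_true.size
    sen = tp / (tp + fn)
    spe = tn / (tn + fp)
    precision = tp / (tp + fp) if (tp + fp) else 0.0
    f1 = (
        2 * precision * sen / (precision + sen) if (precision + sen) > 0 else 0.0
    )
    auc = float(roc_auc_score(pos.astype(int), scores))
    return {
        "ACC": 100.0 * acc,
        "SEN": 100.0 * sen,
        "SPE": 100.0 * spe,
        "F1": 100.0 * f1,
        "AUC": auc,
    }


@dataclass(frozen=True)
class TrainedFold:
    """One outer-fold fit: chosen configuration, selected features, weights,
    and held-out predictions."""

    repetition: int
    fold: int
    key: tuple  # (window, requested K) or (None, None) for static kinds
    selected: np.ndarray  # feature (cluster) indices, 0-based
    weights: np.ndarray  # SVM weights over selected features
    bias: float
    test_idx: np.ndarray
    test_ids: tuple[str, ...]
    scores: np.ndarray
    predictions: np.ndarray
    clustering: EdgeClustering | None


@dataclass(frozen=True)
class ClassificationReport:
    """Mean and per-repetition performance of the nested CV."""

    kind: str
    per_repetition: tuple[dict, ...]
    mean: dict
    chosen_keys: tuple[tuple, ...]  # per outer fit, repetition-major order

    def summary(self) -> str:
        m = self.mean
        return (
            f"{self.kind}: ACC {m['ACC']:.2f}% SEN {m['SEN']:.2f}% "
            f"SPE {m['SPE']:.2f}% F1 {m['F1']:.2f}% AUC {m['AUC']:.4f}"
        )


@dataclass(frozen=True)
class PermutationResult:
    """Label-permutation null distribution of the nested-CV accuracy."""

    n_perm: int
    null_acc: np.ndarray
    real_acc: float
    p_value: float
    null_95th: float

    @property
    def significant(self) -> bool:
        return self.real_acc > self.null_95th


def _fit_and_score(X, y, train_idx, test_idx, config: CVConfig, seed: int):
    """Standardize on train, LASSO-select, fit SVM, score the test rows."""
    mu, sd, _ = _standardize_train(X[train_idx])
    Xtr = (X[train_idx] - mu) / sd
    Xte = (X[test_idx] - mu) / sd
    selected = lasso_select(
        Xtr, y[train_idx], seed, n_alphas=config.lasso_alphas, cv=config.lasso_cv
    )
    w, b = train_linear_svm(Xtr[:, selected], y[train_idx], C=config.svm_C)
    scores = Xte[:, selected] @ w + b
    pos, neg = config.positive_label, -config.positive_label
    preds = np.where(scores >= 0, pos, neg)
    return selected, w, b, scores, preds


def inner_model_selection(
    bank: dict, y: np.ndarray, train_idx: np.ndarray, config: CVConfig, seed: int
) -> tuple:
    """Pick the (window, K) key with the largest mean inner-CV accuracy.

    Ties break toward smaller K, then smaller window.  With a single
    configuration in the bank it is chosen directly.
    """
    keys = sorted(bank.keys(), key=_sort_key)
    if len(keys) == 1:
        return keys[0]
    y_tr = y[train_idx]
    n_inner = min(config.inner_folds, *(int((y_tr == c).sum()) for c in np.unique(y_tr)))
    if n_inner < 2:
        raise ParameterError("inner CV needs >= 2 members of each class")
    skf = StratifiedKFold(n_splits=n_inner, shuffle=True, random_state=int(seed))
    splits = list(skf.split(np.zeros(len(train_idx)), y_tr))
    best_key, best_acc = None, -np.inf
    for key in keys:
        X = bank[key].X[train_idx]
        correct = 0
        total = 0
        degenerate = False
        for s, (itr, iva) in enumerate(splits):
            try:
                _, _, _, _, preds = _fit_and_score(
                    X, y_tr, itr, iva, config, seed + 7 * s + 1
                )
            except ParameterError:
                degenerate = True
                break
            correct += int((preds == y_tr[iva]).sum())
            total += len(iva)
        if degenerate:
            continue
        acc = correct / total
        if acc > best_acc:
            best_key, best_acc = key, acc
    if best_key is None:
        raise ParameterError("all configurations degenerate in inner selection")
    return best_key


def nested_cv_on_bank(
    bank_or_builder,
    y: np.ndarray,
    config: CVConfig,
    subject_ids: tuple[str, ...] | None = None,
    kind: str = "eFC-WLCC",
) -> tuple[ClassificationReport, list[TrainedFold]]:
    """Nested CV over a prebuilt feature bank (or a builder for scope='train').

    Returns the report and the repetitions x outer_folds fold records.
    """
    y = np.asarray(y)
    n = len(y)
    if subject_ids is None:
        subject_ids = tuple(f"sub-{k + 1:03d}" for k in range(n))
    builder = bank_or_builder if isinstance(bank_or_builder, FeatureBankBuilder) else None
    static_bank = bank_or_builder if builder is None else None
    if builder is not None and config.cluster_scope == "all":
        static_bank = builder.build()
        builder = None

    seed_state = np.random.SeedSequence(config.seed).generate_state(
        config.repetitions * (config.outer_folds + 1) + 1
    ) % (2**31)
    folds_out: list[TrainedFold] = []
    per_rep: list[dict] = []
    si = 0
    for rep in range(config.repetitions):
        assignment = stratified_folds(y, config.outer_folds, int(seed_state[si]))
        si += 1
        rep_true, rep_pred, rep_scores = [], [], []
        for fold in range(config.outer_folds):
            fold_seed = int(seed_state[si])
            si += 1
            test_idx = np.flatnonzero(assignment == fold)
            train_idx = np.flatnonzero(assignment != fold)
            bank = (
                static_bank
                if static_bank is not None
                else bank_or_builder.build(fit_idx=train_idx)
            )
            key = inner_model_selection(bank, y, train_idx, config, fold_seed)
            X = bank[key].X
            selected, w, b, scores, preds = _fit_and_score(
                X, y, train_idx, test_idx, config, fold_seed
            )
            folds_out.append(
                TrainedFold(
                    rep,
                    fold,
                    key,
                    selected,
                    w,
                    b,
                    test_idx,
                    tuple(subject_ids[i] for i in test_idx),
                    scores,
                    preds,
                    bank[key].clustering,
                )
            )
            rep_true.append(y[test_idx])
            rep_pred.append(preds)
            rep_scores.append(scores)
        per_rep.append(
            classification_metrics(
                np.concatenate(rep_true),
                np.concatenate(rep_pred),
                np.concatenate(rep_scores),
                config.positive_label,
            )
        )
    mean = {m: float(np.mean([r[m] for r in per_rep])) for m in METRIC_NAMES}
    report = ClassificationReport(
        kind, tuple(per_rep), mean, tuple(f.key for f in folds_out)
    )
    return report, folds_out


def nested_cv(
    cohort: CohortTimeSeries, config: CVConfig
) -> tuple[ClassificationReport, list[TrainedFold]]:
    """End-to-end nested CV on eFC-WLCC features of a cohort."""
    builder = FeatureBankBuilder(cohort, config)
    return nested_cv_on_bank(
        builder, cohort.labels, builder.config, cohort.subject_ids
    )


def permutation_test(
    cohort_or_bank,
    y_or_config,
    config_or_nperm=None,
    n_perm: int = 100,
    seed: int | None = None,
) -> PermutationResult:
    """Label-permutation validation of the nested-CV accuracy.

    ``permutation_test(cohort, config, n_perm=...)`` builds the feature bank
    once (it does not depend on labels) and reruns the full nested CV on the
    real labels and on ``n_perm`` seeded shuffles.  The p-value is
    ``(1 + #{null >= real}) / (1 + n_perm)``, and the real accuracy is flagged
    significant when it exceeds the null 95th percentile.
    """
    if isinstance(cohort_or_bank, CohortTimeSeries):
        cohort, config = cohort_or_bank, y_or_config
        if config_or_nperm is not None:
            n_perm = int(config_or_nperm)
        builder = FeatureBankBuilder(cohort, config)
        config = builder.config
        bank = builder.build() if config.cluster_scope == "all" else builder
        y = cohort.labels
        ids = cohort.subject_ids
    else:
        bank, y, config = cohort_or_bank, np.asarray(y_or_config), config_or_nperm
        ids = None
    if n_perm < 1:
        raise ParameterError("n_perm must be >= 1")
    rng = np.random.default_rng(config.seed if seed is None else seed)

    real_report, _ = nested_cv_on_bank(bank, y, config, ids)
    real_acc = real_report.mean["ACC"]
    null_acc = np.empty(n_perm)
    for b in range(n_perm):
        y_perm = rng.permutation(y)
        rep, _ = nested_cv_on_bank(bank, y_perm, config, ids)
        null_acc[b] = rep.mean["ACC"]
    p = (1 + int((null_acc >= real_acc).sum())) / (1 + n_perm)
    return PermutationResult(
        n_perm, null_acc, real_acc, p, float(np.percentile(null_acc, 95))
    )
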