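"""Static-FC baselines: group statistics with FDR and static classifiers.

The edge-centric classifier is benchmarked against the conventional static
view: (i) mass-univariate two-sample t-tests on full-scan edge correlations
with Benjamini-Hochberg FDR control, and (ii) the same nested-CV LASSO+SVM
protocol run on static features — either the length-E static correlation
vector ("sFC") or the length-R clustering coefficients of the static network
("sFC-WLCC").  Static classification has no (window, K) grid, so inner model
selection is trivial and only the LASSO penalty is tuned internally.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .classify import (
    ClassificationReport,
    CVConfig,
    TrainedFold,
    nested_cv_on_bank,
    static_feature_bank,
)
from .errors import ParameterError
from .simulate import CohortTimeSeries

logger = logging.getLogger(__name__)

__all__ = ["GroupTestResult", "classify_static", "groupwise_ttest_fdr"]


@dataclass(frozen=True)
class GroupTestResult:
    """Per-edge two-sample t-tests with BH-FDR adjustment."""

    t: np.ndarray
    p: np.ndarray
    q: np.ndarray
    significant: np.ndarray  # boolean, q < alpha
    alpha: float

    @property
    def n_significant(self) -> int:
        return int(self.significant.sum())


def classify_static(
    cohort: CohortTimeSeries, config: CVConfig, kind: str = "sFC"
) -> tuple[ClassificationReport, list[TrainedFold]]:
    """Nested-CV LASSO+SVM on static features (kind 'sFC' or 'sFC-WLCC')."""
    bank = static_feature_bank(cohort, kind, negatives=config.negatives)
    return nested_cv_on_bank(
        bank, cohort.labels, config, cohort.subject_ids, kind=kind
    )


def groupwise_ttest_fdr(
    features: np.ndarray,
    labels: np.ndarray,
    alpha: float = 0.05,
    welch: bool = False,
) -> GroupTestResult:
    """Two-sided two-sample t-test per feature with BH step-up adjustment.

    Pooled-variance (Student) t by default; ``welch=True`` drops the
    equal-variance assumption.  Features with zero variance in both groups
    get p = 1 (with a warning) rather than an undefined statistic.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    groups = np.unique(y)
    if len(groups) != 2:
        raise ParameterError(f"need exactly two groups, got {len(groups)}")
    a = X[y == groups.max()]
    b = X[y == groups.min()]
    if len(a) < 2 or len(b) < 2:
        raise ParameterError("both groups need n >= 2")
    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = sps.ttest_ind(a, b, equal_var=not welch)
    degenerate = ~np.isfinite(p)
    if degenerate.any():
        logger.warning(
            "%d features had zero within-group variance; p set to 1",
            int(degenerate.sum()),
        )
        t = np.where(degenerate, 0.0, t)
        p = np.where(degenerate, 1.0, p)
    _, q, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return GroupTestResult(t, p, q, q < alpha, alpha)
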