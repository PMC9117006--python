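"""Nested-CV machinery: folds, LASSO selection, SVM, metrics, permutations."""

import dataclasses

import numpy as np
import pytest

from efcpipe import (
    CVConfig,
    FeatureBankBuilder,
    ParameterError,
    classification_metrics,
    generate_cohort,
    inner_model_selection,
    lasso_select,
    nested_cv_on_bank,
    permutation_test,
    static_feature_bank,
    stratified_folds,
    train_linear_svm,
)
from efcpipe.classify import FeatureSet, _fit_and_score

from conftest import tiny_cv_config, tiny_sim_params


class TestStratifiedFolds:
    def test_study_sized_fold_composition(self):
        # 15 exposed + 24 controls into 10 folds
        labels = np.array([1] * 15 + [-1] * 24)
        assignment = stratified_folds(labels, 10, seed=0)
        for fold in range(10):
            in_fold = assignment == fold
            n_pos = int((labels[in_fold] == 1).sum())
            n_neg = int((labels[in_fold] == -1).sum())
            assert n_pos in (1, 2)
            assert n_neg in (2, 3)

    def test_leave_one_out(self):
        labels = np.array([1, 1, 1, -1, -1, -1])
        assignment = stratified_folds(labels, 3, seed=1)
        assert sorted(np.bincount(assignment)) == [2, 2, 2]

    def test_deterministic(self):
        labels = np.array([1] * 8 + [-1] * 8)
        a = stratified_folds(labels, 4, seed=5)
        b = stratified_folds(labels, 4, seed=5)
        np.testing.assert_array_equal(a, b)

    def test_small_class_named_in_error(self):
        labels = np.array([1, 1, -1, -1, -1, -1])
        with pytest.raises(ParameterError, match="class 1"):
            stratified_folds(labels, 3, seed=0)


class TestLassoSelect:
    def test_planted_feature_recovered(self, rng):
        n = 40
        y = np.where(rng.random(n) < 0.5, 1.0, -1.0)
        X = rng.standard_normal((n, 51))
        X[:, 17] = y + 0.01 * rng.standard_normal(n)
        X = (X - X.mean(0)) / X.std(0)
        selected = lasso_select(X, y, seed=0)
        assert 17 in selected

    def test_null_selection_is_sparse_on_average(self):
        sizes = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            X = rng.standard_normal((40, 100))
            X = (X - X.mean(0)) / X.std(0)
            y = np.where(rng.random(40) < 0.5, 1.0, -1.0)
            sizes.append(len(lasso_select(X, y, seed=seed)))
        assert np.mean(sizes) <= 10  # <= 10% of features

    def test_all_constant_rejected(self):
        X = np.ones((20, 5))
        y = np.array([1.0, -1.0] * 10)
        with pytest.raises(ParameterError, match="no valid feature"):
            lasso_select(X, y, seed=0)

    def test_empty_model_falls_back_to_best_t(self, rng):
        # pure noise with a tiny mean shift: LASSO usually empties, fallback
        # must return exactly one feature
        X = rng.standard_normal((20, 8))
        X = (X - X.mean(0)) / X.std(0)
        y = np.array([1.0] * 10 + [-1.0] * 10)
        selected = lasso_select(X, y, seed=3)
        assert len(selected) >= 1


class TestLinearSVM:
    def test_separable_toy(self):
        X = np.array([[1.0, 0.0], [-1.0, 0.0]])
        y = np.array([1, -1])
        w, b = train_linear_svm(X, y)
        scores = X @ w + b
        assert np.sign(scores[0]) == 1 and np.sign(scores[1]) == -1

    def test_duplicated_column_equals_sqrt2_rescaling(self, rng):
        # duplicating a feature is kernel-equivalent to scaling it by sqrt(2)
        X = rng.standard_normal((30, 4))
        y = np.where(rng.random(30) < 0.5, 1, -1)
        y[0], y[1] = 1, -1
        Xd = np.hstack([X, X[:, [0]]])
        wd, bd = train_linear_svm(Xd, y)
        Xs = X.copy()
        Xs[:, 0] *= np.sqrt(2)
        ws, bs = train_linear_svm(Xs, y)
        np.testing.assert_allclose(Xd @ wd + bd, Xs @ ws + bs, atol=1e-6)

    def test_single_class_rejected(self):
        with pytest.raises(ParameterError):
            train_linear_svm(np.eye(3), np.ones(3))

    def test_label_flip_flips_decision(self, rng):
        X = rng.standard_normal((20, 6))
        y = np.array([1] * 10 + [-1] * 10)
        cfg = CVConfig()
        tr, te = np.arange(14), np.arange(14, 20)
        _, _, _, s1, p1 = _fit_and_score(X, y, tr, te, cfg, seed=0)
        _, _, _, s2, p2 = _fit_and_score(X, -y, tr, te, cfg, seed=0)
        np.testing.assert_allclose(s1, -s2, atol=1e-6)
        np.testing.assert_array_equal(p1, -p2)


class TestMetrics:
    def test_perfect_predictions(self):
        y = np.array([1, 1, -1, -1])
        m = classification_metrics(y, y, np.array([2.0, 1.0, -1.0, -2.0]))
        assert m["ACC"] == m["SEN"] == m["SPE"] == m["F1"] == 100.0
        assert m["AUC"] == 1.0

    def test_hand_computed_confusion(self):
        # TP=3, FN=1, TN=2, FP=2
        y_true = np.array([1, 1, 1, 1, -1, -1, -1, -1])
        y_pred = np.array([1, 1, 1, -1, 1, 1, -1, -1])
        scores = y_pred.astype(float)
        m = classification_metrics(y_true, y_pred, scores)
        assert m["ACC"] == pytest.approx(62.5)
        assert m["SEN"] == pytest.approx(75.0)
        assert m["SPE"] == pytest.approx(50.0)
        assert m["F1"] == pytest.approx(200.0 / 3.0, abs=1e-9)

    def test_score_sign_reversal_mirrors_auc(self, rng):
        y = np.array([1] * 5 + [-1] * 5)
        scores = rng.standard_normal(10)
        preds = np.where(scores >= 0, 1, -1)
        a = classification_metrics(y, preds, scores)["AUC"]
        b = classification_metrics(y, preds, -scores)["AUC"]
        assert a == pytest.approx(1.0 - b)

    def test_label_negation_swaps_sen_spe(self, rng):
        y = np.array([1] * 6 + [-1] * 6)
        preds = np.where(rng.random(12) < 0.5, 1, -1)
        scores = preds + 0.1 * rng.standard_normal(12)
        m1 = classification_metrics(y, preds, scores)
        m2 = classification_metrics(-y, -preds, -scores)
        assert m1["ACC"] == pytest.approx(m2["ACC"])
        assert m1["SEN"] == pytest.approx(m2["SPE"])
        assert m1["SPE"] == pytest.approx(m2["SEN"])

    def test_single_class_auc_undefined(self):
        with pytest.raises(ParameterError, match="one class"):
            classification_metrics(np.ones(4), np.ones(4), np.ones(4))


def _toy_bank(X, keys):
    return {k: FeatureSet(X, k[0], k[1], None, "eFC-WLCC") for k in keys}


class TestInnerSelection:
    def test_single_configuration_chosen_directly(self, rng):
        X = rng.standard_normal((20, 5))
        bank = _toy_bank(X, [(30, 16)])
        y = np.array([1] * 10 + [-1] * 10)
        key = inner_model_selection(bank, y, np.arange(20), CVConfig(), seed=0)
        assert key == (30, 16)

    def test_tie_broken_toward_smaller_window(self, rng):
        # identical features under two keys -> identical inner ACC -> tie
        X = rng.standard_normal((24, 6))
        X[:, 0] = np.array([1.0] * 12 + [-1.0] * 12) + 0.1 * rng.standard_normal(24)
        bank = _toy_bank(X, [(60, 8), (50, 8)])
        y = np.array([1] * 12 + [-1] * 12)
        cfg = CVConfig(inner_folds=3)
        key = inner_model_selection(bank, y, np.arange(24), cfg, seed=0)
        assert key == (50, 8)

    def test_tie_broken_toward_smaller_k_first(self, rng):
        X = rng.standard_normal((24, 6))
        bank = _toy_bank(X, [(50, 16), (60, 8)])
        y = np.array([1] * 12 + [-1] * 12)
        cfg = CVConfig(inner_folds=3)
        key = inner_model_selection(bank, y, np.arange(24), cfg, seed=0)
        assert key == (60, 8)


class TestNestedCV:
    def test_fold_bookkeeping_and_determinism(self, tiny_cohort):
        cohort, _ = tiny_cohort
        cfg = tiny_cv_config(seed=2)
        builder = FeatureBankBuilder(cohort, cfg)
        bank = builder.build()
        rep1, folds1 = nested_cv_on_bank(bank, cohort.labels, cfg, cohort.subject_ids)
        rep2, folds2 = nested_cv_on_bank(bank, cohort.labels, cfg, cohort.subject_ids)
        assert len(folds1) == cfg.repetitions * cfg.outer_folds
        assert rep1.mean == rep2.mean
        for f1, f2 in zip(folds1, folds2):
            np.testing.assert_array_equal(f1.selected, f2.selected)
            np.testing.assert_allclose(f1.scores, f2.scores)
        # every subject predicted exactly once per repetition
        for rep in range(cfg.repetitions):
            covered = np.concatenate(
                [f.test_idx for f in folds1 if f.repetition == rep]
            )
            assert sorted(covered) == list(range(cohort.n_subjects))

    def test_metrics_within_bounds(self, tiny_cohort):
        cohort, _ = tiny_cohort
        cfg = tiny_cv_config(seed=4)
        builder = FeatureBankBuilder(cohort, cfg)
        report, _ = nested_cv_on_bank(
            builder.build(), cohort.labels, cfg, cohort.subject_ids
        )
        for m in ("ACC", "SEN", "SPE", "F1"):
            assert 0.0 <= report.mean[m] <= 100.0
        assert 0.0 <= report.mean["AUC"] <= 1.0

    def test_train_scope_refits_clustering_per_fold(self):
        cohort, _ = generate_cohort(tiny_sim_params(seed=9))
        cfg = tiny_cv_config(seed=9, repetitions=1, cluster_scope="train")
        builder = FeatureBankBuilder(cohort, cfg)
        report, folds = nested_cv_on_bank(
            builder, cohort.labels, cfg, cohort.subject_ids
        )
        assert len(folds) == cfg.outer_folds
        assert all(f.clustering is not None for f in folds)


class TestPermutation:
    def test_p_value_formula_consistency(self, tiny_cohort):
        cohort, _ = tiny_cohort
        cfg = tiny_cv_config(seed=1, repetitions=1)
        bank = FeatureBankBuilder(cohort, cfg).build()
        result = permutation_test(bank, cohort.labels, cfg, n_perm=5, seed=11)
        assert len(result.null_acc) == 5
        expected_p = (1 + int((result.null_acc >= result.real_acc).sum())) / 6
        assert result.p_value == pytest.approx(expected_p)
        assert 0 < result.p_value <= 1

    def test_static_bank_identity(self, tiny_cohort):
        from efcpipe.graph import static_fc

        cohort, _ = tiny_cohort
        bank = static_feature_bank(cohort, "sFC")
        X = bank[(None, None)].X
        np.testing.assert_allclose(X[0], static_fc(cohort.data[0]), atol=1e-12)
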