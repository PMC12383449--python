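"""RBF-SVM classification workflow: sigma heuristic, split, CV, metrics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.svm import SVC

from ivimid import (
    CohortSpec,
    SVMConfig,
    classification_experiment,
    estimate_sigma,
    evaluate_classifier,
    feature_importance,
    generate_cohort,
    stratified_split,
    train_svm,
)
from ivimid import reference_stats as ref


class TestSigmaHeuristic:
    def test_single_pair_brute_force(self):
        # one pair at squared distance 4: both quantiles are 1/4
        x = np.array([[0.0, 0.0], [2.0, 0.0]])
        assert estimate_sigma(x) == pytest.approx(0.25)

    def test_scale_equivariance(self, rng):
        x = rng.normal(size=(30, 4))
        s1 = estimate_sigma(x, seed=0)
        s2 = estimate_sigma(3.0 * x, seed=0)
        assert s2 == pytest.approx(s1 / 9.0, rel=1e-9)

    def test_deterministic_given_seed(self, rng):
        x = rng.normal(size=(300, 4))
        assert estimate_sigma(x, seed=5) == estimate_sigma(x, seed=5)

    def test_identical_points_rejected(self):
        with pytest.raises(ValueError):
            estimate_sigma(np.ones((5, 2)))


class TestStratifiedSplit:
    def test_42_plus_42_at_80_percent(self):
        table = generate_cohort(CohortSpec(n_per_group=42, seed=0))
        train, test = stratified_split(table, 0.8, seed=1)
        assert (train["group"] == "ID").sum() == 34
        assert (train["group"] == "NC").sum() == 34
        assert (test["group"] == "ID").sum() == 8
        assert (test["group"] == "NC").sum() == 8

    def test_disjoint_and_exhaustive(self):
        table = generate_cohort(CohortSpec(n_per_group=15, seed=0))
        train, test = stratified_split(table, 0.7, seed=2)
        ids = set(train["subject_id"]) | set(test["subject_id"])
        assert not (set(train["subject_id"]) & set(test["subject_id"]))
        assert ids == set(table["subject_id"])

    def test_degenerate_fraction_rejected(self):
        table = generate_cohort(CohortSpec(n_per_group=5, seed=0))
        for frac in (0.0, 1.0):
            with pytest.raises(ValueError):
                stratified_split(table, frac, seed=0)

    def test_same_seed_identical_split(self):
        table = generate_cohort(CohortSpec(n_per_group=10, seed=0))
        t1, _ = stratified_split(table, 0.8, seed=7)
        t2, _ = stratified_split(table, 0.8, seed=7)
        assert t1.equals(t2)


class TestTrainSVM:
    def test_separable_data_reaches_full_cv_accuracy(self, rng):
        x = np.vstack([rng.normal(-4, 0.3, (30, 2)), rng.normal(4, 0.3, (30, 2))])
        y = np.repeat([0, 1], 30)
        _, cv_acc, _ = train_svm(x, y, SVMConfig(cv_folds=5, seed=0))
        assert max(cv_acc.values()) == pytest.approx(1.0)

    def test_permuted_labels_give_chance_cv_accuracy(self, rng):
        x = rng.normal(size=(80, 4))
        y = rng.permutation(np.repeat([0, 1], 40))
        _, cv_acc, best = train_svm(x, y, SVMConfig(cv_folds=10, seed=0))
        # binomial SD at n=80 is ~0.056
        assert abs(cv_acc[best] - 0.5) < 3 * 0.056

    def test_ties_pick_smallest_cost(self, rng):
        x = np.vstack([rng.normal(-4, 0.1, (20, 2)), rng.normal(4, 0.1, (20, 2))])
        y = np.repeat([0, 1], 20)
        _, cv_acc, best = train_svm(x, y, SVMConfig(cv_folds=5, seed=0))
        tied = [c for c, a in cv_acc.items() if a == cv_acc[best]]
        assert best == min(tied)

    def test_deterministic_given_seed(self, rng):
        x = rng.normal(size=(40, 3))
        y = np.repeat([0, 1], 20)
        _, acc1, c1 = train_svm(x, y, SVMConfig(seed=3, cv_folds=5))
        _, acc2, c2 = train_svm(x, y, SVMConfig(seed=3, cv_folds=5))
        assert acc1 == acc2 and c1 == c2


class TestEvaluate:
    def _model_with_scores(self, scores, y):
        """A stub exposing decision_function for fixed scores."""

        class Stub:
            classes_ = np.array([0, 1])

            def decision_function(self, x):
                return np.asarray(scores, dtype=float)

        return Stub()

    def test_perfect_ranking(self):
        y = np.array([1, 1, 0, 0])
        m = self._model_with_scores([0.9, 0.8, -0.2, -0.1], y)
        out = evaluate_classifier(m, np.zeros((4, 1)), y)
        assert out.auc == pytest.approx(1.0)
        assert out.accuracy == pytest.approx(1.0)

    def test_tied_scores_give_half(self):
        y = np.array([1, 1, 0, 0])
        m = self._model_with_scores([0.3, 0.3, 0.3, 0.3], y)
        assert evaluate_classifier(m, np.zeros((4, 1)), y).auc == pytest.approx(0.5)

    def test_auc_equals_mann_whitney_u(self, rng):
        """Trapezoidal AUC equals U / (n1*n2) for any score set."""
        for _ in range(5):
            y = rng.integers(0, 2, 30)
            if len(np.unique(y)) < 2:
                continue
            scores = rng.normal(size=30)
            m = self._model_with_scores(scores, y)
            auc = evaluate_classifier(m, np.zeros((30, 1)), y).auc
            u = stats.mannwhitneyu(scores[y == 1], scores[y == 0]).statistic
            assert auc == pytest.approx(u / ((y == 1).sum() * (y == 0).sum()))

    def test_auc_invariant_under_monotone_transform(self, rng):
        y = np.repeat([0, 1], 15)
        scores = rng.normal(size=30)
        m1 = self._model_with_scores(scores, y)
        m2 = self._model_with_scores(np.exp(scores * 2), y)
        a1 = evaluate_classifier(m1, np.zeros((30, 1)), y).auc
        a2 = evaluate_classifier(m2, np.zeros((30, 1)), y).auc
        assert a1 == pytest.approx(a2)

    def test_sensitivity_specificity_threshold_zero(self):
        y = np.array([1, 1, 1, 0, 0])
        m = self._model_with_scores([1.0, 0.5, -0.5, -1.0, 0.2], y)
        out = evaluate_classifier(m, np.zeros((5, 1)), y)
        assert out.sensitivity == pytest.approx(2 / 3)
        assert out.specificity == pytest.approx(1 / 2)

    def test_single_class_test_set_rejected(self):
        y = np.ones(4, dtype=int)
        m = self._model_with_scores([1, 2, 3, 4], y)
        with pytest.raises(ValueError):
            evaluate_classifier(m, np.zeros((4, 1)), y)

    def test_ci_brackets_auc(self, rng):
        y = np.repeat([0, 1], 20)
        scores = y + rng.normal(0, 0.8, 40)
        m = self._model_with_scores(scores, y)
        out = evaluate_classifier(m, np.zeros((40, 1)), y)
        assert out.auc_ci[0] <= out.auc <= out.auc_ci[1]


class TestFeatureImportance:
    def test_perfect_predictor_scores_100(self):
        y = np.repeat([0, 1], 10)
        feats = pd.DataFrame({"exact": y.astype(float)})
        out = feature_importance(feats, y)
        assert out.loc[0, "importance"] == pytest.approx(100.0)

    def test_uninformative_feature_near_50(self, rng):
        y = np.repeat([0, 1], 500)
        feats = pd.DataFrame({"noise": rng.normal(size=1000)})
        assert feature_importance(feats, y).loc[0, "importance"] < 60

    def test_ranking_invariant_under_monotone_transform(self, rng):
        y = np.repeat([0, 1], 30)
        a = y + rng.normal(0, 1.0, 60)
        b = y + rng.normal(0, 0.2, 60)
        f1 = feature_importance(pd.DataFrame({"a": a, "b": b}), y)
        f2 = feature_importance(pd.DataFrame({"a": np.exp(a), "b": b}), y)
        assert list(f1["feature"]) == list(f2["feature"])
        assert f1.loc[0, "feature"] == "b"


class TestExperiment:
    def test_full_workflow_on_default_cohort(self):
        cohort = generate_cohort(CohortSpec(seed=2))
        exp = classification_experiment(
            cohort, sorted(ref.IVIM_FEATURE_STATS), SVMConfig(seed=2)
        )
        assert 0.5 <= exp.metrics.auc <= 1.0
        assert exp.screened  # strong generating effects must survive the screen
        assert exp.best_cost in SVMConfig().cost_grid
        assert set(exp.importance["feature"]) == set(exp.screened)
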