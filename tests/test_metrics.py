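"""Metric definitions against hand arithmetic and the scikit-learn
reference implementation; SHAP attribution sanity."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import accuracy_score, f1_score, recall_score

from edasleep.metrics import (
    adjusted_accuracy,
    aggregate_folds,
    macro_scores,
    normalized_confusion,
    shap_report,
    shap_values,
)
from edasleep.model import FoldResult, LabelSpec, train_classifier

from conftest import make_feature_matrix


class TestMacroScores:
    def test_perfect_prediction(self):
        y = ["a", "b", "c"] * 5
        assert macro_scores(y, y, ("a", "b", "c")) == (1.0, 1.0, 1.0)

    def test_hand_confusion_arithmetic(self):
        y_true = ["A", "A", "B", "B"]
        y_pred = ["A", "B", "B", "B"]
        f1, rec, acc = macro_scores(y_true, y_pred, ("A", "B"))
        assert rec == pytest.approx((0.5 + 1.0) / 2)
        assert f1 == pytest.approx((2 / 3 + 0.8) / 2)
        assert acc == pytest.approx(0.75)

    def test_constant_prediction_on_balanced_truth(self):
        y_true = ["a", "b", "c", "d"] * 10
        y_pred = ["a"] * 40
        f1, rec, acc = macro_scores(y_true, y_pred, ("a", "b", "c", "d"))
        assert acc == pytest.approx(0.25)
        assert rec == pytest.approx(0.25)

    def test_agrees_with_sklearn_on_random_vectors(self):
        rng = np.random.default_rng(0)
        classes = ("w", "x", "y", "z")
        for _ in range(100):
            n = int(rng.integers(5, 60))
            y_true = rng.choice(classes, n)
            y_pred = rng.choice(classes, n)
            f1, rec, acc = macro_scores(y_true, y_pred, classes)
            assert f1 == pytest.approx(
                f1_score(y_true, y_pred, labels=list(classes), average="macro", zero_division=0)
            )
            assert rec == pytest.approx(
                recall_score(y_true, y_pred, labels=list(classes), average="macro", zero_division=0)
            )
            assert acc == pytest.approx(accuracy_score(y_true, y_pred))

    def test_joint_shuffle_invariance(self):
        rng = np.random.default_rng(1)
        y_true = rng.choice(["a", "b", "c"], 60)
        y_pred = rng.choice(["a", "b", "c"], 60)
        perm = rng.permutation(60)
        assert macro_scores(y_true, y_pred, ("a", "b", "c")) == macro_scores(
            y_true[perm], y_pred[perm], ("a", "b", "c")
        )

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            macro_scores([], [], ("a",))


class TestAdjustedAccuracy:
    def test_mild_versus_severe_confusion_counts_as_correct(self):
        assert adjusted_accuracy(["mild"], ["moderate-severe"]) == 1.0

    def test_total_miss_scores_zero(self):
        assert adjusted_accuracy(["mild", "moderate-severe"], ["non-OSA"] * 2) == 0.0

    def test_dominates_three_class_accuracy(self):
        rng = np.random.default_rng(2)
        classes = ("non-OSA", "mild", "moderate-severe")
        for _ in range(50):
            y_true = rng.choice(classes, 30)
            y_pred = rng.choice(classes, 30)
            _, _, acc3 = macro_scores(y_true, y_pred, classes)
            assert adjusted_accuracy(y_true, y_pred) >= acc3

    def test_stage_labels_rejected(self):
        with pytest.raises(ValueError):
            adjusted_accuracy(["W"], ["REM"])


class TestNormalizedConfusion:
    def test_perfect_prediction_is_identity(self):
        y = ["a", "b"] * 4
        assert np.allclose(normalized_confusion(y, y, ("a", "b")), np.eye(2))

    def test_rows_sum_to_one(self):
        rng = np.random.default_rng(3)
        y_true = rng.choice(["a", "b", "c"], 50)
        y_pred = rng.choice(["a", "b", "c"], 50)
        m = normalized_confusion(y_true, y_pred, ("a", "b", "c"))
        assert np.allclose(m.sum(axis=1), 1.0, atol=1e-12)

    def test_hand_example_rows(self):
        m = normalized_confusion(
            ["A", "A", "B", "B"], ["A", "B", "B", "B"], ("A", "B")
        )
        assert np.allclose(m, [[0.5, 0.5], [0.0, 1.0]])


class TestAggregateFolds:
    def test_fold_average_versus_pooled(self):
        f1 = FoldResult("s1", np.array(["a", "a"]), np.array(["a", "a"]), "loso")
        f2 = FoldResult("s2", np.array(["b", "b"]), np.array(["a", "a"]), "loso")
        rep_avg = aggregate_folds([f1, f2], ("a", "b"))
        rep_pool = aggregate_folds([f1, f2], ("a", "b"), fold_average=False)
        assert rep_avg.accuracy == pytest.approx(0.5)
        assert rep_pool.accuracy == pytest.approx(0.5)
        # fold averaging: fold1 macro F1 = 0.5 (class b absent -> 0), fold2 = 0
        assert rep_avg.macro_f1 == pytest.approx(0.25)
        assert rep_avg.confusion.tolist() == [[2, 0], [2, 0]]


class TestShap:
    def _informative_model(self, seed=0):
        rng = np.random.default_rng(seed)
        fm = make_feature_matrix(n_subjects=4, epochs_per_subject=50, seed=seed)
        labels = np.where(rng.random(len(fm)) < 0.5, "non-OSA", "OSA")
        # only the storm-sample fraction carries the class signal
        fm.data["storm_frac"] = np.where(
            labels == "OSA", 1.0, 0.0
        ) + 0.05 * rng.normal(size=len(fm))
        model = train_classifier(fm.features, labels, seed=seed)
        return model, fm

    def test_additivity_and_planted_importance(self):
        model, fm = self._informative_model()
        contribs = shap_values(model, fm.features)  # raises if additivity fails
        assert contribs.shape[0] == len(fm)
        ranking = shap_report(model, fm.features, top_k=20)
        assert ranking[0][0] == "storm_frac"

    def test_unused_feature_has_zero_attribution(self):
        _, fm = self._informative_model(seed=1)
        X = fm.features.copy()
        X["eda_mode"] = 0.0  # constant: the model cannot have split on it
        y = np.array(["a" if v > 0.5 else "b" for v in fm.data["storm_frac"]])
        model = train_classifier(X, y, seed=2)
        ranking = dict(shap_report(model, X, top_k=77))
        assert ranking["eda_mode"] == 0.0

    def test_schema_mismatch_rejected(self):
        model, fm = self._informative_model(seed=3)
        wrong = fm.features[list(fm.features.columns[::-1])]
        with pytest.raises(ValueError):
            shap_report(model, wrong)
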