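"""Labels, SMOTE balancing, classifier training and the two
cross-validation protocols (leakage guards included)."""

import numpy as np
import pandas as pd
import pytest

from edasleep.model import (
    EvalConfig,
    LabelSpec,
    assign_osa_class,
    loso_evaluate,
    make_labels,
    merge_stages,
    personalized_evaluate,
    smote_balance,
    train_classifier,
)

from conftest import make_feature_matrix


class TestLabels:
    def test_stage_merge_mapping(self):
        assert merge_stages(["W", "N1", "N2", "N3", "REM"]) == [
            "W",
            "light",
            "light",
            "deep",
            "REM",
        ]

    def test_merged_vocabulary_is_rejected_as_input(self):
        with pytest.raises(ValueError):
            merge_stages(["light"])

    @pytest.mark.parametrize(
        "value,expected",
        [
            (2.8, "non-OSA"),
            (10.0, "mild"),
            (24.9, "moderate-severe"),
            (5.0, "mild"),
            (15.0, "moderate-severe"),
            (0.0, "non-OSA"),
        ],
    )
    def test_osa_class_boundaries(self, value, expected):
        assert assign_osa_class(value, "AHI") == expected
        assert assign_osa_class(value, "ODI") == expected

    def test_negative_index_rejected(self):
        with pytest.raises(ValueError):
            assign_osa_class(-0.1)

    def test_epochs_inherit_subject_osa_class(self):
        fm = make_feature_matrix(n_subjects=3, ahis=[2.0, 8.0, 20.0], seed=0)
        y = make_labels(fm, LabelSpec("osa3_ahi"))
        per_subject = {
            sid: set(y[fm.subject_id == sid]) for sid in fm.subject_id.unique()
        }
        assert per_subject == {
            "S000": {"non-OSA"},
            "S001": {"mild"},
            "S002": {"moderate-severe"},
        }


class TestSmote:
    def _toy(self, sizes, seed=0):
        rng = np.random.default_rng(seed)
        n = sum(sizes)
        X = pd.DataFrame(
            {
                "a": rng.normal(size=n),
                "b": rng.normal(size=n),
                "sex": rng.integers(0, 2, n).astype(float),
            }
        )
        y = np.repeat([f"c{i}" for i in range(len(sizes))], sizes)
        return X, y

    def test_balanced_input_unchanged(self):
        X, y = self._toy([50, 50])
        Xb, yb = smote_balance(X, y, seed=1)
        assert len(Xb) == 100 and (yb == y).all()

    def test_minority_oversampled_to_majority(self):
        X, y = self._toy([100, 20])
        Xb, yb = smote_balance(X, y, seed=1)
        assert sorted(np.unique(yb, return_counts=True)[1]) == [100, 100]

    def test_synthetic_rows_lie_on_neighbour_segments(self):
        X, y = self._toy([40, 10], seed=2)
        Xb, yb = smote_balance(X, y, k_neighbors=1, seed=3)
        real = X.loc[y == "c1", ["a", "b"]].to_numpy()
        synth = Xb.loc[40 + 10 :, ["a", "b"]].to_numpy()[
            np.asarray(yb[50:]) == "c1"
        ]
        for s in synth:
            # point-to-segment distance over all same-class pairs
            dmin = np.inf
            for i in range(len(real)):
                for j in range(len(real)):
                    if i == j:
                        continue
                    u = real[j] - real[i]
                    t = np.clip(np.dot(s - real[i], u) / np.dot(u, u), 0, 1)
                    dmin = min(dmin, np.linalg.norm(s - (real[i] + t * u)))
            assert dmin < 1e-9

    def test_sex_column_is_copied_not_interpolated(self):
        X, y = self._toy([60, 15], seed=4)
        Xb, _ = smote_balance(X, y, seed=5)
        assert set(np.unique(Xb["sex"])) <= {0.0, 1.0}

    def test_tiny_class_reduces_k_with_warning(self):
        X, y = self._toy([30, 3], seed=6)
        with pytest.warns(UserWarning, match="k reduced"):
            Xb, yb = smote_balance(X, y, k_neighbors=5, seed=7)
        assert (yb == "c1").sum() == 30


class TestClassifier:
    def test_separable_problem_is_learned(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame({"a": rng.normal(size=200), "b": rng.normal(size=200)})
        y = np.where(X["a"] > 0, "pos", "neg")
        model = train_classifier(X, y, seed=0)
        assert (model.predict(X) == y).mean() > 0.99

    def test_same_seed_same_predictions(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame(rng.normal(size=(150, 4)), columns=list("abcd"))
        y = rng.choice(["x", "y", "z"], 150)
        p1 = train_classifier(X, y, seed=3).predict(X)
        p2 = train_classifier(X, y, seed=3).predict(X)
        assert (p1 == p2).all()

    def test_single_class_rejected(self):
        X = pd.DataFrame({"a": np.arange(10.0)})
        with pytest.raises(ValueError):
            train_classifier(X, np.repeat("only", 10))


FAST = EvalConfig(hyperparams={"n_estimators": 30, "max_depth": 3})


class TestCrossValidation:
    def test_loso_fold_structure_and_leakage_guard(self):
        fm = make_feature_matrix(n_subjects=3, epochs_per_subject=30, seed=1)
        folds = loso_evaluate(fm, LabelSpec("stage4"), FAST)
        assert [f.subject_id for f in folds] == ["S000", "S001", "S002"]
        for f in folds:
            assert len(f.y_true) == 30  # exactly the held-out subject's epochs

    def test_personalized_split_sizes_and_seed_stability(self):
        fm = make_feature_matrix(n_subjects=2, epochs_per_subject=100, seed=2)
        folds_a = personalized_evaluate(fm, LabelSpec("stage4"), FAST)
        folds_b = personalized_evaluate(fm, LabelSpec("stage4"), FAST)
        for f in folds_a:
            assert len(f.y_true) == 75  # 25% of 100 epochs join training
        for fa, fb in zip(folds_a, folds_b):
            assert (fa.y_true == fb.y_true).all()
            assert (fa.y_pred == fb.y_pred).all()

    def test_invalid_personal_fraction_rejected(self):
        fm = make_feature_matrix(n_subjects=2, seed=3)
        with pytest.raises(ValueError):
            personalized_evaluate(
                fm, LabelSpec("stage4"), EvalConfig(personal_frac=1.5)
            )

    def test_noise_features_score_at_chance(self):
        """Balanced 4-class truth with pure-noise features: LOSO macro F1
        stays near the 0.25 chance level."""
        from edasleep.metrics import aggregate_folds

        scores = []
        for seed in range(6):
            fm = make_feature_matrix(n_subjects=4, epochs_per_subject=40, seed=seed)
            # balanced over the four merged classes (N1 -> light, N3 -> deep)
            fm.data["stage"] = np.tile(["W", "N1", "N3", "REM"], len(fm) // 4)
            folds = loso_evaluate(fm, LabelSpec("stage4"), FAST)
            rep = aggregate_folds(folds, ("W", "light", "deep", "REM"))
            scores.append(rep.macro_f1)
        assert abs(np.mean(scores) - 0.25) < 0.1
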