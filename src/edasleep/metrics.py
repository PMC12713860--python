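"""Evaluation metrics and SHAP-based model interpretation.

Macro scores average per-class values over *all* classes of the task
vocabulary (a class absent from a fold contributes 0, the standard
macro convention under imbalance — this deliberately depresses scores
when a fold lacks a class).  The *adjusted accuracy* of the three-class
OSA task collapses mild and moderate-severe into one OSA class and
reports binary accuracy, so a mild/moderate-severe confusion counts as
correct.

Feature attribution uses TreeSHAP through XGBoost's native
``pred_contribs`` path; per-feature importance is the mean absolute
SHAP value across epochs, summed over class outputs for multiclass
models, with per-sample additivity (contributions + base value = model
margin) verified internally.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import xgboost as xgb

from .model import FoldResult, StageClassifier

__all__ = [
    "EvalReport",
    "confusion_counts",
    "macro_scores",
    "adjusted_accuracy",
    "normalized_confusion",
    "aggregate_folds",
    "shap_values",
    "shap_report",
]


@dataclass
class EvalReport:
    task: str
    mode: str
    classes: tuple[str, ...]
    per_class_f1: dict[str, float]
    macro_f1: float
    macro_recall: float
    accuracy: float
    adjusted_accuracy: float | None
    confusion: np.ndarray
    per_fold: pd.DataFrame
    shap_rank: list[tuple[str, float]] | None = None

    def to_dict(self) -> dict:
        d = {
            "task": self.task,
            "mode": self.mode,
            "classes": list(self.classes),
            "per_class_f1": self.per_class_f1,
            "macro_f1": self.macro_f1,
            "macro_recall": self.macro_recall,
            "accuracy": self.accuracy,
            "adjusted_accuracy": self.adjusted_accuracy,
            "confusion": self.confusion.tolist(),
            "per_fold": self.per_fold.to_dict(orient="records"),
        }
        if self.shap_rank is not None:
            d["shap_rank"] = [[n, v] for n, v in self.shap_rank]
        return d


def confusion_counts(y_true, y_pred, classes) -> np.ndarray:
    """K x K confusion counts; rows = true class, columns = predicted."""
    classes = list(classes)
    index = {c: i for i, c in enumerate(classes)}
    m = np.zeros((len(classes), len(classes)), dtype=int)
    for t, p in zip(y_true, y_pred, strict=True):
        m[index[t], index[p]] += 1
    return m


def macro_scores(y_true, y_pred, classes) -> tuple[float, float, float]:
    """(macro F1, macro recall, accuracy) with the 0/0 -> 0 convention.

    Averages run over every class in ``classes`` whether or not it
    occurs in the fold.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.size == 0:
        raise ValueError("empty label vectors")
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    extra = (set(y_true) | set(y_pred)) - set(classes)
    if extra:
        raise ValueError(f"labels outside the class vocabulary: {sorted(extra)}")
    m = confusion_counts(y_true, y_pred, classes)
    tp = np.diag(m).astype(float)
    support = m.sum(axis=1).astype(float)
    predicted = m.sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        recall = np.where(support > 0, tp / support, 0.0)
        precision = np.where(predicted > 0, tp / predicted, 0.0)
        denom = precision + recall
        f1 = np.where(denom > 0, 2 * precision * recall / denom, 0.0)
    accuracy = float(tp.sum() / m.sum())
    return float(f1.mean()), float(recall.mean()), accuracy


def adjusted_accuracy(y_true, y_pred) -> float:
    """Binary accuracy after collapsing mild and moderate-severe OSA."""
    allowed = {"non-OSA", "mild", "moderate-severe"}
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.size == 0:
        raise ValueError("empty label vectors")
    if not (set(y_true) | set(y_pred)) <= allowed:
        raise ValueError("adjusted accuracy is defined for 3-class OSA labels only")
    collapse = lambda v: np.where(v == "non-OSA", "non-OSA", "OSA")  # noqa: E731
    return float(np.mean(collapse(y_true) == collapse(y_pred)))


def normalized_confusion(y_true, y_pred, classes) -> np.ndarray:
    """Row-normalised confusion matrix (rows sum to 1; zero-support rows
    are all-zero)."""
    m = confusion_counts(y_true, y_pred, classes).astype(float)
    sums = m.sum(axis=1, keepdims=True)
    return np.divide(m, sums, out=np.zeros_like(m), where=sums > 0)


def aggregate_folds(
    folds: list[FoldResult],
    classes,
    task: str = "",
    fold_average: bool = True,
) -> EvalReport:
    """Combine per-subject fold results into one report.

    By default macro scores are computed per fold and averaged over
    folds; ``fold_average=False`` pools all epochs before scoring.  The
    confusion matrix always pools epochs.  Adjusted accuracy is filled
    in for the three-class OSA vocabulary.
    """
    if not folds:
        raise ValueError("no folds to aggregate")
    rows = []
    for f in folds:
        mf1, mrec, acc = macro_scores(f.y_true, f.y_pred, classes)
        row = {
            "subject_id": f.subject_id,
            "macro_f1": mf1,
            "macro_recall": mrec,
            "accuracy": acc,
        }
        if set(classes) == {"non-OSA", "mild", "moderate-severe"}:
            row["adjusted_accuracy"] = adjusted_accuracy(f.y_true, f.y_pred)
        rows.append(row)
    per_fold = pd.DataFrame(rows)
    y_true = np.concatenate([f.y_true for f in folds])
    y_pred = np.concatenate([f.y_pred for f in folds])
    if fold_average:
        macro_f1 = float(per_fold["macro_f1"].mean())
        macro_recall = float(per_fold["macro_recall"].mean())
        accuracy = float(per_fold["accuracy"].mean())
        adj = (
            float(per_fold["adjusted_accuracy"].mean())
            if "adjusted_accuracy" in per_fold
            else None
        )
    else:
        macro_f1, macro_recall, accuracy = macro_scores(y_true, y_pred, classes)
        adj = (
            adjusted_accuracy(y_true, y_pred)
            if set(classes) == {"non-OSA", "mild", "moderate-severe"}
            else None
        )
    m = confusion_counts(y_true, y_pred, classes)
    tp = np.diag(m).astype(float)
    support = m.sum(axis=1).astype(float)
    predicted = m.sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        rec = np.where(support > 0, tp / support, 0.0)
        prec = np.where(predicted > 0, tp / predicted, 0.0)
        f1 = np.where(prec + rec > 0, 2 * prec * rec / (prec + rec), 0.0)
    per_class_f1 = {c: float(v) for c, v in zip(classes, f1)}
    return EvalReport(
        task=task,
        mode=folds[0].mode,
        classes=tuple(classes),
        per_class_f1=per_class_f1,
        macro_f1=macro_f1,
        macro_recall=macro_recall,
        accuracy=accuracy,
        adjusted_accuracy=adj,
        confusion=m,
        per_fold=per_fold,
    )


# --- SHAP ------------------------------------------------------------------


def shap_values(model: StageClassifier, X: pd.DataFrame) -> np.ndarray:
    """Exact TreeSHAP contributions for every sample.

    Returns an array of shape (n, n_classes, n_features + 1) — the last
    slot is the base value — or (n, n_features + 1) for binary models.
    Additivity against the booster's margin output is asserted.
    """
    if tuple(X.columns) != model.feature_names:
        raise ValueError("feature schema mismatch with the trained model")
    dm = xgb.DMatrix(X.to_numpy(dtype=float))
    booster = model.booster.get_booster()
    contribs = booster.predict(dm, pred_contribs=True)
    margin = booster.predict(dm, output_margin=True)
    total = contribs.sum(axis=-1)
    if not np.allclose(total, margin, atol=1e-3):
        raise AssertionError("SHAP additivity check failed")
    return contribs


def shap_report(
    model: StageClassifier, X: pd.DataFrame, top_k: int = 20
) -> list[tuple[str, float]]:
    """Top-k features by mean |SHAP| across epochs (summed over class
    outputs for multiclass models), descending."""
    contribs = shap_values(model, X)
    vals = contribs[..., :-1]  # drop the base-value slot
    if vals.ndim == 3:
        importance = np.abs(vals).mean(axis=0).sum(axis=0)
    else:
        importance = np.abs(vals).mean(axis=0)
    order = np.argsort(-importance)[:top_k]
    return [(model.feature_names[i], float(importance[i])) for i in order]
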