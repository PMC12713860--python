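"""Label construction, class balancing, and cross-validated classification.

Tasks
-----
* ``stage5`` — the five scored stages W, N1, N2, N3, REM;
* ``stage4`` — N1 and N2 merged into *light* sleep and N3 relabelled
  *deep* sleep (W, light, deep, REM);
* ``osa3_ahi`` / ``osa3_odi`` — per-subject severity from the index
  value: non-OSA (< 5), mild (5-15), moderate-severe (>= 15), inherited
  by every epoch of the subject;
* ``osa2_ahi`` / ``osa2_odi`` — the same collapsed to OSA vs non-OSA.

Validation
----------
Leave-one-subject-out (LOSO): each subject in turn is the test fold and
all remaining subjects the training set.  *Personalized* validation
additionally moves a seeded random 25% of the left-out subject's epochs
into the training set before balancing, testing on the remaining 75%.
Within every fold, normalisation, feature reduction, SMOTE balancing
and the classifier are fitted on the fold's training portion only.

Class balancing uses SMOTE: synthetic minority-class rows are convex
combinations of a seed row and one of its k nearest same-class
neighbours in numeric feature space; the categorical sex column is
copied from the seed row rather than interpolated.  The classifier is a
gradient-boosted tree ensemble (XGBoost).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xgboost as xgb
from sklearn.neighbors import NearestNeighbors

from .features import CATEGORICAL_COLUMNS, FeatureMatrix, FeatureNormalizer
from .reduce import reduce_features

__all__ = [
    "LabelSpec",
    "FoldResult",
    "StageClassifier",
    "merge_stages",
    "assign_osa_class",
    "make_labels",
    "smote_balance",
    "train_classifier",
    "loso_evaluate",
    "personalized_evaluate",
]

STAGE5 = ("W", "N1", "N2", "N3", "REM")
STAGE4 = ("W", "light", "deep", "REM")
OSA3 = ("non-OSA", "mild", "moderate-severe")
OSA2 = ("non-OSA", "OSA")

_TASK_CLASSES = {
    "stage5": STAGE5,
    "stage4": STAGE4,
    "osa3_ahi": OSA3,
    "osa3_odi": OSA3,
    "osa2_ahi": OSA2,
    "osa2_odi": OSA2,
}

_MERGE = {"W": "W", "N1": "light", "N2": "light", "N3": "deep", "REM": "REM"}


@dataclass(frozen=True)
class LabelSpec:
    task: str

    def __post_init__(self) -> None:
        if self.task not in _TASK_CLASSES:
            raise ValueError(f"unknown task {self.task!r}")

    @property
    def class_names(self) -> tuple[str, ...]:
        return _TASK_CLASSES[self.task]


@dataclass
class FoldResult:
    subject_id: str
    y_true: np.ndarray
    y_pred: np.ndarray
    mode: str  # loso | personalized


def merge_stages(labels) -> list[str]:
    """Map 5-stage codes to the 4-stage vocabulary (W, light, deep, REM)."""
    out = []
    for s in labels:
        if s not in _MERGE:
            raise ValueError(f"unknown 5-stage code {s!r}")
        out.append(_MERGE[s])
    return out


def assign_osa_class(index_value: float, index_kind: str = "AHI") -> str:
    """Severity class from an AHI or ODI value (events/hour)."""
    if index_kind not in ("AHI", "ODI"):
        raise ValueError("index_kind must be 'AHI' or 'ODI'")
    if index_value < 0:
        raise ValueError(f"{index_kind} must be non-negative")
    if index_value < 5:
        return "non-OSA"
    if index_value < 15:
        return "mild"
    return "moderate-severe"


def make_labels(fm: FeatureMatrix, spec: LabelSpec) -> np.ndarray:
    """Per-epoch label vector for the requested task."""
    if spec.task == "stage5":
        return fm.stage.to_numpy()
    if spec.task == "stage4":
        return np.array(merge_stages(fm.stage))
    kind = "AHI" if spec.task.endswith("ahi") else "ODI"
    idx = fm.data["ahi" if kind == "AHI" else "odi"].to_numpy(dtype=float)
    three = np.array([assign_osa_class(v, kind) for v in idx])
    if spec.task.startswith("osa2"):
        return np.where(three == "non-OSA", "non-OSA", "OSA")
    return three


# --- SMOTE -----------------------------------------------------------------


def smote_balance(
    X: pd.DataFrame,
    y: np.ndarray,
    k_neighbors: int = 5,
    seed: int = 0,
    categorical: tuple[str, ...] = CATEGORICAL_COLUMNS,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Oversample minority classes to the majority count.

    Each synthetic row is ``x + u * (neighbour - x)`` with ``u`` drawn
    uniformly from [0, 1] and the neighbour one of the seed row's
    ``k_neighbors`` nearest same-class rows in numeric feature space;
    categorical columns are copied from the seed row.  Classes smaller
    than ``k_neighbors + 1`` fall back to a reduced k with a warning.
    Already-balanced input is returned unchanged.
    """
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    n_max = int(counts.max())
    if np.all(counts == n_max):
        return X.reset_index(drop=True), y.copy()
    rng = np.random.default_rng(seed)
    num_cols = [c for c in X.columns if c not in categorical]
    cat_cols = [c for c in X.columns if c in categorical]
    parts_X, parts_y = [X.reset_index(drop=True)], [y]
    for cls, n in zip(classes, counts):
        need = n_max - int(n)
        if need == 0:
            continue
        sub = X.loc[y == cls].reset_index(drop=True)
        k = min(k_neighbors, len(sub) - 1)
        if k < k_neighbors:
            warnings.warn(
                f"class {cls!r} has only {len(sub)} rows; k reduced to {max(k,0)}",
                stacklevel=2,
            )
        xnum = sub[num_cols].to_numpy(dtype=float)
        if k < 1:  # a singleton class can only be duplicated
            picks = rng.integers(0, len(sub), need)
            synth = sub.iloc[picks].reset_index(drop=True)
        else:
            nn = NearestNeighbors(n_neighbors=k + 1).fit(xnum)
            _, idx = nn.kneighbors(xnum)
            seeds = rng.integers(0, len(sub), need)
            nbrs = idx[seeds, rng.integers(1, k + 1, need)]
            u = rng.uniform(0.0, 1.0, (need, 1))
            new_num = xnum[seeds] + u * (xnum[nbrs] - xnum[seeds])
            synth = pd.DataFrame(new_num, columns=num_cols)
            for c in cat_cols:
                synth[c] = sub[c].to_numpy()[seeds]
            synth = synth[list(X.columns)]
        parts_X.append(synth)
        parts_y.append(np.full(need, cls, dtype=y.dtype))
    Xb = pd.concat(parts_X, ignore_index=True)
    yb = np.concatenate(parts_y)
    return Xb, yb


# --- classifier ------------------------------------------------------------


DEFAULT_HYPERPARAMS = dict(
    n_estimators=300,
    max_depth=6,
    learning_rate=0.1,
    tree_method="hist",
    n_jobs=1,
)


@dataclass
class StageClassifier:
    """A fitted gradient-boosted tree ensemble plus its label encoding."""

    booster: xgb.XGBClassifier
    classes: tuple[str, ...]
    feature_names: tuple[str, ...]
    hyperparams: dict = field(default_factory=dict)

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        if tuple(X.columns) != self.feature_names:
            raise ValueError("feature schema mismatch with the trained model")
        enc = self.booster.predict(X.to_numpy(dtype=float))
        return np.array([self.classes[i] for i in enc])


def train_classifier(
    X: pd.DataFrame,
    y: np.ndarray,
    hyperparams: dict | None = None,
    seed: int = 0,
) -> StageClassifier:
    """Train an XGBoost classifier; deterministic for a fixed seed."""
    y = np.asarray(y)
    classes = tuple(sorted(np.unique(y).tolist()))
    if len(classes) < 2:
        raise ValueError("training set contains a single class")
    hp = dict(DEFAULT_HYPERPARAMS)
    if hyperparams:
        hp.update(hyperparams)
    enc = np.array([classes.index(v) for v in y])
    clf = xgb.XGBClassifier(random_state=seed, **hp)
    clf.fit(X.to_numpy(dtype=float), enc)
    return StageClassifier(
        booster=clf,
        classes=classes,
        feature_names=tuple(X.columns),
        hyperparams=hp,
    )


# --- cross-validation ------------------------------------------------------


@dataclass(frozen=True)
class EvalConfig:
    r_th: float = 0.8
    reduce_fold_wise: bool = True
    apply_reduction: bool = True
    smote_k: int = 5
    hyperparams: dict | None = None
    personal_frac: float = 0.25
    seed: int = 0


def _fit_fold(
    train: FeatureMatrix,
    test: FeatureMatrix,
    spec: LabelSpec,
    cfg: EvalConfig,
    columns: list[str] | None,
    fold_seed: int,
) -> tuple[np.ndarray, np.ndarray]:
    train_n, test_n, _ = _normalize_pair(train, test)
    if columns is None:
        columns = list(train_n.features.columns)
    Xtr = train_n.data[columns]
    Xte = test_n.data[columns]
    ytr = make_labels(train_n, spec)
    yte = make_labels(test_n, spec)
    Xb, yb = smote_balance(Xtr, ytr, k_neighbors=cfg.smote_k, seed=fold_seed)
    model = train_classifier(Xb, yb, cfg.hyperparams, seed=fold_seed)
    return yte, model.predict(Xte)


def _normalize_pair(train: FeatureMatrix, test: FeatureMatrix):
    norm = FeatureNormalizer().fit(train)
    return norm.transform(train), norm.transform(test), norm


def _fold_columns(train: FeatureMatrix, cfg: EvalConfig) -> list[str] | None:
    if not cfg.apply_reduction:
        return None
    cols, _ = reduce_features(train, r_th=cfg.r_th)
    return cols


def loso_evaluate(
    cohort: FeatureMatrix, spec: LabelSpec, cfg: EvalConfig | None = None
) -> list[FoldResult]:
    """Leave-one-subject-out evaluation.

    One fold per subject; all fitting (normalisation, reduction, SMOTE,
    classifier) happens inside the fold's training portion.  With
    ``cfg.reduce_fold_wise`` False the reduction is fitted once on the
    whole cohort, matching the original single-fit protocol.
    """
    cfg = cfg or EvalConfig()
    subjects = list(dict.fromkeys(cohort.subject_id))
    if len(subjects) < 2:
        raise ValueError("LOSO needs at least 2 subjects")
    pooled_cols = (
        None
        if cfg.reduce_fold_wise or not cfg.apply_reduction
        else reduce_features(cohort, r_th=cfg.r_th)[0]
    )
    results = []
    for i, sid in enumerate(subjects):
        test = cohort.subset(cohort.subject_id == sid)
        if len(test) == 0:
            warnings.warn(f"subject {sid} has no epochs; skipped", stacklevel=2)
            continue
        train = cohort.subset(cohort.subject_id != sid)
        cols = _fold_columns(train, cfg) if pooled_cols is None and cfg.apply_reduction else pooled_cols
        yte, ypred = _fit_fold(train, test, spec, cfg, cols, cfg.seed + i)
        results.append(FoldResult(sid, yte, ypred, mode="loso"))
    return results


def personalized_evaluate(
    cohort: FeatureMatrix,
    spec: LabelSpec,
    cfg: EvalConfig | None = None,
) -> list[FoldResult]:
    """LOSO plus a seeded random 25% of the left-out subject's epochs in
    the training set (added before SMOTE); the remaining 75% is tested."""
    cfg = cfg or EvalConfig()
    if not (0.0 < cfg.personal_frac < 1.0):
        raise ValueError("personal_frac must lie in (0, 1)")
    subjects = list(dict.fromkeys(cohort.subject_id))
    if len(subjects) < 2:
        raise ValueError("personalized evaluation needs at least 2 subjects")
    results = []
    for i, sid in enumerate(subjects):
        own = cohort.subset(cohort.subject_id == sid)
        if len(own) < 8:
            warnings.warn(f"subject {sid} has < 8 epochs; skipped", stacklevel=2)
            continue
        rng = np.random.default_rng(cfg.seed + i)
        n_personal = int(round(cfg.personal_frac * len(own)))
        picks = rng.choice(len(own), size=n_personal, replace=False)
        mask = np.zeros(len(own), dtype=bool)
        mask[picks] = True
        others = cohort.subset(cohort.subject_id != sid)
        train = FeatureMatrix.concat([others, own.subset(mask)])
        test = own.subset(~mask)
        cols = _fold_columns(train, cfg)
        yte, ypred = _fit_fold(train, test, spec, cfg, cols, cfg.seed + i)
        results.append(FoldResult(sid, yte, ypred, mode="personalized"))
    return results
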