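"""Greedy correlation-based feature elimination.

Highly correlated features are redundant for tree ensembles and blur
importance attribution, so the feature set is pruned with a single
deterministic greedy scan over the Pearson correlation matrix: anchors
are visited in ascending index order, skipping anchors that were
already eliminated; each surviving anchor i eliminates every later
feature j with |r_ij| above the threshold (default r_th = 0.8).

By default the absolute correlation is thresholded — an anticorrelated
duplicate is just as redundant as a correlated one — with
``signed=True`` available for the literal positive-correlation
reading.  The categorical sex column never enters the scan (it is not a
numeric column) and is always retained.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .features import CATEGORICAL_COLUMNS, FEATURE_COLUMNS, FeatureMatrix

__all__ = ["ReductionResult", "pearson_matrix", "greedy_reduce", "reduce_features"]


@dataclass(frozen=True)
class ReductionResult:
    retained: tuple[int, ...]
    eliminated: tuple[tuple[int, int, float], ...]  # (dropped, anchor, r)
    r_th: float

    @property
    def n_retained(self) -> int:
        return len(self.retained)


def pearson_matrix(values: np.ndarray | FeatureMatrix) -> np.ndarray:
    """Pairwise Pearson correlations between columns.

    Zero-variance columns get correlation 0 with everything (and 1 with
    themselves), with a warning — they carry no pairwise information.
    """
    if isinstance(values, FeatureMatrix):
        values = values.data[values.numeric_columns].to_numpy(dtype=float)
    x = np.asarray(values, dtype=float)
    if x.ndim != 2 or x.shape[0] < 3:
        raise ValueError("need a 2-D array with at least 3 rows")
    sd = x.std(axis=0)
    constant = sd <= 1e-12
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} zero-variance column(s); their correlations "
            "are reported as 0",
            stacklevel=2,
        )
    xs = (x - x.mean(axis=0)) / np.where(constant, 1.0, sd)
    xs[:, constant] = 0.0
    r = xs.T @ xs / x.shape[0]
    np.fill_diagonal(r, 1.0)
    return np.clip(r, -1.0, 1.0)


def greedy_reduce(
    corr: np.ndarray, r_th: float = 0.8, signed: bool = False
) -> ReductionResult:
    """The greedy elimination scan (see module docstring).

    Deterministic: anchors in ascending index order; anchor i (if not
    itself eliminated) drops every j > i with |r_ij| > r_th (or
    r_ij > r_th when ``signed``) not yet dropped.
    """
    corr = np.asarray(corr, dtype=float)
    if corr.ndim != 2 or corr.shape[0] != corr.shape[1]:
        raise ValueError("correlation matrix must be square")
    if not np.allclose(corr, corr.T, atol=1e-8):
        raise ValueError("correlation matrix must be symmetric")
    if not (0.0 < r_th < 1.0):
        raise ValueError("r_th must lie strictly between 0 and 1")
    p = corr.shape[0]
    dropped: dict[int, tuple[int, float]] = {}
    for i in range(p):
        if i in dropped:
            continue
        for j in range(i + 1, p):
            if j in dropped:
                continue
            r = corr[i, j] if signed else abs(corr[i, j])
            if r > r_th:
                dropped[j] = (i, float(corr[i, j]))
    retained = tuple(i for i in range(p) if i not in dropped)
    eliminated = tuple((j, a, r) for j, (a, r) in sorted(dropped.items()))
    return ReductionResult(retained=retained, eliminated=eliminated, r_th=r_th)


def reduce_features(
    fm: FeatureMatrix, r_th: float = 0.8, signed: bool = False
) -> tuple[list[str], ReductionResult]:
    """Fit the reduction on a feature matrix and return the retained
    column names (categorical columns always appended)."""
    numeric = fm.numeric_columns
    corr = pearson_matrix(fm.data[numeric].to_numpy(dtype=float))
    res = greedy_reduce(corr, r_th=r_th, signed=signed)
    cols = [numeric[i] for i in res.retained] + [
        c for c in CATEGORICAL_COLUMNS if c in FEATURE_COLUMNS
    ]
    return cols, res
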