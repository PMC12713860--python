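"""End-to-end convenience drivers: raw night -> feature matrix -> report.

Each function here is thin glue over the preprocessing, detection,
feature, reduction and modelling modules, so scripts, the CLI and the
tests all run the identical computation.
"""

from __future__ import annotations

import numpy as np

from . import events as ev
from . import features as ft
from . import metrics as mt
from . import model as md
from .preprocess import PreprocessConfig, derive_signals
from .synth import GroundTruth, RawRecording, Scenario, generate_cohort, osa_scenario

__all__ = [
    "extract_night",
    "cohort_features",
    "run_experiment",
    "storm_fraction_by_subject",
]


def extract_night(
    rec: RawRecording,
    cfg: PreprocessConfig | None = None,
    amp_threshold: float = 0.5,
) -> ft.FeatureMatrix:
    """Preprocess one night, detect events/storms, extract all features."""
    cfg = cfg or PreprocessConfig(fs_in=rec.fs)
    derived = derive_signals(rec.signal, cfg)
    detected = ev.detect_events(derived.eda, fs=cfg.fs_out, amp_threshold=amp_threshold)
    storms = ev.detect_storms(detected, duration_s=rec.duration_s)
    return ft.extract_all(rec, derived, detected, storms)


def cohort_features(
    cohort: list[tuple[RawRecording, GroundTruth]],
    amp_threshold: float = 0.5,
) -> ft.FeatureMatrix:
    """Feature matrices of every night in a cohort, concatenated."""
    return ft.FeatureMatrix.concat(
        [extract_night(rec, amp_threshold=amp_threshold) for rec, _ in cohort]
    )


def run_experiment(
    fm: ft.FeatureMatrix,
    task: str,
    mode: str = "loso",
    cfg: md.EvalConfig | None = None,
    fold_average: bool = True,
) -> mt.EvalReport:
    """Cross-validated evaluation of one task on a cohort feature matrix."""
    spec = md.LabelSpec(task)
    cfg = cfg or md.EvalConfig()
    if mode == "loso":
        folds = md.loso_evaluate(fm, spec, cfg)
    elif mode == "personalized":
        folds = md.personalized_evaluate(fm, spec, cfg)
    else:
        raise ValueError("mode must be 'loso' or 'personalized'")
    return mt.aggregate_folds(folds, spec.class_names, task=task, fold_average=fold_average)


def storm_fraction_by_subject(
    n_subjects: int = 20,
    scenario: Scenario | None = None,
    seed: int = 0,
    amp_threshold: float = 0.5,
) -> tuple[np.ndarray, np.ndarray]:
    """Night-level detected storm-sample fraction vs planted AHI.

    Generates a cohort (by default the sparse-background OSA scenario,
    where the storm statistic is informative), runs the detector on each
    night and returns (ahi values, per-night fraction of time inside a
    detected storm) — the quantity whose monotone growth with apnoea
    severity the storm features encode.
    """
    from .preprocess import downsample

    scenario = scenario or osa_scenario()
    cohort = generate_cohort(n_subjects, scenario, seed=seed)
    ahis, fracs = [], []
    for rec, _ in cohort:
        eda = downsample(rec.signal, rec.fs, 35.0)
        detected = ev.detect_events(eda, fs=35.0, amp_threshold=amp_threshold)
        storms = ev.detect_storms(detected, duration_s=rec.duration_s)
        covered = sum(s.offset_s - s.onset_s for s in storms)
        ahis.append(rec.ahi)
        fracs.append(covered / rec.duration_s)
    return np.asarray(ahis), np.asarray(fracs)
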