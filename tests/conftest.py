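import numpy as np
import pandas as pd
import pytest

from edasleep.features import FEATURE_COLUMNS, FeatureMatrix
from edasleep.pipeline import extract_night
from edasleep.preprocess import derive_signals
from edasleep.synth import SubjectProfile, generate_hypnogram, generate_recording


@pytest.fixture(scope="session")
def night():
    """One 30-min synthetic night with ground truth (fixed seed)."""
    hyp = generate_hypnogram(60, (0.122, 0.165, 0.325, 0.182, 0.206), seed=11)
    profile = SubjectProfile("S000", "F", ahi=12.0, odi=10.0)
    return generate_recording(hyp, profile, seed=11)


@pytest.fixture(scope="session")
def night_derived(night):
    rec, _ = night
    return derive_signals(rec.signal)


@pytest.fixture(scope="session")
def night_features(night):
    rec, _ = night
    return extract_night(rec)


def make_feature_matrix(
    n_subjects: int = 4,
    epochs_per_subject: int = 40,
    seed: int = 0,
    informative: dict[str, np.ndarray] | None = None,
    stages=("W", "N1", "N2", "N3", "REM"),
    ahis=None,
) -> FeatureMatrix:
    """A synthetic feature matrix with i.i.d. noise features.

    ``informative`` maps column names to per-row values that overwrite
    the noise, letting tests plant a known signal in a known column.
    """
    rng = np.random.default_rng(seed)
    n = n_subjects * epochs_per_subject
    df = pd.DataFrame(
        rng.normal(size=(n, len(FEATURE_COLUMNS))), columns=list(FEATURE_COLUMNS)
    )
    df["sex"] = rng.integers(0, 2, n).astype(float)
    df["subject_id"] = np.repeat(
        [f"S{i:03d}" for i in range(n_subjects)], epochs_per_subject
    )
    df["stage"] = rng.choice(list(stages), n)
    if ahis is None:
        ahis = rng.uniform(0, 30, n_subjects)
    df["ahi"] = np.repeat(np.asarray(ahis, dtype=float), epochs_per_subject)
    df["odi"] = df["ahi"]
    if informative:
        for col, values in informative.items():
            df[col] = values
    return FeatureMatrix(df)


@pytest.fixture
def noise_fm():
    return make_feature_matrix(seed=5)
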