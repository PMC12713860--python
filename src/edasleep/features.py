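"""The 77-variable per-epoch EDA feature set.

Features are computed per 30 s epoch (1050 samples at 35 Hz) from the
derived signals:

====== ============================== =========================================
index  signal                         features
====== ============================== =========================================
1-18   EDA, detEDA                    mode, median, max |.|, line length,
                                      10th quantile, 75th quantile, SVD
                                      entropy, non-linear (Teager-Kaiser)
                                      energy, Shannon entropy
19-34  dEDA, d2EDA, ddetEDA, d2detEDA mean, variance, median, count > 0
35-40  EDA, detEDA                    max PSD, frequency of max PSD, Fisher's g
41-64  detail coefficients DL1-DL4    max, mean, std, median, Euclidean norm,
                                      normalised count > 0
65-70  EDA, detEDA                    Lyapunov exponent, max upper envelope,
                                      min lower envelope
71-72  diffEDA                        sum of cross-correlation, max convolution
73-76  EDA                            event-sample fraction, event energy,
                                      storm-sample fraction, storm energy
77     individual                     sex
====== ============================== =========================================

Conventions for quantities that are undefined on degenerate input are
fixed here once: histogram statistics use Freedman-Diaconis binning with
the modal-bin midpoint as the mode; entropies of single-bin or zero
signals are 0; the Lyapunov estimate of a constant trace is 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy.spatial.distance import cdist

from .events import EdaEvent, EdaStorm, event_storm_features
from .preprocess import DerivedSignals
from .synth import RawRecording

__all__ = [
    "FEATURE_COLUMNS",
    "META_COLUMNS",
    "FeatureMatrix",
    "FeatureNormalizer",
    "epoch_slices",
    "time_features",
    "derivative_features",
    "freq_features",
    "wavelet_features",
    "nonlinear_features",
    "diff_features",
    "extract_all",
    "normalize_features",
]

EPOCH_SAMPLES = 1050  # 30 s at 35 Hz

_TIME_NAMES = (
    "mode",
    "median",
    "max_abs",
    "line_length",
    "q10",
    "q75",
    "svd_entropy",
    "nonlinear_energy",
    "shannon_entropy",
)
_DERIV_NAMES = ("mean", "variance", "median", "n_above_zero")
_FREQ_NAMES = ("psd_max", "psd_argmax_freq", "fishers_g")
_WAVE_NAMES = ("max", "mean", "std", "median", "norm", "frac_above_zero")
_NONLIN_NAMES = ("lyapunov", "upper_env_max", "lower_env_min")

#: Canonical column order; index i corresponds to variable i+1.
FEATURE_COLUMNS: tuple[str, ...] = tuple(
    [f"eda_{n}" for n in _TIME_NAMES]
    + [f"deteda_{n}" for n in _TIME_NAMES]
    + [f"{d}_{n}" for d in ("d1eda", "d2eda", "d1deteda", "d2deteda") for n in _DERIV_NAMES]
    + [f"eda_{n}" for n in _FREQ_NAMES]
    + [f"deteda_{n}" for n in _FREQ_NAMES]
    + [f"dl{lvl}_{n}" for lvl in (1, 2, 3, 4) for n in _WAVE_NAMES]
    + [f"eda_{n}" for n in _NONLIN_NAMES]
    + [f"deteda_{n}" for n in _NONLIN_NAMES]
    + ["diffeda_xcorr_sum", "diffeda_conv_max"]
    + ["event_frac", "event_norm", "storm_frac", "storm_norm"]
    + ["sex"]
)
assert len(FEATURE_COLUMNS) == 77

META_COLUMNS = ("subject_id", "stage", "ahi", "odi")

CATEGORICAL_COLUMNS = ("sex",)


@dataclass
class FeatureMatrix:
    """Epochs x 77 feature table with per-row subject/stage/OSA labels.

    ``data`` holds the feature columns in canonical order followed by
    the metadata columns.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in FEATURE_COLUMNS + META_COLUMNS if c not in self.data]
        if missing:
            raise ValueError(f"feature matrix is missing columns: {missing[:5]}...")
        self.data = self.data[list(FEATURE_COLUMNS) + list(META_COLUMNS)].reset_index(
            drop=True
        )

    @property
    def features(self) -> pd.DataFrame:
        return self.data[list(FEATURE_COLUMNS)]

    @property
    def numeric_columns(self) -> list[str]:
        return [c for c in FEATURE_COLUMNS if c not in CATEGORICAL_COLUMNS]

    @property
    def subject_id(self) -> pd.Series:
        return self.data["subject_id"]

    @property
    def stage(self) -> pd.Series:
        return self.data["stage"]

    def __len__(self) -> int:
        return len(self.data)

    def subset(self, mask) -> "FeatureMatrix":
        return FeatureMatrix(self.data.loc[mask].reset_index(drop=True))

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "FeatureMatrix":
        return cls(pd.read_csv(path))

    @classmethod
    def concat(cls, parts: list["FeatureMatrix"]) -> "FeatureMatrix":
        return cls(pd.concat([p.data for p in parts], ignore_index=True))


def epoch_slices(recording: RawRecording) -> list[tuple[float, float]]:
    """Consecutive non-overlapping 30 s windows; trailing partial dropped."""
    dur = recording.duration_s
    if dur < 30:
        raise ValueError("recording shorter than one 30 s epoch")
    n = int(dur // 30)
    return [(30.0 * k, 30.0 * (k + 1)) for k in range(n)]


# --- elementary statistics -------------------------------------------------


def _fd_histogram(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Freedman-Diaconis histogram; collapses to one bin when IQR = 0."""
    q75, q25 = np.percentile(x, [75, 25])
    iqr = q75 - q25
    if iqr <= 0 or x.max() == x.min():
        return np.array([float(len(x))]), np.array([x.min(), x.max() + 1e-12])
    width = 2.0 * iqr / len(x) ** (1.0 / 3.0)
    nbins = max(int(np.ceil((x.max() - x.min()) / width)), 1)
    counts, edges = np.histogram(x, bins=min(nbins, 512))
    return counts.astype(float), edges


def _mode(x: np.ndarray) -> float:
    counts, edges = _fd_histogram(x)
    i = int(np.argmax(counts))
    return float(0.5 * (edges[i] + edges[i + 1]))


def _shannon_entropy(x: np.ndarray) -> float:
    counts, _ = _fd_histogram(x)
    p = counts / counts.sum()
    p = p[p > 0]
    if p.size <= 1:
        return 0.0
    return float(-(p * np.log(p)).sum())


def _svd_entropy(x: np.ndarray, dim: int = 10, delay: int = 1) -> float:
    """Shannon entropy of the normalised singular values of the
    delay-embedded trajectory matrix (delay 1, dimension 10)."""
    n = x.size - (dim - 1) * delay
    if n < dim:
        return 0.0
    idx = np.arange(dim) * delay + np.arange(n)[:, None]
    s = np.linalg.svd(x[idx], compute_uv=False)
    total = s.sum()
    if total <= 0:
        return 0.0
    p = s / total
    p = p[p > 1e-15]
    h = float(-(p * np.log(p)).sum())
    return h if h > 1e-12 else 0.0  # clamp rounding residue for rank-1 input


def _teager_kaiser(x: np.ndarray) -> float:
    if x.size < 3:
        return 0.0
    psi = x[1:-1] ** 2 - x[:-2] * x[2:]
    return float(psi.mean())


def time_features(x: np.ndarray) -> tuple[float, ...]:
    """The nine time-domain statistics of one epoch trace."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("empty epoch")
    return (
        _mode(x),
        float(np.median(x)),
        float(np.max(np.abs(x))),
        float(np.sum(np.abs(np.diff(x)))),
        float(np.percentile(x, 10)),
        float(np.percentile(x, 75)),
        _svd_entropy(x),
        _teager_kaiser(x),
        _shannon_entropy(x),
    )


def derivative_features(d: np.ndarray) -> tuple[float, float, float, int]:
    """(mean, population variance, median, count of strictly positive
    samples) of a derivative epoch trace."""
    d = np.asarray(d, dtype=float)
    if d.size == 0:
        raise ValueError("empty derivative trace")
    return (
        float(d.mean()),
        float(d.var()),  # population variance (ddof=0)
        float(np.median(d)),
        int(np.sum(d > 0)),
    )


def freq_features(x: np.ndarray, fs: float = 35.0) -> tuple[float, float, float]:
    """(max periodogram ordinate, its frequency, Fisher's g).

    Fisher's g is the maximum ordinate over the sum of ordinates with
    the zero-frequency term excluded; all three are 0 for an all-zero
    epoch.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 64:
        raise ValueError("epoch too short for a periodogram")
    f, p = sps.periodogram(x, fs=fs)
    f, p = f[1:], p[1:]  # drop DC
    total = p.sum()
    if total <= 0:
        return (0.0, 0.0, 0.0)
    i = int(np.argmax(p))
    return (float(p[i]), float(f[i]), float(p[i] / total))


def wavelet_features(dl_epoch: np.ndarray) -> tuple[float, ...]:
    """Six statistics of one decomposition level's coefficients within
    the epoch: max, mean, std, median, Euclidean norm, normalised count
    of strictly positive coefficients."""
    c = np.asarray(dl_epoch, dtype=float)
    if c.size == 0:
        raise ValueError("empty coefficient span for epoch")
    return (
        float(c.max()),
        float(c.mean()),
        float(c.std()),
        float(np.median(c)),
        float(np.linalg.norm(c)),
        float(np.mean(c > 0)),
    )


def lyapunov_exponent(
    x: np.ndarray,
    dim: int = 5,
    delay: int = 4,
    theiler: int = 35,
    follow: int = 30,
    stride: int = 3,
) -> float:
    """Largest-Lyapunov-exponent estimate (Rosenstein-style).

    Delay-embeds the trace, pairs every ``stride``-th point with its
    nearest neighbour outside a Theiler window, and fits the slope of
    the mean log divergence over ``follow`` steps.  Units: nats per
    sample.  Returns 0 for (near-)constant traces, for which divergence
    is undefined.
    """
    x = np.asarray(x, dtype=float)
    sd = x.std()
    if sd < 1e-12 or x.size < (dim - 1) * delay + theiler + follow + 2:
        return 0.0
    x = (x - x.mean()) / sd
    n = x.size - (dim - 1) * delay
    emb = x[np.arange(dim) * delay + np.arange(n)[:, None]]
    max_i = n - follow
    refs = np.arange(0, max_i, stride)
    d = cdist(emb[refs].astype(np.float32), emb.astype(np.float32))
    cols = np.arange(n)
    d[np.abs(cols[None, :] - refs[:, None]) <= theiler] = np.inf
    d[:, max_i:] = np.inf  # neighbour trajectories must be followable
    nn = np.argmin(d, axis=1)
    finite = np.isfinite(d[np.arange(len(refs)), nn])
    pairs_i, pairs_j = refs[finite], nn[finite]
    if pairs_i.size < 10:
        return 0.0
    logs = np.empty(follow)
    for k in range(follow):
        dk = np.linalg.norm(emb[pairs_i + k] - emb[pairs_j + k], axis=1)
        dk = np.maximum(dk, 1e-12)
        logs[k] = np.log(dk).mean()
    slope = np.polyfit(np.arange(follow), logs, 1)[0]
    return float(slope)


def _envelope_extrema(x: np.ndarray) -> tuple[float, float]:
    """(max of the upper peak envelope, min of the lower peak envelope)."""
    peaks, _ = sps.find_peaks(x)
    troughs, _ = sps.find_peaks(-x)
    upper = float(x[peaks].max()) if peaks.size else float(x.max())
    lower = float(x[troughs].min()) if troughs.size else float(x.min())
    return upper, lower


def nonlinear_features(x: np.ndarray) -> tuple[float, float, float]:
    """(Lyapunov exponent, max upper envelope, min lower envelope)."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("empty epoch")
    upper, lower = _envelope_extrema(x)
    return (lyapunov_exponent(x), upper, lower)


def diff_features(d: np.ndarray) -> tuple[float, float]:
    """(sum over all lags of the autocorrelation sequence, maximum of
    the self-convolution) of the diffEDA epoch trace.  The
    autocorrelation sum equals (sum d)^2, a useful cross-check."""
    d = np.asarray(d, dtype=float)
    if d.size == 0:
        return (0.0, 0.0)
    xcorr = np.correlate(d, d, mode="full")
    conv = np.convolve(d, d, mode="full")
    return (float(xcorr.sum()), float(conv.max()))


# --- per-recording assembly ------------------------------------------------


def _deriv_epoch(d: np.ndarray, offset: int, k: int) -> np.ndarray:
    """Slice a derivative trace (shifted by ``offset`` base samples) to
    epoch ``k``'s base-sample window."""
    start = max(k * EPOCH_SAMPLES - offset, 0)
    stop = min((k + 1) * EPOCH_SAMPLES - offset, len(d))
    return d[start:stop]


def _level_epoch(dl: np.ndarray, level: int, k: int) -> np.ndarray:
    factor = 2**level
    start = (k * EPOCH_SAMPLES) // factor
    stop = max(int(np.ceil((k + 1) * EPOCH_SAMPLES / factor)), start + 1)
    stop = min(stop, len(dl))
    if stop <= start:
        raise ValueError(f"empty level-{level} coefficient span for epoch {k}")
    return dl[start:stop]


def extract_all(
    recording: RawRecording,
    derived: DerivedSignals,
    events: list[EdaEvent],
    storms: list[EdaStorm],
) -> FeatureMatrix:
    """Assemble the full 77-column per-epoch feature matrix for one night."""
    fs = derived.fs
    n_epochs = min(len(recording.hypnogram), len(derived.eda) // EPOCH_SAMPLES)
    if n_epochs < 1:
        raise ValueError("recording shorter than one epoch")
    sex_code = 1.0 if recording.sex == "M" else 0.0
    rows = []
    for k in range(n_epochs):
        try:
            s0, s1 = k * EPOCH_SAMPLES, (k + 1) * EPOCH_SAMPLES
            eda_ep = derived.eda[s0:s1]
            det_ep = derived.det_eda[s0:s1]
            diff_ep = derived.diff_eda[s0:s1]
            row: list[float] = []
            row += list(time_features(eda_ep))
            row += list(time_features(det_ep))
            for d, off in (
                (derived.d1_eda, derived.d1_offset),
                (derived.d2_eda, derived.d2_offset),
                (derived.d1_det, derived.d1_offset),
                (derived.d2_det, derived.d2_offset),
            ):
                row += list(derivative_features(_deriv_epoch(d, off, k)))
            row += list(freq_features(eda_ep, fs))
            row += list(freq_features(det_ep, fs))
            for lvl in (1, 2, 3, 4):
                row += list(
                    wavelet_features(_level_epoch(derived.dwt_detail[lvl - 1], lvl, k))
                )
            row += list(nonlinear_features(eda_ep))
            row += list(nonlinear_features(det_ep))
            row += list(diff_features(diff_ep))
            row += list(
                event_storm_features(events, storms, (30.0 * k, 30.0 * (k + 1)), eda_ep, fs)
            )
            row.append(sex_code)
        except Exception as exc:  # attach the epoch index to any failure
            raise RuntimeError(f"feature extraction failed at epoch {k}: {exc}") from exc
        if not np.all(np.isfinite(row)):
            bad = [FEATURE_COLUMNS[i] for i, v in enumerate(row) if not np.isfinite(v)]
            raise RuntimeError(f"non-finite features at epoch {k}: {bad}")
        rows.append(row)
    df = pd.DataFrame(rows, columns=list(FEATURE_COLUMNS))
    df["subject_id"] = recording.subject_id
    df["stage"] = [recording.hypnogram.epoch_stage[k] for k in range(n_epochs)]
    df["ahi"] = recording.ahi
    df["odi"] = recording.odi
    return FeatureMatrix(df)


# --- cross-individual normalisation ---------------------------------------


@dataclass
class FeatureNormalizer:
    """Column-wise z-scoring fitted on training epochs only.

    The fitted transform is stored and applied unchanged to test
    epochs, so no information leaks from test subjects.  The
    categorical sex column is excluded; zero-variance columns are left
    unscaled with a warning.
    """

    mean_: dict[str, float] = field(default_factory=dict)
    std_: dict[str, float] = field(default_factory=dict)
    constant_columns: list[str] = field(default_factory=list)

    def fit(self, fm: FeatureMatrix) -> "FeatureNormalizer":
        if fm.subject_id.nunique() < 2:
            raise ValueError("normalisation requires epochs from >= 2 subjects")
        self.mean_, self.std_, self.constant_columns = {}, {}, []
        for col in fm.numeric_columns:
            v = fm.data[col].to_numpy(dtype=float)
            mu, sd = float(v.mean()), float(v.std())
            if sd <= 1e-12:
                self.constant_columns.append(col)
                self.mean_[col], self.std_[col] = 0.0, 1.0
            else:
                self.mean_[col], self.std_[col] = mu, sd
        if self.constant_columns:
            warnings.warn(
                f"zero-variance columns left unscaled: {self.constant_columns}",
                stacklevel=2,
            )
        return self

    def transform(self, fm: FeatureMatrix) -> FeatureMatrix:
        if not self.mean_:
            raise RuntimeError("normalizer has not been fitted")
        df = fm.data.copy()
        for col, mu in self.mean_.items():
            df[col] = (df[col] - mu) / self.std_[col]
        return FeatureMatrix(df)


def normalize_features(
    train: FeatureMatrix, test: FeatureMatrix | None = None
) -> tuple[FeatureMatrix, FeatureMatrix | None, FeatureNormalizer]:
    """Fit z-scoring on the training epochs and apply it to both sets."""
    norm = FeatureNormalizer().fit(train)
    train_n = norm.transform(train)
    test_n = norm.transform(test) if test is not None else None
    return train_n, test_n, norm
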