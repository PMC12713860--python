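"""EDA signal conditioning.

The raw 200 Hz trace is turned into the family of derived signals that
the feature set is computed from:

* ``eda`` — the trace anti-alias resampled to 35 Hz (all further work
  happens at 35 Hz; EDA events live in 0.25-3 Hz, far below the new
  17.5 Hz Nyquist);
* ``detEDA`` — the trace minus its whole-night least-squares
  second-order polynomial fit, removing individual tonic drift;
* ``sgEDA`` — a seventh-order Savitzky-Golay smoothing of the trace;
* ``dwtEDA`` — a 4-level discrete-wavelet reconstruction after soft
  thresholding of the detail coefficients (plus the thresholded
  per-level details DL1-DL4 themselves);
* ``diffEDA`` — dwtEDA minus sgEDA, isolating what wavelet denoising
  keeps but polynomial smoothing removes;
* first and second time derivatives of ``eda`` and ``detEDA`` via an
  order-50 FIR differentiator (passband 10 Hz, stopband 12.5 Hz), one
  pass per derivative order, discarding the 50-sample start-up
  transient of each pass.

Every stage here is linear and deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt
from scipy import signal as sps

__all__ = [
    "PreprocessConfig",
    "DerivedSignals",
    "downsample",
    "detrend_poly2",
    "savgol",
    "dwt_denoise",
    "make_diff_eda",
    "fir_derivative",
    "derive_signals",
]


@dataclass(frozen=True)
class PreprocessConfig:
    fs_in: float = 200.0
    fs_out: float = 35.0
    detrend_degree: int = 2
    sg_order: int = 7
    sg_window: int = 127          # ~3.6 s at 35 Hz; must be odd and > sg_order
    wavelet_name: str = "db4"
    dwt_levels: int = 4
    threshold_rule: str = "universal"   # sigma * sqrt(2 ln n), sigma from DL1 MAD
    fir_order: int = 50
    fir_passband: float = 10.0
    fir_stopband: float = 12.5
    transient_discard: int = 50

    def __post_init__(self) -> None:
        if self.sg_window % 2 == 0 or self.sg_window <= self.sg_order:
            raise ValueError("sg_window must be odd and greater than sg_order")
        if not (self.fir_passband < self.fir_stopband < self.fs_out / 2):
            raise ValueError("need fir_passband < fir_stopband < fs_out/2")
        if self.dwt_levels != 4:
            raise ValueError("feature set requires exactly 4 decomposition levels")


@dataclass
class DerivedSignals:
    """The preprocessing products for one night, all at ``fs`` Hz.

    ``eda``..``diff_eda`` share one length.  Derivative traces are
    shorter: each differentiator pass discards ``transient_discard``
    samples and delays the output by ``fir_order / 2`` samples, so
    sample ``j`` of a derivative trace estimates the derivative at base
    sample ``j + offset`` (``offset`` = discard − delay per pass).
    ``dwt_detail[l]`` holds the thresholded level-(l+1) detail
    coefficients (DL1 = finest).
    """

    fs: float
    eda: np.ndarray
    det_eda: np.ndarray
    sg_eda: np.ndarray
    dwt_eda: np.ndarray
    diff_eda: np.ndarray
    d1_eda: np.ndarray
    d2_eda: np.ndarray
    d1_det: np.ndarray
    d2_det: np.ndarray
    dwt_detail: list[np.ndarray]
    d1_offset: int
    d2_offset: int

    def __post_init__(self) -> None:
        n = len(self.eda)
        for name in ("det_eda", "sg_eda", "dwt_eda", "diff_eda"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length differs from eda length")


def downsample(x: np.ndarray, fs_in: float = 200.0, fs_out: float = 35.0) -> np.ndarray:
    """Anti-aliased rational resampling (7/40 for 200 -> 35 Hz)."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("cannot downsample an empty trace")
    if x.size < 40:
        raise ValueError("trace too short to downsample (need >= 40 samples)")
    from fractions import Fraction

    frac = Fraction(fs_out / fs_in).limit_denominator(1000)
    # remove the mean first: the polyphase branches of the anti-alias FIR
    # carry ~1e-5 DC ripple, which would smear a constant signal
    m = x.mean()
    return (
        sps.resample_poly(x - m, frac.numerator, frac.denominator, padtype="line") + m
    )


def detrend_poly2(x: np.ndarray, degree: int = 2) -> np.ndarray:
    """Subtract the whole-recording least-squares degree-2 polynomial.

    Removes the subject-specific tonic drift so that signals from
    different sweating patterns become comparable.  Idempotent: the
    output's best quadratic fit is zero.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 samples to fit a quadratic")
    t = np.linspace(-1.0, 1.0, x.size)  # scaled abscissa for conditioning
    coeffs = np.polynomial.polynomial.polyfit(t, x, degree)
    return x - np.polynomial.polynomial.polyval(t, coeffs)


def _sg_coeffs(window: int, order: int) -> np.ndarray:
    """Savitzky-Golay smoothing weights on a scaled abscissa.

    Solving the local least-squares fit on positions scaled to [-1, 1]
    keeps the degree-7 normal equations well conditioned (the unscaled
    Vandermonde loses ~6 digits at a 127-sample window), so polynomials
    up to the fit order pass through the filter exactly.
    """
    half = (window - 1) // 2
    pos = (np.arange(window) - half) / half
    A = np.polynomial.polynomial.polyvander(pos, order)
    # fitted value at the window centre = <weights, samples>
    e0 = np.zeros(order + 1)
    e0[0] = 1.0
    return A @ np.linalg.solve(A.T @ A, e0)


def savgol(x: np.ndarray, cfg: PreprocessConfig | None = None) -> np.ndarray:
    """Seventh-order Savitzky-Golay smoothing (removes > ~3 Hz content
    at the default 127-sample window while passing local polynomials of
    degree <= 7 unchanged).  Edge samples are filled by evaluating the
    polynomial fitted to the first/last full window."""
    cfg = cfg or PreprocessConfig()
    x = np.asarray(x, dtype=float)
    if x.size < cfg.sg_window:
        raise ValueError(
            f"trace length {x.size} shorter than the SG window {cfg.sg_window}"
        )
    w = _sg_coeffs(cfg.sg_window, cfg.sg_order)
    y = np.convolve(x, w[::-1], mode="same")
    half = (cfg.sg_window - 1) // 2
    pos = (np.arange(cfg.sg_window) - half) / half
    for sl, seg in ((slice(0, half), x[: cfg.sg_window]),
                    (slice(-half, None), x[-cfg.sg_window :])):
        coeffs = np.polynomial.polynomial.polyfit(pos, seg, cfg.sg_order)
        at = pos[:half] if sl.start == 0 else pos[-half:]
        y[sl] = np.polynomial.polynomial.polyval(at, coeffs)
    return y


def dwt_denoise(
    x: np.ndarray,
    cfg: PreprocessConfig | None = None,
    threshold: float | None = None,
) -> tuple[np.ndarray, list[np.ndarray]]:
    """4-level DWT soft-threshold denoising.

    The threshold defaults to the universal rule sigma*sqrt(2 ln n) with
    sigma estimated from the median absolute deviation of the finest
    detail level (MAD / 0.6745); pass ``threshold=0`` for the
    perfect-reconstruction identity.  Returns the denoised trace and the
    thresholded detail coefficients DL1..DL4 (finest first), which feed
    the time-frequency features.
    """
    cfg = cfg or PreprocessConfig()
    x = np.asarray(x, dtype=float)
    wav = pywt.Wavelet(cfg.wavelet_name)
    if x.size < 2**cfg.dwt_levels or x.size < wav.dec_len:
        raise ValueError("trace too short for a 4-level DWT")
    coeffs = pywt.wavedec(x, wav, level=cfg.dwt_levels)
    # coeffs = [cA4, cD4, cD3, cD2, cD1]
    if threshold is None:
        d1 = coeffs[-1]
        sigma = np.median(np.abs(d1 - np.median(d1))) / 0.6745
        threshold = float(sigma * np.sqrt(2.0 * np.log(max(x.size, 2))))
    if threshold > 0:
        thr = [coeffs[0]] + [
            pywt.threshold(c, threshold, mode="soft") for c in coeffs[1:]
        ]
    else:  # nothing to shrink (also avoids 0/0 inside soft thresholding)
        thr = list(coeffs)
    rec = pywt.waverec(thr, wav)[: x.size]
    details = [thr[-1], thr[-2], thr[-3], thr[-4]]  # DL1 (finest) .. DL4
    return rec, details


def make_diff_eda(dwt_eda: np.ndarray, sg_eda: np.ndarray) -> np.ndarray:
    """diffEDA = wavelet-denoised trace minus Savitzky-Golay trace."""
    dwt_eda = np.asarray(dwt_eda, dtype=float)
    sg_eda = np.asarray(sg_eda, dtype=float)
    if dwt_eda.shape != sg_eda.shape:
        raise ValueError("dwt_eda and sg_eda must have equal length")
    return dwt_eda - sg_eda


def _differentiator(cfg: PreprocessConfig) -> np.ndarray:
    """Linear-phase (type III) FIR differentiator: gain 2*pi*f in the
    passband, zero in the stopband."""
    return sps.firwin2(
        cfg.fir_order + 1,
        [0.0, cfg.fir_passband, cfg.fir_stopband, cfg.fs_out / 2],
        [0.0, 2 * np.pi * cfg.fir_passband, 0.0, 0.0],
        fs=cfg.fs_out,
        antisymmetric=True,
    )


def fir_derivative(
    x: np.ndarray, order: int = 1, cfg: PreprocessConfig | None = None
) -> tuple[np.ndarray, int]:
    """First or second time derivative via the FIR differentiator.

    One filter pass per derivative order; the first
    ``transient_discard`` output samples of each pass are dropped.
    Returns ``(trace, offset)`` where sample ``j`` of the trace
    estimates the derivative at input sample ``j + offset`` (the offset
    accounts for the discard minus the filter's group delay).
    """
    if order not in (1, 2):
        raise ValueError("order must be 1 or 2")
    cfg = cfg or PreprocessConfig()
    x = np.asarray(x, dtype=float)
    min_len = order * (cfg.fir_order + cfg.transient_discard)
    if x.size <= min_len:
        raise ValueError(f"trace too short for order-{order} differentiation")
    h = _differentiator(cfg)
    delay = cfg.fir_order // 2
    y = x
    offset = 0
    for _ in range(order):
        y = sps.lfilter(h, 1.0, y)[cfg.transient_discard :]
        offset += cfg.transient_discard - delay
    return y, offset


def derive_signals(
    x200: np.ndarray, cfg: PreprocessConfig | None = None
) -> DerivedSignals:
    """Run the full conditioning chain on a raw trace at ``cfg.fs_in``."""
    cfg = cfg or PreprocessConfig()
    eda = downsample(x200, cfg.fs_in, cfg.fs_out)
    det = detrend_poly2(eda, cfg.detrend_degree)
    sg = savgol(eda, cfg)
    dwt, details = dwt_denoise(eda, cfg)
    diff = make_diff_eda(dwt, sg)
    d1_eda, off1 = fir_derivative(eda, 1, cfg)
    d2_eda, off2 = fir_derivative(eda, 2, cfg)
    d1_det, _ = fir_derivative(det, 1, cfg)
    d2_det, _ = fir_derivative(det, 2, cfg)
    return DerivedSignals(
        fs=cfg.fs_out,
        eda=eda,
        det_eda=det,
        sg_eda=sg,
        dwt_eda=dwt,
        diff_eda=diff,
        d1_eda=d1_eda,
        d2_eda=d2_eda,
        d1_det=d1_det,
        d2_det=d2_det,
        dwt_detail=details,
        d1_offset=off1,
        d2_offset=off2,
    )
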