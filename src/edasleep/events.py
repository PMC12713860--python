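"""EDA event and storm detection.

An EDA *event* is a band-limited (0.25-3 Hz) oscillation of the skin
potential.  Detection runs in two stages.  First, the 35 Hz trace is
band-passed with a zero-phase filter (so onsets are not shifted), split
into lobes at zero crossings, and an event is seeded wherever a lobe's
peak magnitude reaches the amplitude threshold, growing over
neighbouring lobes above half the peak.  Second — because band-passing
a one-signed excursion necessarily creates zero-mean ringing
side-lobes, which reach 25-45% of the peak for slow events — the
candidate span is re-examined on the *raw* trace after subtracting a
locally interpolated baseline: the lobes found there are genuine
morphology, and the run of lobes reaching at least 25% of the raw peak
fixes the onset, offset and phase count.  The lobe count classifies the
morphology: one lobe -> positive or negative monophasic, two ->
biphasic, three or more -> triphasic.

An EDA *storm* is a timespan of at least one minute containing at least
two events: every sliding 60 s window holding >= 2 event onsets
qualifies, and overlapping qualifying windows merge into one storm.

Four per-epoch summary features are derived: the fraction of epoch
samples inside an event (or storm) and the Euclidean norm of the trace
restricted to those samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

__all__ = [
    "EdaEvent",
    "EdaStorm",
    "bandpass",
    "detect_events",
    "detect_storms",
    "event_storm_features",
]

MAX_EVENT_SPAN_S = 12.0  # three full periods at the 0.25 Hz band edge


@dataclass(frozen=True)
class EdaEvent:
    onset_s: float
    offset_s: float
    kind: str  # mono+ | mono- | bi | tri
    peak_amplitude: float

    def __post_init__(self) -> None:
        if not self.onset_s < self.offset_s:
            raise ValueError("event onset must precede offset")
        if self.kind not in ("mono+", "mono-", "bi", "tri"):
            raise ValueError(f"unknown event kind {self.kind!r}")


@dataclass(frozen=True)
class EdaStorm:
    onset_s: float
    offset_s: float
    n_events: int

    def __post_init__(self) -> None:
        if self.offset_s - self.onset_s < 60.0 - 1e-9:
            raise ValueError("a storm must span at least 60 s")
        if self.n_events < 2:
            raise ValueError("a storm must contain at least 2 events")


def bandpass(
    x: np.ndarray, fs: float = 35.0, band: tuple[float, float] = (0.25, 3.0)
) -> np.ndarray:
    """Zero-phase Butterworth band-pass to the EDA event band."""
    sos = sps.butter(2, band, btype="bandpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, np.asarray(x, dtype=float))


def _lobes(bp: np.ndarray) -> list[tuple[int, int, float]]:
    """Split the band-passed trace into constant-sign lobes.

    Returns (start, stop, signed_peak) per lobe, stop exclusive.
    """
    sign = np.sign(bp)
    sign[sign == 0] = 1
    changes = np.flatnonzero(np.diff(sign)) + 1
    bounds = np.concatenate([[0], changes, [len(bp)]])
    out = []
    for a, b in zip(bounds[:-1], bounds[1:]):
        seg = bp[a:b]
        idx = np.argmax(np.abs(seg))
        out.append((int(a), int(b), float(seg[idx])))
    return out


def _refine_on_raw(
    x: np.ndarray, start: int, stop: int, fs: float, lobe_ratio: float
) -> tuple[int, int, str, float] | None:
    """Morphology and boundaries from the raw trace over a candidate span.

    A local baseline is interpolated linearly between the trace medians
    just before and after the span and subtracted; the run of lobes of
    the residual that reach ``lobe_ratio`` of its peak, around the peak
    lobe, gives the final onset, offset and phase count.
    """
    pad = int(0.5 * fs)
    a = max(start - pad, 0)
    b = min(stop + pad, len(x))
    pre = x[max(a - pad, 0) : a]
    post = x[b : b + pad]
    left = np.median(pre) if pre.size else np.median(x[a : a + pad])
    right = np.median(post) if post.size else np.median(x[b - pad : b])
    seg = x[a:b] - np.linspace(left, right, b - a)
    lobes = _lobes(seg)
    if not lobes:
        return None
    peaks = np.array([abs(p) for _, _, p in lobes])
    imax = int(np.argmax(peaks))
    ref = peaks[imax]
    if ref <= 0:
        return None
    lo = imax
    while lo - 1 >= 0 and peaks[lo - 1] >= lobe_ratio * ref:
        lo -= 1
    hi = imax
    while hi + 1 < len(lobes) and peaks[hi + 1] >= lobe_ratio * ref:
        hi += 1
    count = hi - lo + 1
    # trim boundary lobes to their 10%-of-lobe-peak crossings, so flat
    # (near-zero) stretches sharing the lobe's sign do not stretch the span
    s0, s1 = lobes[lo][0], lobes[hi][1]
    seg_abs = np.abs(seg)
    above0 = np.flatnonzero(seg_abs[s0 : lobes[lo][1]] >= 0.1 * peaks[lo])
    if above0.size:
        s0 = s0 + int(above0[0])
    above1 = np.flatnonzero(seg_abs[lobes[hi][0] : s1] >= 0.1 * peaks[hi])
    if above1.size:
        s1 = lobes[hi][0] + int(above1[-1]) + 1
    if count == 1:
        kind = "mono+" if lobes[imax][2] > 0 else "mono-"
    elif count == 2:
        kind = "bi"
    else:
        kind = "tri"
    return a + s0, a + s1, kind, float(ref)


def detect_events(
    x: np.ndarray,
    fs: float = 35.0,
    amp_threshold: float = 0.5,
    band: tuple[float, float] = (0.25, 3.0),
    lobe_ratio: float = 0.25,
    grow_ratio: float = 0.5,
    edge_guard_s: float = 2.0,
) -> list[EdaEvent]:
    """Detect EDA events on a 35 Hz trace (see module docstring).

    Parameters
    ----------
    x : trace of at least 60 s.
    amp_threshold : minimum peak magnitude (signal units) of the
        band-passed excursion for an event to be seeded.
    band : detection band in Hz.
    lobe_ratio : a raw-trace lobe counts towards the morphology while
        its peak is at least this fraction of the event's peak.
    grow_ratio : candidate-span growth ratio on the band-passed trace
        (kept higher than ``lobe_ratio`` to exclude filter ringing).
    edge_guard_s : events whose seed lobe falls within this margin of
        the trace boundaries are discarded (zero-phase filtering leaves
        start-up transients there, and truncated events have no
        interpretable morphology).
    """
    x = np.asarray(x, dtype=float)
    if amp_threshold <= 0:
        raise ValueError("amp_threshold must be positive")
    if x.size < 60 * fs:
        raise ValueError("need at least 60 s of signal")
    bp = bandpass(x, fs, band)
    lobes = _lobes(bp)
    peaks = np.array([abs(p) for _, _, p in lobes])
    n_lobes = len(lobes)
    used = np.zeros(n_lobes, dtype=bool)
    raw: list[tuple[int, int, str, float]] = []
    max_span = int(MAX_EVENT_SPAN_S * fs)
    guard = int(edge_guard_s * fs)
    for i in np.argsort(-peaks):
        if used[i] or peaks[i] < amp_threshold:
            continue
        if lobes[i][1] <= guard or lobes[i][0] >= x.size - guard:
            used[i] = True
            continue
        lo = hi = i
        ref = peaks[i]
        while lo - 1 >= 0 and not used[lo - 1] and peaks[lo - 1] >= grow_ratio * ref:
            lo -= 1
        while (
            hi + 1 < n_lobes and not used[hi + 1] and peaks[hi + 1] >= grow_ratio * ref
        ):
            hi += 1
        start = lobes[lo][0]
        stop = lobes[hi][1]
        if stop - start > max_span:  # clip runaway growth to the band limit
            mid = (lobes[i][0] + lobes[i][1]) // 2
            start = max(start, mid - max_span // 2)
            stop = min(stop, mid + max_span // 2)
        # consume filter-ringing side-lobes too (>= ring_ratio of the peak)
        # so they cannot seed spurious duplicate events
        ring_ratio = 0.1
        mlo, mhi = lo, hi
        while mlo - 1 >= 0 and peaks[mlo - 1] >= ring_ratio * ref:
            mlo -= 1
        while mhi + 1 < n_lobes and peaks[mhi + 1] >= ring_ratio * ref:
            mhi += 1
        used[mlo : mhi + 1] = True
        refined = _refine_on_raw(x, start, stop, fs, lobe_ratio)
        if refined is not None:
            raw.append(refined)
    # resolve overlaps after refinement: keep the larger-amplitude event
    raw.sort(key=lambda r: -r[3])
    kept: list[tuple[int, int, str, float]] = []
    for cand in raw:
        if all(cand[1] <= k[0] or cand[0] >= k[1] for k in kept):
            kept.append(cand)
    events = [
        EdaEvent(onset_s=a / fs, offset_s=b / fs, kind=kind, peak_amplitude=amp)
        for a, b, kind, amp in kept
    ]
    events.sort(key=lambda e: e.onset_s)
    return events


def detect_storms(
    events: list[EdaEvent],
    duration_s: float | None = None,
    window_s: float = 60.0,
) -> list[EdaStorm]:
    """Merge qualifying 60 s windows (>= 2 event onsets) into storms.

    Any window position [t, t+60] containing at least two event onsets
    qualifies; the union of all qualifying windows, clamped to the
    recording, forms the storm spans.  A pair of onsets further than
    60 s apart never shares a window and so never forms a storm by
    itself.
    """
    onsets = [e.onset_s for e in events]
    if onsets != sorted(onsets):
        raise ValueError("events must be sorted by onset")
    spans: list[tuple[float, float]] = []
    for i in range(len(onsets)):
        for j in range(i + 1, len(onsets)):
            gap = onsets[j] - onsets[i]
            if gap > window_s:
                break
            # union of all windows covering both onsets
            lo = max(onsets[j] - window_s, 0.0)
            hi = onsets[i] + window_s
            if duration_s is not None:
                hi = min(hi, duration_s)
            spans.append((lo, hi))
    if not spans:
        return []
    spans.sort()
    merged = [spans[0]]
    for lo, hi in spans[1:]:
        if lo <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], hi))
        else:
            merged.append((lo, hi))
    storms = []
    for lo, hi in merged:
        n = sum(1 for t in onsets if lo <= t <= hi)
        storms.append(EdaStorm(onset_s=lo, offset_s=hi, n_events=n))
    return storms


def _interval_mask(
    intervals: list[tuple[float, float]],
    start_s: float,
    end_s: float,
    n_samples: int,
    fs: float,
) -> np.ndarray:
    mask = np.zeros(n_samples, dtype=bool)
    for a, b in intervals:
        if b <= start_s or a >= end_s:
            continue
        i0 = max(int(np.ceil((a - start_s) * fs)), 0)
        i1 = min(int(np.ceil((b - start_s) * fs)), n_samples)
        mask[i0:i1] = True
    return mask


def event_storm_features(
    events: list[EdaEvent],
    storms: list[EdaStorm],
    epoch_window: tuple[float, float],
    x_epoch: np.ndarray,
    fs: float = 35.0,
) -> tuple[float, float, float, float]:
    """The four per-epoch event/storm features.

    Returns (event-sample fraction, Euclidean norm of the trace on
    event samples, storm-sample fraction, norm on storm samples).  The
    norm is taken over the raw 35 Hz trace of the epoch.
    """
    start_s, end_s = epoch_window
    if end_s - start_s != 30:
        raise ValueError("epoch window must span exactly 30 s")
    x_epoch = np.asarray(x_epoch, dtype=float)
    n = x_epoch.size
    if n == 0:
        raise ValueError("empty epoch trace")
    ev_mask = _interval_mask(
        [(e.onset_s, e.offset_s) for e in events], start_s, end_s, n, fs
    )
    st_mask = _interval_mask(
        [(s.onset_s, s.offset_s) for s in storms], start_s, end_s, n, fs
    )
    return (
        float(ev_mask.mean()),
        float(np.linalg.norm(x_epoch[ev_mask])),
        float(st_mask.mean()),
        float(np.linalg.norm(x_epoch[st_mask])),
    )
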