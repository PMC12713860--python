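"""Synthetic full-night electrodermal activity (EDA) cohorts.

Real overnight EDA recordings with expert-scored hypnograms are rarely
shareable, so every downstream stage of this package (preprocessing,
event/storm detection, feature extraction, classification) is exercised
against cohorts produced here.  A synthetic night consists of

* a hypnogram — a per-30-s-epoch sequence of sleep stages (W, N1, N2,
  N3, REM) generated by a cyclically modulated first-order Markov chain
  whose long-run stage proportions match a requested mix;
* a raw 200 Hz EDA trace — slow tonic drift (second-order polynomial
  plus a smoothed random walk) with planted band-limited (0.25-3 Hz)
  oscillatory events at a stage-dependent rate, storm episodes (event
  clusters spanning >= 60 s) whose nightly density grows with the
  subject's apnoea severity, sparse movement-artifact spikes, and white
  measurement noise;
* ground truth — the exact onset/offset/type of every planted event and
  storm, which serves as the oracle for detector tests.

All generators are pure functions of their arguments and a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

STAGES = ("W", "N1", "N2", "N3", "REM")
EVENT_KINDS = ("mono+", "mono-", "bi", "tri")
EPOCH_LEN_S = 30

__all__ = [
    "STAGES",
    "EVENT_KINDS",
    "EPOCH_LEN_S",
    "Hypnogram",
    "SubjectProfile",
    "GroundTruth",
    "RawRecording",
    "Scenario",
    "generate_hypnogram",
    "generate_recording",
    "generate_cohort",
]


@dataclass(frozen=True)
class Hypnogram:
    """Per-epoch sleep-stage sequence at 30 s resolution."""

    epoch_stage: tuple[str, ...]
    epoch_len_s: int = EPOCH_LEN_S

    def __post_init__(self) -> None:
        if len(self.epoch_stage) < 1:
            raise ValueError("hypnogram must contain at least one epoch")
        if self.epoch_len_s != EPOCH_LEN_S:
            raise ValueError(f"epoch length must be {EPOCH_LEN_S} s")
        bad = set(self.epoch_stage) - set(STAGES)
        if bad:
            raise ValueError(f"unknown stage codes: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.epoch_stage)

    @property
    def duration_s(self) -> float:
        return len(self) * self.epoch_len_s

    def proportions(self) -> dict[str, float]:
        n = len(self)
        return {s: self.epoch_stage.count(s) / n for s in STAGES}


@dataclass(frozen=True)
class SubjectProfile:
    """Per-subject generative parameters.

    Rates are events/min (stage_event_rate, storm_burst_rate) or
    spikes/hour (artifact_rate).  ``tonic_level`` and amplitudes are in
    microvolt-scale signal units; ``drift_coeffs`` are the three
    coefficients (c0, c1, c2) of a second-order polynomial in normalised
    recording time t in [0, 1].
    """

    subject_id: str
    sex: str
    ahi: float
    odi: float
    tonic_level: float = 10.0
    drift_coeffs: tuple[float, float, float] = (0.0, 0.0, 0.0)
    stage_event_rate: dict[str, float] = field(
        default_factory=lambda: {"W": 0.2, "N1": 0.6, "N2": 2.0, "N3": 5.0, "REM": 3.0}
    )
    storm_burst_rate: float = 6.0
    artifact_rate: float = 2.0
    noise_sd: float = 0.1
    event_amp_range: tuple[float, float] = (1.5, 6.0)
    amp_scale: float = 1.0
    walk_sd: float = 0.002
    #: optional per-stage carrier-frequency band (Hz) of planted events;
    #: stages absent from the map use the full 0.25-3 Hz band
    stage_freq_range: dict[str, tuple[float, float]] = field(default_factory=dict)
    #: optional per-stage multiplier on event amplitude
    stage_amp_scale: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.sex not in ("F", "M"):
            raise ValueError("sex must be 'F' or 'M'")
        if self.ahi < 0 or self.odi < 0:
            raise ValueError("AHI and ODI must be non-negative")
        if len(self.drift_coeffs) != 3:
            raise ValueError("drift_coeffs must have exactly 3 entries")
        if any(v < 0 for v in self.stage_event_rate.values()):
            raise ValueError("stage event rates must be non-negative")
        if self.storm_burst_rate < 0 or self.artifact_rate < 0 or self.noise_sd < 0:
            raise ValueError("rates and noise_sd must be non-negative")


@dataclass(frozen=True)
class GroundTruth:
    """Planted event and storm intervals, the oracle for detector tests."""

    event_intervals: tuple[tuple[float, float, str], ...]
    storm_intervals: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        for onset, offset, kind in self.event_intervals:
            if not (0 <= onset < offset):
                raise ValueError("event intervals must satisfy 0 <= onset < offset")
            if kind not in EVENT_KINDS:
                raise ValueError(f"unknown event kind {kind!r}")
        for onset, offset in self.storm_intervals:
            if not (0 <= onset < offset):
                raise ValueError("storm intervals must satisfy 0 <= onset < offset")
        ev = [e[0] for e in self.event_intervals]
        st = [s[0] for s in self.storm_intervals]
        if ev != sorted(ev) or st != sorted(st):
            raise ValueError("intervals must be sorted by onset")


@dataclass(frozen=True)
class RawRecording:
    """One subject's raw EDA night plus labels."""

    subject_id: str
    signal: np.ndarray
    fs: float
    hypnogram: Hypnogram
    sex: str
    ahi: float
    odi: float

    @property
    def duration_s(self) -> float:
        return len(self.signal) / self.fs


def _cycle_weights(stage_mix: np.ndarray, phase: float, strength: float) -> np.ndarray:
    """Stage weights modulated over the sleep cycle, zero-mean over a cycle.

    Early cycle phase favours deep sleep (N3), late phase favours REM —
    the hallmark ultradian pattern — while wake is pushed towards cycle
    boundaries.  Because each stage's modulation integrates to zero over
    a full cycle, the long-run proportions stay at ``stage_mix`` to
    first order in ``strength``.
    """
    mod = np.array(
        [
            np.cos(2 * np.pi * phase),            # W: cycle boundaries
            np.sin(2 * np.pi * phase),            # N1
            -np.cos(2 * np.pi * phase) * 0.5,     # N2
            np.cos(2 * np.pi * (phase - 0.15)),   # N3: early cycle
            -np.cos(2 * np.pi * (phase - 0.1)),   # REM: late cycle
        ]
    )
    w = stage_mix * (1.0 + strength * mod)
    w = np.clip(w, 1e-12, None)
    return w / w.sum()


def generate_hypnogram(
    n_epochs: int,
    stage_mix: tuple[float, float, float, float, float],
    cycle_len_epochs: int = 180,
    seed: int = 0,
    persistence: float = 0.85,
    cycle_strength: float = 0.3,
) -> Hypnogram:
    """Generate a hypnogram from a cyclic first-order Markov model.

    Each step stays in the current stage with probability ``persistence``
    and otherwise resamples from the cycle-modulated stage distribution.
    The chain's long-run stage proportions converge to ``stage_mix``
    (modulation averages out over each ~90-min cycle).

    Parameters
    ----------
    n_epochs : number of 30 s epochs (>= 1).
    stage_mix : target long-run proportions of (W, N1, N2, N3, REM);
        must sum to 1.
    cycle_len_epochs : sleep-cycle period in epochs (180 = 90 min).
    seed : RNG seed; identical seeds give identical hypnograms.
    """
    if n_epochs < 1:
        raise ValueError("n_epochs must be >= 1")
    mix = np.asarray(stage_mix, dtype=float)
    if mix.shape != (5,):
        raise ValueError("stage_mix must contain exactly 5 proportions")
    if np.any(mix < 0):
        raise ValueError("stage_mix proportions must be non-negative")
    if abs(mix.sum() - 1.0) > 1e-9:
        raise ValueError(
            f"stage_mix must sum to 1 (got {mix.sum():.12g}); normalise it first"
        )
    rng = np.random.default_rng(seed)
    stages = np.empty(n_epochs, dtype=object)
    w0 = _cycle_weights(mix, 0.0, cycle_strength)
    current = int(rng.choice(5, p=w0))
    stages[0] = STAGES[current]
    for k in range(1, n_epochs):
        if rng.random() >= persistence:
            phase = (k % cycle_len_epochs) / cycle_len_epochs
            w = _cycle_weights(mix, phase, cycle_strength)
            current = int(rng.choice(5, p=w))
        stages[k] = STAGES[current]
    return Hypnogram(tuple(stages))


def _event_waveform(
    kind: str, freq: float, amp: float, fs: float, sign: int
) -> np.ndarray:
    """A planted oscillation: ``n_lobes`` alternating half-cycles of a
    sine at ``freq``, Hann-tapered so the excursion starts and ends at
    zero.  Lobe count fixes the morphology: 1 -> monophasic, 2 ->
    biphasic, 3 -> triphasic."""
    n_lobes = {"mono+": 1, "mono-": 1, "bi": 2, "tri": 3}[kind]
    dur = n_lobes / (2.0 * freq)
    n = max(int(round(dur * fs)), 8)
    t = np.arange(n) / fs
    # sin(pi * k * t / dur) has exactly k alternating half-period lobes on [0, dur]
    wave = np.sin(np.pi * n_lobes * t / dur)
    # flat-top taper: every genuine lobe keeps >= ~80% of the peak amplitude,
    # well above band-pass ringing, so morphology survives detection
    from scipy.signal.windows import tukey

    return sign * amp * wave * tukey(n, 0.3)


def _place_events(
    rng: np.random.Generator,
    windows: list[tuple[float, float]],
    n_events: int,
    occupied: list[tuple[float, float]],
    fs: float,
    amp_range: tuple[float, float],
    min_gap: float = 1.0,
    freq_range: tuple[float, float] = (0.25, 3.0),
    amp_scale: float = 1.0,
) -> list[tuple[float, float, str, np.ndarray]]:
    """Draw ``n_events`` non-overlapping events inside the given windows."""
    out = []
    lo, hi = amp_range
    for _ in range(n_events):
        kind = EVENT_KINDS[rng.integers(0, 4)]
        freq = rng.uniform(*freq_range)
        amp = amp_scale * float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        sign = -1 if kind == "mono-" else 1
        wave = _event_waveform(kind, freq, amp, fs, sign)
        dur = len(wave) / fs
        for _attempt in range(20):
            w0, w1 = windows[rng.integers(0, len(windows))]
            if w1 - w0 <= dur:
                continue
            onset = rng.uniform(w0, w1 - dur)
            offset = onset + dur
            if all(
                offset + min_gap <= a or onset - min_gap >= b for a, b in occupied
            ):
                occupied.append((onset, offset))
                out.append((onset, offset, kind, wave))
                break
    return out


def generate_recording(
    hypnogram: Hypnogram,
    profile: SubjectProfile,
    fs: float = 200.0,
    seed: int = 0,
) -> tuple[RawRecording, GroundTruth]:
    """Synthesize one night of raw EDA at ``fs`` Hz with ground truth.

    The trace is the sum of a tonic component (baseline + second-order
    polynomial drift + smoothed random walk), planted oscillatory events
    at the current stage's rate, storm episodes whose nightly count
    increases linearly with min(AHI, 30), rectangular movement-artifact
    spikes, and white Gaussian noise.
    """
    if fs < 70:
        raise ValueError("fs must be >= 70 Hz (downsampling to 35 Hz must hold)")
    if len(hypnogram) < 1:
        raise ValueError("hypnogram must be non-empty")
    rng = np.random.default_rng(seed)
    n_epochs = len(hypnogram)
    duration = n_epochs * hypnogram.epoch_len_s
    n = int(round(duration * fs))
    t_norm = np.linspace(0.0, 1.0, n)

    c0, c1, c2 = profile.drift_coeffs
    signal = profile.tonic_level + c0 + c1 * t_norm + c2 * t_norm**2
    if profile.walk_sd > 0 and profile.noise_sd > 0:
        # slow tonic wander: heavily smoothed random walk
        walk = np.cumsum(rng.normal(0.0, profile.walk_sd, n))
        kernel = np.ones(int(fs * 5)) / int(fs * 5)
        walk = np.convolve(walk, kernel, mode="same")
        signal = signal + walk

    occupied: list[tuple[float, float]] = []
    events: list[tuple[float, float, str, np.ndarray]] = []

    # storm episodes: density coupled to OSA severity
    storm_intervals: list[tuple[float, float]] = []
    storms_per_hour = 0.5 + 0.25 * min(profile.ahi, 30.0)
    n_storms = rng.poisson(storms_per_hour * duration / 3600.0)
    for _ in range(n_storms):
        span = rng.uniform(60.0, 120.0)
        if span >= duration - 1:
            continue
        s0 = rng.uniform(0.0, duration - span)
        s1 = s0 + span
        if any(s1 > a and s0 < b for a, b in storm_intervals):
            continue
        burst = profile.storm_burst_rate * span / 60.0
        n_ev = max(2, int(rng.poisson(burst)))
        placed = _place_events(
            rng, [(s0, s1)], n_ev, occupied, fs, profile.event_amp_range
        )
        if len(placed) >= 2:
            storm_intervals.append((s0, s1))
            events.extend(placed)
        else:
            for p in placed:
                occupied.remove((p[0], p[1]))

    # stage-driven events outside storms
    epoch_starts = np.arange(n_epochs) * float(hypnogram.epoch_len_s)
    for k, stage in enumerate(hypnogram.epoch_stage):
        rate = profile.stage_event_rate.get(stage, 0.0)
        lam = rate * hypnogram.epoch_len_s / 60.0
        if lam <= 0:
            continue
        n_ev = rng.poisson(lam)
        if n_ev == 0:
            continue
        e0 = epoch_starts[k]
        e1 = e0 + hypnogram.epoch_len_s
        events.extend(
            _place_events(
                rng,
                [(e0, e1)],
                n_ev,
                occupied,
                fs,
                profile.event_amp_range,
                freq_range=profile.stage_freq_range.get(stage, (0.25, 3.0)),
                amp_scale=profile.stage_amp_scale.get(stage, 1.0),
            )
        )

    for onset, _offset, _kind, wave in events:
        i0 = int(round(onset * fs))
        wave = wave * profile.amp_scale
        signal[i0 : i0 + len(wave)] += wave[: max(0, n - i0)]

    # movement artifacts: rectangular out-of-scale spikes
    n_art = rng.poisson(profile.artifact_rate * duration / 3600.0)
    for _ in range(n_art):
        dur = rng.uniform(0.5, 2.0)
        a0 = rng.uniform(0.0, max(duration - dur, 0.0))
        i0 = int(round(a0 * fs))
        i1 = min(int(round((a0 + dur) * fs)), n)
        signal[i0:i1] += rng.choice([-1.0, 1.0]) * rng.uniform(5.0, 8.0) * abs(
            profile.tonic_level
        )

    if profile.noise_sd > 0:
        signal = signal + rng.normal(0.0, profile.noise_sd, n)

    event_intervals = tuple(
        sorted((on, off, kind) for on, off, kind, _ in events)
    )
    gt = GroundTruth(
        event_intervals=event_intervals,
        storm_intervals=tuple(sorted(storm_intervals)),
    )
    rec = RawRecording(
        subject_id=profile.subject_id,
        signal=signal,
        fs=fs,
        hypnogram=hypnogram,
        sex=profile.sex,
        ahi=profile.ahi,
        odi=profile.odi,
    )
    return rec, gt


def planted_event_trace(
    n_events: int = 50,
    spacing_s: float = 30.0,
    fs: float = 200.0,
    amp_range: tuple[float, float] = (1.5, 4.5),
    freq_range: tuple[float, float] = (0.25, 3.0),
    noise_sd: float = 0.02,
    baseline: float = 10.0,
    seed: int = 0,
) -> tuple[np.ndarray, GroundTruth]:
    """A flat trace with well-separated planted events at known onsets.

    One event is centred in each consecutive ``spacing_s`` window, so
    events never crowd each other; amplitudes and carrier frequencies
    are drawn uniformly (amplitudes log-uniformly) from the given
    ranges.  The ground truth is the oracle for detector-recovery
    tests.
    """
    rng = np.random.default_rng(seed)
    duration = (n_events + 1) * spacing_s
    n = int(round(duration * fs))
    x = np.full(n, baseline)
    intervals = []
    for k in range(n_events):
        kind = EVENT_KINDS[rng.integers(0, 4)]
        freq = rng.uniform(*freq_range)
        amp = float(np.exp(rng.uniform(np.log(amp_range[0]), np.log(amp_range[1]))))
        sign = -1 if kind == "mono-" else 1
        wave = _event_waveform(kind, freq, amp, fs, sign)
        center = (k + 1) * spacing_s
        onset = center - len(wave) / fs / 2
        i0 = int(round(onset * fs))
        x[i0 : i0 + len(wave)] += wave
        intervals.append((onset, onset + len(wave) / fs, kind))
    if noise_sd > 0:
        x = x + rng.normal(0.0, noise_sd, n)
    return x, GroundTruth(tuple(sorted(intervals)), ())


# --- cohort scenarios ------------------------------------------------------

#: Default long-run stage mix: W, N1, N2, N3, REM.
DEFAULT_STAGE_MIX = (0.122, 0.165, 0.325, 0.182, 0.206)

#: Strongly stage-dependent phasic-event rates (events/min): sparse in
#: wake, dense in slow-wave sleep, intermediate in REM.
STRONG_STAGE_RATES = {"W": 0.2, "N1": 1.0, "N2": 4.0, "N3": 12.0, "REM": 6.0}

#: Stage-dependent event character of the strong-signal scenario: slow,
#: large fluctuations in slow-wave sleep, faster and smaller events
#: towards REM — so stages differ in spectral content and amplitude,
#: not only in count.
STRONG_STAGE_FREQS = {
    "W": (0.25, 3.0),
    "N1": (1.2, 2.4),
    "N2": (0.6, 1.5),
    "N3": (0.25, 0.7),
    "REM": (1.8, 3.0),
}
STRONG_STAGE_AMPS = {"W": 1.0, "N1": 0.7, "N2": 1.0, "N3": 1.8, "REM": 0.8}

#: Sparse background event rates (events/min) for storm-oriented
#: simulation: the "two events per minute" storm criterion saturates
#: once background events approach 2/min, so apnoea-storm analyses keep
#: events outside storms rare.
SPARSE_STAGE_RATES = {"W": 0.05, "N1": 0.1, "N2": 0.3, "N3": 0.8, "REM": 0.5}


def osa_scenario(n_epochs: int = 60) -> Scenario:
    """Scenario for storm/OSA analyses: sparse stage-driven background
    events so that detected storms reflect the planted, AHI-coupled
    storm episodes rather than dense tonic event activity."""
    return Scenario(
        n_epochs=n_epochs,
        stage_event_rate=dict(SPARSE_STAGE_RATES),
        stage_freq_range={},
        stage_amp_scale={},
    )


@dataclass(frozen=True)
class Scenario:
    """Cohort-level generative settings.

    ``ahi_strata`` gives the (low, high) AHI range of each severity
    stratum (non-OSA, mild, moderate-severe); subjects cycle through the
    strata.  ``null_stages=True`` removes all stage dependence of the
    event rate, producing a cohort with no stage signal (the negative
    control for the classifiers).
    """

    n_epochs: int = 120
    stage_mix: tuple[float, ...] = DEFAULT_STAGE_MIX
    stage_event_rate: dict[str, float] = field(
        default_factory=lambda: dict(STRONG_STAGE_RATES)
    )
    stage_freq_range: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(STRONG_STAGE_FREQS)
    )
    stage_amp_scale: dict[str, float] = field(
        default_factory=lambda: dict(STRONG_STAGE_AMPS)
    )
    ahi_strata: tuple[tuple[float, float], ...] = ((0.5, 4.5), (5.0, 14.5), (15.0, 35.0))
    null_stages: bool = False
    noise_sd: float = 0.1
    artifact_rate: float = 2.0
    fs: float = 200.0
    subject_variability: float = 0.3


def _null_rates(rates: dict[str, float]) -> dict[str, float]:
    mean_rate = float(np.mean(list(rates.values())))
    return {s: mean_rate for s in STAGES}


def generate_cohort(
    n_subjects: int,
    scenario: Scenario | None = None,
    seed: int = 0,
) -> list[tuple[RawRecording, GroundTruth]]:
    """Generate a cohort of synthetic nights.

    Per-subject seeds are spawned deterministically from the master seed,
    so the same (n_subjects, scenario, seed) triple always yields a
    byte-identical cohort.  Subject AHI values cycle through the
    scenario's three severity strata; ODI tracks AHI with multiplicative
    jitter.  Per-subject tonic level, event-amplitude scale and noise
    vary (controlled by ``scenario.subject_variability``) to emulate
    inter-individual differences in sweating patterns.
    """
    if n_subjects < 2:
        raise ValueError("n_subjects must be >= 2 (leave-one-subject-out needs >= 2)")
    scenario = scenario or Scenario()
    if scenario.null_stages:
        rates = _null_rates(scenario.stage_event_rate)
        freqs: dict[str, tuple[float, float]] = {}
        amps: dict[str, float] = {}
    else:
        rates = scenario.stage_event_rate
        freqs = scenario.stage_freq_range
        amps = scenario.stage_amp_scale
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_subjects)
    cohort = []
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        stratum = scenario.ahi_strata[i % len(scenario.ahi_strata)]
        ahi = float(rng.uniform(*stratum))
        odi = float(max(0.0, ahi * rng.uniform(0.8, 1.1)))
        v = scenario.subject_variability
        profile = SubjectProfile(
            subject_id=f"S{i:03d}",
            sex="F" if rng.random() < 0.5 else "M",
            ahi=ahi,
            odi=odi,
            tonic_level=float(10.0 * (1.0 + v * rng.uniform(-1, 1))),
            drift_coeffs=(
                float(rng.uniform(-1, 1)),
                float(rng.uniform(-2, 2)),
                float(rng.uniform(-1, 1)),
            ),
            stage_event_rate=dict(rates),
            stage_freq_range=dict(freqs),
            stage_amp_scale=dict(amps),
            artifact_rate=scenario.artifact_rate,
            noise_sd=float(scenario.noise_sd * (1.0 + v * rng.uniform(-0.5, 1.0))),
            amp_scale=float(1.0 + v * rng.uniform(-0.5, 1.0)),
        )
        hyp_seed = int(rng.integers(0, 2**31 - 1))
        rec_seed = int(rng.integers(0, 2**31 - 1))
        hyp = generate_hypnogram(
            scenario.n_epochs, tuple(scenario.stage_mix), seed=hyp_seed
        )
        cohort.append(generate_recording(hyp, profile, fs=scenario.fs, seed=rec_seed))
    return cohort
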