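"""File formats and run configuration.

Signals travel as EDF (one EDA channel); all tabular sidecars are plain
CSV: the hypnogram (epoch_index, stage), the subject table (subject_id,
sex, ahi, odi), ground-truth/event/storm interval tables, feature
matrices and fold predictions.  Reports serialise to JSON and run
configuration to YAML.

The EDF writer is a minimal single-channel implementation of the
standard (ASCII header, 1 s data records of little-endian 16-bit
integers, physical range mapped to the full digital range); reading
goes through ``mne.io.read_raw_edf``, which doubles as an independent
check on the writer.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .synth import GroundTruth, Hypnogram, RawRecording

__all__ = [
    "write_edf",
    "read_edf",
    "write_recording",
    "read_recording",
    "write_ground_truth",
    "read_ground_truth",
    "RunConfig",
]


def _ascii(value, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def _num(value: float, width: int = 8) -> bytes:
    return _ascii(f"{value:.8g}"[:width], width)


def write_edf(
    path,
    x: np.ndarray,
    fs: float,
    label: str = "EDA",
    physical_dim: str = "uV",
    patient: str = "X",
    recording_id: str = "edasleep",
) -> None:
    """Write one channel to an EDF file with 1 s data records.

    The physical range is mapped onto the full 16-bit digital range, so
    the quantisation step is (max - min) / 65535.  The trailing partial
    record, if any, is padded by repeating the last sample.
    """
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("cannot write an empty signal")
    if not np.isclose(fs, round(fs)):
        raise ValueError("EDF records of 1 s require an integer sampling rate")
    spr = int(round(fs))
    nrec = int(np.ceil(x.size / spr))
    pad = nrec * spr - x.size
    xp = np.concatenate([x, np.full(pad, x[-1])]) if pad else x
    pmin, pmax = float(xp.min()), float(xp.max())
    if pmax <= pmin:
        pmax = pmin + 1.0
    dmin, dmax = -32768, 32767
    scale = (pmax - pmin) / (dmax - dmin)
    digital = np.clip(np.round((xp - pmin) / scale + dmin), dmin, dmax).astype("<i2")
    header = b"".join(
        [
            _ascii("0", 8),
            _ascii(patient, 80),
            _ascii(recording_id, 80),
            _ascii("01.01.20", 8),
            _ascii("00.00.00", 8),
            _ascii(256 + 256, 8),  # header bytes: fixed + one signal block
            _ascii("", 44),
            _ascii(nrec, 8),
            _ascii("1", 8),  # record duration, seconds
            _ascii("1", 4),  # number of signals
        ]
    )
    signal_header = b"".join(
        [
            _ascii(label, 16),
            _ascii("", 80),  # transducer
            _ascii(physical_dim, 8),
            _num(pmin),
            _num(pmax),
            _num(dmin),
            _num(dmax),
            _ascii("", 80),  # prefiltering
            _ascii(spr, 8),
            _ascii("", 32),
        ]
    )
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(signal_header)
        fh.write(digital.tobytes())


def read_edf(path, channel_hint: str = "EDA") -> tuple[np.ndarray, float]:
    """Read the single EDA channel of an EDF file.

    Returns (trace in the file's physical units, sampling rate).  A
    file with no — or more than one — channel whose label contains the
    hint is rejected.
    """
    import mne

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    except Exception as exc:
        raise ValueError(f"not a readable EDF file: {path} ({exc})") from exc
    matches = [ch for ch in raw.ch_names if channel_hint.lower() in ch.lower()]
    if len(matches) == 0:
        raise ValueError(f"no channel labelled like {channel_hint!r} in {path}")
    if len(matches) > 1:
        raise ValueError(
            f"ambiguous: {len(matches)} channels labelled like {channel_hint!r}"
        )
    data = raw.get_data(picks=matches)[0]
    # mne rescales recognised physical dimensions to SI units; undo it so
    # the caller sees the file's own physical units.
    unit = getattr(raw, "_orig_units", {}).get(matches[0], "")
    factor = {"uV": 1e6, "µV": 1e6, "mV": 1e3, "V": 1.0}.get(unit, 1.0)
    return data * factor, float(raw.info["sfreq"])


# --- recording + sidecars --------------------------------------------------


def write_recording(directory, rec: RawRecording, gt: GroundTruth | None = None) -> None:
    """Write one night as EDF plus CSV sidecars into ``directory``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    sid = rec.subject_id
    write_edf(directory / f"{sid}.edf", rec.signal, rec.fs, patient=sid)
    pd.DataFrame(
        {
            "epoch_index": range(len(rec.hypnogram)),
            "stage": list(rec.hypnogram.epoch_stage),
        }
    ).to_csv(directory / f"{sid}_hypnogram.csv", index=False)
    pd.DataFrame(
        [{"subject_id": sid, "sex": rec.sex, "ahi": rec.ahi, "odi": rec.odi}]
    ).to_csv(directory / f"{sid}_subject.csv", index=False)
    if gt is not None:
        write_ground_truth(directory / f"{sid}_truth.csv", gt)


def read_recording(directory, subject_id: str) -> RawRecording:
    """Read a night written by :func:`write_recording`."""
    directory = Path(directory)
    signal, fs = read_edf(directory / f"{subject_id}.edf")
    hyp = pd.read_csv(directory / f"{subject_id}_hypnogram.csv")
    subj = pd.read_csv(directory / f"{subject_id}_subject.csv").iloc[0]
    return RawRecording(
        subject_id=subject_id,
        signal=signal,
        fs=fs,
        hypnogram=Hypnogram(tuple(hyp["stage"])),
        sex=str(subj["sex"]),
        ahi=float(subj["ahi"]),
        odi=float(subj["odi"]),
    )


def write_ground_truth(path, gt: GroundTruth) -> None:
    rows = [
        {"onset_s": a, "offset_s": b, "kind": k} for a, b, k in gt.event_intervals
    ] + [{"onset_s": a, "offset_s": b, "kind": "storm"} for a, b in gt.storm_intervals]
    pd.DataFrame(rows, columns=["onset_s", "offset_s", "kind"]).to_csv(
        path, index=False
    )


def read_ground_truth(path) -> GroundTruth:
    df = pd.read_csv(path)
    events = tuple(
        sorted(
            (r.onset_s, r.offset_s, r.kind)
            for r in df.itertuples()
            if r.kind != "storm"
        )
    )
    storms = tuple(
        sorted((r.onset_s, r.offset_s) for r in df.itertuples() if r.kind == "storm")
    )
    return GroundTruth(event_intervals=events, storm_intervals=storms)


# --- run configuration -----------------------------------------------------


@dataclass
class RunConfig:
    """One experiment: generation, detection, reduction, model, task.

    Round-trips losslessly through YAML; the master seed is mandatory
    and feeds every random substream (cohort, SMOTE, model,
    personalisation) downstream.
    """

    seed: int
    task: str = "stage4"
    mode: str = "loso"  # loso | personalized
    n_subjects: int = 10
    n_epochs: int = 120
    amp_threshold: float = 0.5
    r_th: float = 0.8
    personal_frac: float = 0.25
    scenario: str = "strong"  # strong | null
    hyperparams: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "seed" not in raw:
            raise KeyError("config is missing the mandatory key 'seed'")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise KeyError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


def write_json(path, payload: dict) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
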