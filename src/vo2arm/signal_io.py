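"""Reading, validation, writing and time-alignment of armband sensor streams.

A recording bundles four uniformly sampled streams from one subject:

* ``emg``   — 8-channel surface EMG, 200 Hz, signed 8-bit integers in [-128, 127]
* ``accel`` — 3-axis accelerometer, 50 Hz, units of g
* ``gyro``  — 3-axis gyroscope, 50 Hz, deg/s
* ``vo2``   — reference oxygen uptake, 1 Hz, mL·kg⁻¹·min⁻¹

Streams are stored as plain CSV (header row, first column ``t`` in seconds
from recording start, six decimal places) so recordings are diff-able and
language neutral.  Windows downstream are half-open ``[k, k+1)`` seconds,
0-based, which makes per-second sample counts exact at the nominal rates.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

__all__ = [
    "ChannelStream",
    "SensorRecording",
    "load_recording",
    "write_recording",
    "trim_to_overlap",
    "write_manifest",
    "load_manifest",
]

EMG_MIN, EMG_MAX = -128, 127

#: expected channel widths per modality
_WIDTHS = {"emg": 8, "accel": 3, "gyro": 3, "vo2": 1}
_RATES = {"emg": 200.0, "accel": 50.0, "gyro": 50.0, "vo2": 1.0}
_HEADERS = {
    "emg": [f"emg{i}" for i in range(1, 9)],
    "accel": ["ax", "ay", "az"],
    "gyro": ["gx", "gy", "gz"],
    "vo2": ["vo2"],
}


@dataclass
class ChannelStream:
    """One uniformly sampled stream: ``values[i]`` is the sample at ``t0 + i/rate``."""

    name: str
    rate: float
    t0: float
    values: np.ndarray  # shape (n_samples, width)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim == 1:
            self.values = self.values[:, None]
        if self.rate <= 0:
            raise ValueError(f"stream {self.name!r}: rate must be > 0, got {self.rate}")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def width(self) -> int:
        return self.values.shape[1]

    @property
    def span(self) -> tuple[float, float]:
        """Closed-open time span [t0, t0 + n/rate) covered by the samples."""
        return (self.t0, self.t0 + self.n_samples / self.rate)

    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) / self.rate


@dataclass
class SensorRecording:
    """One subject's synchronized raw streams plus body mass and optional labels."""

    subject_id: str
    mass: float  # kg
    emg: ChannelStream
    accel: ChannelStream
    gyro: ChannelStream
    vo2: ChannelStream
    labels: np.ndarray | None = None  # per-second activity tags
    vo2_truth: np.ndarray | None = None  # noiseless ground truth, simulation only

    def __post_init__(self) -> None:
        if self.mass <= 0:
            raise ValueError(f"mass must be > 0 kg, got {self.mass}")

    def streams(self) -> dict[str, ChannelStream]:
        return {"emg": self.emg, "accel": self.accel, "gyro": self.gyro, "vo2": self.vo2}


def _validate_stream(stream: ChannelStream, modality: str) -> None:
    width = _WIDTHS[modality]
    if stream.width != width:
        raise ValueError(
            f"{modality} stream must have {width} channels, got {stream.width}"
        )
    if modality == "emg":
        vals = stream.values
        bad = np.argwhere((vals < EMG_MIN) | (vals > EMG_MAX))
        if bad.size:
            i, j = bad[0]
            raise ValueError(
                f"EMG value {vals[i, j]} at sample {i} channel {j} outside "
                f"[{EMG_MIN}, {EMG_MAX}]"
            )
        if not np.all(vals == np.round(vals)):
            i = int(np.argwhere(vals != np.round(vals))[0][0])
            raise ValueError(f"EMG values must be integers (sample {i})")


def _check_uniform(t: np.ndarray, rate: float, name: str, jitter_tol: float = 0.01) -> None:
    """Timestamps must be strictly increasing and uniform to within 1% of 1/rate."""
    if len(t) < 2:
        return
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise ValueError(f"{name}: timestamps not strictly increasing")
    nominal = 1.0 / rate
    if np.max(np.abs(dt - nominal)) > jitter_tol * nominal:
        raise ValueError(
            f"{name}: non-uniform sampling (jitter beyond {jitter_tol:.0%} of 1/{rate} s)"
        )


# ---------------------------------------------------------------------------
# CSV round-trip


def _write_stream(stream: ChannelStream, modality: str, path: Path) -> None:
    header = ["t"] + _HEADERS[modality]
    t = stream.times()
    is_int = modality == "emg"
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(header)
        for i in range(stream.n_samples):
            row = [f"{t[i]:.6f}"]
            if is_int:
                row += [str(int(v)) for v in stream.values[i]]
            else:
                row += [f"{v:.12g}" for v in stream.values[i]]
            writer.writerow(row)


def _read_stream(path: Path, modality: str) -> ChannelStream:
    import pandas as pd

    df = pd.read_csv(path)
    expected_cols = ["t"] + _HEADERS[modality]
    if list(df.columns) != expected_cols:
        raise ValueError(f"{path}: expected columns {expected_cols}, got {list(df.columns)}")
    t = df["t"].to_numpy(float)
    if len(t) == 0:
        raise ValueError(f"{path}: empty stream")
    rate = _RATES[modality]
    _check_uniform(t, rate, path.name)
    values = df[_HEADERS[modality]].to_numpy()
    stream = ChannelStream(name=modality, rate=rate, t0=float(t[0]), values=values)
    _validate_stream(stream, modality)
    return stream


def write_recording(rec: SensorRecording, outdir: str | Path) -> Path:
    """Write one recording's four streams (plus any ground truth) as CSV files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for modality, stream in rec.streams().items():
        _write_stream(stream, modality, outdir / f"{modality}.csv")
    if rec.vo2_truth is not None:
        with open(outdir / "vo2_truth.csv", "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["t", "vo2_truth"])
            t = rec.vo2.times()
            for i, v in enumerate(np.asarray(rec.vo2_truth).ravel()):
                writer.writerow([f"{t[i]:.6f}", f"{v:.12g}"])
    if rec.labels is not None:
        with open(outdir / "labels.csv", "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["second", "label"])
            for i, lab in enumerate(rec.labels):
                writer.writerow([i, lab])
    return outdir


def load_recording(entry: dict | str | Path) -> SensorRecording:
    """Load and validate a recording from a manifest entry or its directory.

    ``entry`` may be a directory path (subject id and mass read from
    ``meta.csv`` inside it) or a manifest entry dict with keys
    ``subject_id``, ``mass``, ``dir``.
    """
    if isinstance(entry, (str, Path)):
        d = Path(entry)
        meta = _read_meta(d / "meta.csv")
        subject_id, mass = meta["subject_id"], float(meta["mass"])
    else:
        d = Path(entry["dir"])
        subject_id, mass = str(entry["subject_id"]), float(entry["mass"])
    streams = {}
    for modality in _WIDTHS:
        path = d / f"{modality}.csv"
        if not path.exists():
            raise FileNotFoundError(f"manifest error: missing {modality} stream at {path}")
        streams[modality] = _read_stream(path, modality)
    vo2_truth = None
    truth_path = d / "vo2_truth.csv"
    if truth_path.exists():
        import pandas as pd

        vo2_truth = pd.read_csv(truth_path)["vo2_truth"].to_numpy(float)
    labels = None
    labels_path = d / "labels.csv"
    if labels_path.exists():
        import pandas as pd

        labels = pd.read_csv(labels_path)["label"].to_numpy()
    return SensorRecording(
        subject_id=subject_id,
        mass=mass,
        emg=streams["emg"],
        accel=streams["accel"],
        gyro=streams["gyro"],
        vo2=streams["vo2"],
        labels=labels,
        vo2_truth=vo2_truth,
    )


def _read_meta(path: Path) -> dict:
    meta = {}
    with open(path) as fh:
        for row in csv.reader(fh):
            if len(row) == 2:
                meta[row[0]] = row[1]
    return meta


def _write_meta(rec: SensorRecording, path: Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["subject_id", rec.subject_id])
        writer.writerow(["mass", f"{rec.mass:.12g}"])


# ---------------------------------------------------------------------------
# Alignment


def trim_to_overlap(rec: SensorRecording) -> SensorRecording:
    """Cut all four streams to the intersection of their spans, whole seconds.

    The common span is truncated to ``floor`` whole seconds so an integer
    number of 1 s windows exists; each stream then contributes exactly
    ``span × rate`` samples.
    """
    spans = {m: s.span for m, s in rec.streams().items()}
    lo = max(s[0] for s in spans.values())
    hi = min(s[1] for s in spans.values())
    n_sec = math.floor(hi - lo + 1e-9)
    if n_sec <= 0:
        raise ValueError(
            f"streams have no whole-second overlap (intersection [{lo}, {hi}])"
        )
    new_streams = {}
    for modality, stream in rec.streams().items():
        start = int(round((lo - stream.t0) * stream.rate))
        count = int(round(n_sec * stream.rate))
        if start < 0 or start + count > stream.n_samples:
            raise ValueError(f"{modality}: overlap window outside stream extent")
        new_streams[modality] = ChannelStream(
            name=stream.name,
            rate=stream.rate,
            t0=lo,
            values=stream.values[start : start + count],
        )
    vo2_truth = rec.vo2_truth
    if vo2_truth is not None:
        start = int(round((lo - rec.vo2.t0) * rec.vo2.rate))
        vo2_truth = np.asarray(vo2_truth)[start : start + n_sec]
    labels = rec.labels
    if labels is not None:
        start = int(round((lo - rec.vo2.t0) * rec.vo2.rate))
        labels = np.asarray(labels)[start : start + n_sec]
    return replace(
        rec,
        emg=new_streams["emg"],
        accel=new_streams["accel"],
        gyro=new_streams["gyro"],
        vo2=new_streams["vo2"],
        labels=labels,
        vo2_truth=vo2_truth,
    )


# ---------------------------------------------------------------------------
# Cohort manifest (plain-text key-value)


def write_manifest(
    recordings: list[SensorRecording], root: str | Path, seed: int | None = None
) -> Path:
    """Write each recording to ``root/<subject_id>/`` and a cohort manifest."""
    root = Path(root)
    root.mkdir(parents=True, exist_ok=True)
    manifest = root / "manifest.txt"
    with open(manifest, "w") as fh:
        if seed is not None:
            fh.write(f"seed {seed}\n")
        for rec in recordings:
            d = root / rec.subject_id
            write_recording(rec, d)
            _write_meta(rec, d / "meta.csv")
            fh.write(f"subject {rec.subject_id} mass {rec.mass:.12g} dir {d}\n")
    return manifest


def load_manifest(manifest: str | Path) -> list[dict]:
    """Parse a cohort manifest into entry dicts consumable by load_recording."""
    entries = []
    with open(manifest) as fh:
        for line in fh:
            parts = line.split()
            if not parts or parts[0] != "subject":
                continue
            if len(parts) != 6 or parts[2] != "mass" or parts[4] != "dir":
                raise ValueError(f"malformed manifest line: {line.rstrip()}")
            entries.append(
                {"subject_id": parts[1], "mass": float(parts[3]), "dir": parts[5]}
            )
    if not entries:
        raise ValueError(f"manifest {manifest} lists no subjects")
    return entries


def load_cohort(manifest: str | Path) -> list[SensorRecording]:
    return [load_recording(e) for e in load_manifest(manifest)]
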