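"""On-disk CSV formats for chest-patch recordings, with strict validation.

Three plain-text dialects are used throughout the package:

* acceleration: ``time_s,x_g,y_g,z_g`` — triaxial acceleration in g,
  time in seconds from recording start;
* interval labels: ``start_s,end_s,activity`` — non-overlapping activity
  intervals drawn from a closed vocabulary;
* heart rate: ``time_s,hr_bpm`` — the device's 1 Hz heart-rate stream.

Each file may start with an optional comment line ``# subject_id=<id>``;
otherwise the subject id is taken from the filename stem (with a trailing
``_accel``/``_labels``/``_hr`` suffix stripped).

Acceleration is stored in g because the cut-point thresholds used by the
classifiers (0.07 g, 0.04773 g) are only interpretable on that scale.
Readers can divide by 9.80665 on ingest for data recorded in m/s².
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

#: The five mutually exclusive activity states, in canonical order.
ACTIVITY_CLASSES = ("lying", "sitting", "standing", "walking", "jogging")

#: Marker labels for segments excluded from classification.
SPECIAL_LABELS = ("transition", "interference")

ALL_LABELS = ACTIVITY_CLASSES + SPECIAL_LABELS

#: Sampling rates the reader snaps to when the estimate is within 2%.
STANDARD_RATES_HZ = (5.0, 10.0, 25.0, 50.0, 100.0, 128.0)

G_TO_MS2 = 9.80665


class ValidationError(ValueError):
    """Raised when an input file or record violates a format invariant."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class AccelRecording:
    """One subject's triaxial acceleration series.

    Attributes
    ----------
    subject_id : str
    sampling_rate_hz : float
        Nominal rate; 50 Hz for the chest patch.
    t : ndarray
        Seconds from recording start, strictly increasing.
    x, y, z : ndarray
        Per-axis acceleration in g, same length as ``t``.
    """

    subject_id: str
    sampling_rate_hz: float
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    z: np.ndarray

    @property
    def n_samples(self) -> int:
        return len(self.t)

    @property
    def duration_s(self) -> float:
        return float(self.t[-1] - self.t[0])

    def axes(self) -> np.ndarray:
        """Stack the three axes into an (n, 3) array (x, y, z order)."""
        return np.column_stack([self.x, self.y, self.z])

    def validate(self) -> "AccelRecording":
        n = len(self.t)
        if not (len(self.x) == len(self.y) == len(self.z) == n):
            raise ValidationError("axis arrays and time must have equal length")
        if n < 2:
            raise ValidationError("recording must contain at least 2 samples")
        if self.sampling_rate_hz <= 0:
            raise ValidationError("sampling_rate_hz must be positive")
        dt = np.diff(self.t)
        bad = np.nonzero(dt <= 0)[0]
        if bad.size:
            raise ValidationError(f"non-monotone time at row {bad[0] + 2}")
        for name, a in (("time_s", self.t), ("x_g", self.x), ("y_g", self.y), ("z_g", self.z)):
            nf = np.nonzero(~np.isfinite(a))[0]
            if nf.size:
                raise ValidationError(f"non-finite {name} at row {nf[0] + 1}")
        med = float(np.median(dt))
        if abs(med - 1.0 / self.sampling_rate_hz) > 0.1 / self.sampling_rate_hz:
            raise ValidationError(
                f"median sample interval {med:.6f}s inconsistent with "
                f"sampling_rate_hz={self.sampling_rate_hz}"
            )
        return self

    def replace_axes(self, xyz: np.ndarray) -> "AccelRecording":
        """New recording with the same time base and the given (n, 3) axes."""
        return AccelRecording(
            subject_id=self.subject_id,
            sampling_rate_hz=self.sampling_rate_hz,
            t=self.t,
            x=np.asarray(xyz[:, 0], dtype=float),
            y=np.asarray(xyz[:, 1], dtype=float),
            z=np.asarray(xyz[:, 2], dtype=float),
        )


@dataclass
class LabelTrack:
    """Ordered, non-overlapping activity intervals for one subject."""

    subject_id: str
    intervals: list  # of (start_s, end_s, activity)

    def validate(self) -> "LabelTrack":
        prev = None
        for iv in self.intervals:
            s, e, a = iv
            if a not in ALL_LABELS:
                raise ValidationError(f"unknown activity {a!r}")
            if not (s < e):
                raise ValidationError(f"empty or inverted interval ({s}, {e}, {a})")
            if prev is not None and s < prev[1]:
                raise ValidationError(f"overlapping intervals {prev} and {(s, e, a)}")
            prev = (s, e, a)
        return self

    def first_walking_start(self) -> float | None:
        for s, _e, a in self.intervals:
            if a == "walking":
                return s
        return None

    def clip(self, t0: float, t1: float) -> "LabelTrack":
        """Intersect every interval with [t0, t1]; drop the empty ones."""
        out = []
        for s, e, a in self.intervals:
            s2, e2 = max(s, t0), min(e, t1)
            if s2 < e2:
                out.append((s2, e2, a))
        return LabelTrack(self.subject_id, out)

    def as_arrays(self):
        starts = np.array([iv[0] for iv in self.intervals], dtype=float)
        ends = np.array([iv[1] for iv in self.intervals], dtype=float)
        acts = np.array([iv[2] for iv in self.intervals], dtype=object)
        return starts, ends, acts


@dataclass
class HeartRateSeries:
    """Device-computed heart rate at a nominal 1 Hz."""

    subject_id: str
    t: np.ndarray
    hr_bpm: np.ndarray

    def validate(self) -> "HeartRateSeries":
        if len(self.t) == 0:
            raise ValidationError("no samples")
        if len(self.t) != len(self.hr_bpm):
            raise ValidationError("time and hr_bpm must have equal length")
        if np.any(np.diff(self.t) <= 0):
            bad = int(np.nonzero(np.diff(self.t) <= 0)[0][0])
            raise ValidationError(f"non-monotone time at row {bad + 2}")
        bad = np.nonzero(~(np.isfinite(self.hr_bpm) & (self.hr_bpm > 0)))[0]
        if bad.size:
            raise ValidationError(f"invalid hr_bpm at row {bad[0] + 1}")
        return self


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def _subject_from_path(path: os.PathLike, kind: str) -> str:
    stem = Path(path).stem
    suffix = f"_{kind}"
    return stem[: -len(suffix)] if stem.endswith(suffix) else stem


def _read_header_meta(path: os.PathLike) -> dict:
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line.lstrip("#").strip()
            if "=" in body:
                k, v = body.split("=", 1)
                meta[k.strip()] = v.strip()
    return meta

def _read_csv(path, columns) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, comment="#")
    except pd.errors.EmptyDataError:
        raise ValidationError("no samples") from None
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValidationError(f"missing columns {missing} in {path}")
    return df


def estimate_sampling_rate(t: np.ndarray) -> float:
    """1/median(diff), snapped to a standard rate when within 2%."""
    est = 1.0 / float(np.median(np.diff(t)))
    for r in STANDARD_RATES_HZ:
        if abs(est - r) / r <= 0.02:
            return r
    return est


def read_accel(path: os.PathLike, units: str = "g") -> AccelRecording:
    """Read an acceleration CSV and validate it.

    Parameters
    ----------
    path : path to a ``time_s,x_g,y_g,z_g`` CSV.
    units : "g" (default) or "m/s2"; the latter divides by 9.80665 on ingest.
    """
    meta = _read_header_meta(path)
    df = _read_csv(path, ("time_s", "x_g", "y_g", "z_g"))
    if len(df) < 2:
        raise ValidationError("recording must contain at least 2 samples")
    scale = 1.0 / G_TO_MS2 if units == "m/s2" else 1.0
    t = df["time_s"].to_numpy(dtype=float)
    rec = AccelRecording(
        subject_id=meta.get("subject_id", _subject_from_path(path, "accel")),
        sampling_rate_hz=estimate_sampling_rate(t),
        t=t,
        x=df["x_g"].to_numpy(dtype=float) * scale,
        y=df["y_g"].to_numpy(dtype=float) * scale,
        z=df["z_g"].to_numpy(dtype=float) * scale,
    )
    return rec.validate()


def read_labels(path: os.PathLike) -> LabelTrack:
    """Read an interval-label CSV; activities are matched case-insensitively."""
    meta = _read_header_meta(path)
    df = _read_csv(path, ("start_s", "end_s", "activity"))
    intervals = []
    for _, row in df.iterrows():
        act = str(row["activity"]).strip().lower()
        if act not in ALL_LABELS:
            raise ValidationError(f"unknown activity {row['activity']!r}")
        intervals.append((float(row["start_s"]), float(row["end_s"]), act))
    intervals.sort(key=lambda iv: iv[0])
    track = LabelTrack(meta.get("subject_id", _subject_from_path(path, "labels")), intervals)
    return track.validate()


def read_hr(path: os.PathLike) -> HeartRateSeries:
    """Read a 1 Hz heart-rate CSV."""
    meta = _read_header_meta(path)
    df = _read_csv(path, ("time_s", "hr_bpm"))
    if len(df) == 0:
        raise ValidationError("no samples")
    series = HeartRateSeries(
        subject_id=meta.get("subject_id", _subject_from_path(path, "hr")),
        t=df["time_s"].to_numpy(dtype=float),
        hr_bpm=df["hr_bpm"].to_numpy(dtype=float),
    )
    return series.validate()


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

_FLOAT_FMT = "%.9f"


def write_accel(recording: AccelRecording, path: os.PathLike) -> Path:
    recording.validate()
    path = Path(path)
    df = pd.DataFrame(
        {"time_s": recording.t, "x_g": recording.x, "y_g": recording.y, "z_g": recording.z}
    )
    with open(path, "w") as fh:
        fh.write(f"# subject_id={recording.subject_id}\n")
        df.to_csv(fh, index=False, float_format=_FLOAT_FMT)
    return path


def write_labels(track: LabelTrack, path: os.PathLike) -> Path:
    track.validate()
    path = Path(path)
    df = pd.DataFrame(track.intervals, columns=["start_s", "end_s", "activity"])
    with open(path, "w") as fh:
        fh.write(f"# subject_id={track.subject_id}\n")
        df.to_csv(fh, index=False, float_format=_FLOAT_FMT)
    return path


def write_hr(series: HeartRateSeries, path: os.PathLike) -> Path:
    series.validate()
    path = Path(path)
    df = pd.DataFrame({"time_s": series.t, "hr_bpm": series.hr_bpm})
    with open(path, "w") as fh:
        fh.write(f"# subject_id={series.subject_id}\n")
        df.to_csv(fh, index=False, float_format=_FLOAT_FMT)
    return path


# ---------------------------------------------------------------------------
# cohort directories
# ---------------------------------------------------------------------------


def read_cohort(directory: os.PathLike) -> dict:
    """Load every ``<sid>_accel.csv`` / ``_labels.csv`` / ``_hr.csv`` triple.

    Returns a mapping ``subject_id -> dict(recording=..., labels=..., hr=...)``;
    ``hr`` is None when the file is absent.
    """
    directory = Path(directory)
    cohort = {}
    for accel_path in sorted(directory.glob("*_accel.csv")):
        sid = accel_path.stem[: -len("_accel")]
        label_path = directory / f"{sid}_labels.csv"
        if not label_path.exists():
            raise ValidationError(f"missing label file for subject {sid}: {label_path}")
        hr_path = directory / f"{sid}_hr.csv"
        cohort[sid] = {
            "recording": read_accel(accel_path),
            "labels": read_labels(label_path),
            "hr": read_hr(hr_path) if hr_path.exists() else None,
        }
    if not cohort:
        raise ValidationError(f"no *_accel.csv files found in {directory}")
    return cohort
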