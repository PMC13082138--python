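"""Signal conditioning and windowing for chest-patch accelerometry.

The pipeline implemented here mirrors the acquisition protocol the package
targets: truncate each recording to its final 20 minutes (the structured
activity period), band-pass each axis with a 0.05–2 Hz Butterworth filter
(drift below, device/environment vibration above), optionally decimate to a
lower rate, derive the vector-magnitude intensity signal and its robust
rolling-median smoother, and cut fixed-duration labeled windows.

Window labeling follows a trailing-window, most-recent-activity rule: a
window ending at time t carries the activity of the interval covering its
final sample.  Windows that touch transition or interference segments, or
unlabeled gaps, are excluded from classification and tallied instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import signal

from .io_formats import (
    ACTIVITY_CLASSES,
    AccelRecording,
    LabelTrack,
    ValidationError,
)

log = logging.getLogger(__name__)

_EXCLUSION_KEYS = ("transition", "interference", "unlabeled")


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FilterSpec:
    """Butterworth band-pass specification.

    ``mode="zero_phase"`` applies forward-backward filtering (no phase delay,
    effective order doubled); ``mode="causal"`` is a single forward pass and
    is usable in streaming settings.
    """

    low_hz: float = 0.05
    high_hz: float = 2.0
    order: int = 4
    mode: str = "zero_phase"

    def validate(self, sampling_rate_hz: float) -> "FilterSpec":
        nyq = sampling_rate_hz / 2.0
        if not (0 <= self.low_hz < self.high_hz):
            raise ValidationError("need 0 <= low_hz < high_hz")
        if self.high_hz >= nyq:
            raise ValidationError(
                f"high_hz={self.high_hz} must be below the Nyquist frequency {nyq}"
            )
        if self.order < 1:
            raise ValidationError("order must be a positive integer")
        if self.mode not in ("causal", "zero_phase"):
            raise ValidationError(f"unknown filter mode {self.mode!r}")
        return self

    def sos(self, sampling_rate_hz: float) -> np.ndarray:
        if self.low_hz > 0:
            return signal.butter(
                self.order, [self.low_hz, self.high_hz], btype="bandpass",
                fs=sampling_rate_hz, output="sos",
            )
        return signal.butter(
            self.order, self.high_hz, btype="lowpass", fs=sampling_rate_hz, output="sos"
        )


def bandpass(recording: AccelRecording, spec: FilterSpec = FilterSpec()) -> AccelRecording:
    """Filter each axis independently with the given Butterworth band-pass."""
    spec.validate(recording.sampling_rate_hz)
    sos = spec.sos(recording.sampling_rate_hz)
    xyz = recording.axes()
    if spec.mode == "zero_phase":
        out = signal.sosfiltfilt(sos, xyz, axis=0)
    else:
        out = signal.sosfilt(sos, xyz, axis=0)
    return recording.replace_axes(np.asarray(out))


# ---------------------------------------------------------------------------
# magnitude and rolling statistics
# ---------------------------------------------------------------------------


@dataclass
class MagnitudeSeries:
    """Vector magnitude √(x²+y²+z²) of (filtered) axes, in g."""

    t: np.ndarray
    m: np.ndarray
    sampling_rate_hz: float

    def __len__(self) -> int:
        return len(self.m)


def magnitude(recording: AccelRecording) -> MagnitudeSeries:
    m = np.sqrt(recording.x**2 + recording.y**2 + recording.z**2)
    return MagnitudeSeries(t=recording.t, m=m, sampling_rate_hz=recording.sampling_rate_hz)


def window_samples(window_s: float, sampling_rate_hz: float) -> int:
    """Number of samples in a window: round(window_s * fs)."""
    return int(round(window_s * sampling_rate_hz))


def rolling_delay_samples(window_s: float, sampling_rate_hz: float) -> float:
    """Fixed delay (in samples) of the centered rolling statistic when it is
    consumed causally: (N - 1) / 2 for a width-N window."""
    return (window_samples(window_s, sampling_rate_hz) - 1) / 2.0


def nyquist_hz(sampling_rate_hz: float) -> float:
    return sampling_rate_hz / 2.0


def _centered_window_stat(values: np.ndarray, n: int, stat) -> np.ndarray:
    """Apply ``stat`` over centered width-n windows with truncated edges.

    The window at index i covers [i - (n-1)//2, i + n//2]; near the edges the
    available (shorter) window is used, down to a single sample.
    """
    values = np.asarray(values, dtype=float)
    left = (n - 1) // 2
    right = n // 2
    size = len(values)
    out = np.empty(size, dtype=float)
    n_full = size - n + 1
    if n_full > 0:
        out[left : left + n_full] = stat(sliding_window_view(values, n), axis=1)
    for i in range(min(left, size)):
        out[i] = stat(values[: min(i + right + 1, size)])
    for i in range(max(size - right, left if n_full > 0 else 0), size):
        out[i] = stat(values[max(i - left, 0) :])
    return out


def rolling_median(series: MagnitudeSeries, window_s: float = 5.0) -> MagnitudeSeries:
    """Centered rolling median of the magnitude; edges use truncated windows."""
    n = window_samples(window_s, series.sampling_rate_hz)
    if n < 3:
        raise ValidationError("rolling window must span at least 3 samples")
    out = _centered_window_stat(series.m, n, np.median)
    return MagnitudeSeries(t=series.t, m=out, sampling_rate_hz=series.sampling_rate_hz)


# ---------------------------------------------------------------------------
# truncation & resampling
# ---------------------------------------------------------------------------


def truncate_last(
    recording: AccelRecording, labels: LabelTrack, minutes: float = 20.0
) -> tuple[AccelRecording, LabelTrack]:
    """Keep only the final ``minutes`` of the recording (shorter ones pass through)."""
    budget = 60.0 * minutes
    t_end = float(recording.t[-1])
    t_cut = t_end - budget
    if t_cut <= float(recording.t[0]):
        return recording, labels
    keep = recording.t >= t_cut
    rec = AccelRecording(
        subject_id=recording.subject_id,
        sampling_rate_hz=recording.sampling_rate_hz,
        t=recording.t[keep],
        x=recording.x[keep],
        y=recording.y[keep],
        z=recording.z[keep],
    )
    return rec, labels.clip(t_cut, t_end)


def resample(recording: AccelRecording, target_hz: float) -> AccelRecording:
    """Anti-alias low-pass then decimate by an integer factor.

    The anti-alias filter is an 8th-order zero-phase Butterworth low-pass at
    0.8 x the new Nyquist frequency.  ``target_hz`` equal to the native rate
    is the identity.
    """
    native = recording.sampling_rate_hz
    if target_hz > native:
        raise ValidationError(f"target rate {target_hz} exceeds native rate {native}")
    ratio = native / target_hz
    factor = int(round(ratio))
    if abs(ratio - factor) > 1e-6:
        raise ValidationError(f"native/target rate ratio {ratio} is not an integer")
    if factor == 1:
        return recording
    sos = signal.butter(8, 0.8 * (target_hz / 2.0), btype="lowpass", fs=native, output="sos")
    xyz = signal.sosfiltfilt(sos, recording.axes(), axis=0)
    sl = slice(None, None, factor)
    return AccelRecording(
        subject_id=recording.subject_id,
        sampling_rate_hz=target_hz,
        t=recording.t[sl],
        x=np.asarray(xyz[sl, 0]),
        y=np.asarray(xyz[sl, 1]),
        z=np.asarray(xyz[sl, 2]),
    )


# ---------------------------------------------------------------------------
# windowing
# ---------------------------------------------------------------------------


@dataclass
class WindowSet:
    """Fixed-duration labeled windows — the unit of both classifiers.

    ``X`` has shape (n_windows, window_len, 3).  ``labels`` holds one of the
    five activity classes per retained window; windows that touched
    transition/interference segments or unlabeled gaps are only counted in
    ``excluded_counts``.
    """

    subject_id: str
    window_s: float
    sampling_rate_hz: float
    X: np.ndarray
    labels: np.ndarray
    end_times: np.ndarray
    end_indices: np.ndarray
    excluded_counts: dict = field(default_factory=dict)

    @property
    def n_windows(self) -> int:
        return len(self.labels)

    @property
    def window_len(self) -> int:
        return window_samples(self.window_s, self.sampling_rate_hz)


def _label_codes(recording: AccelRecording, labels: LabelTrack) -> np.ndarray:
    """Per-sample label code: 0..4 activities, 5 transition, 6 interference, -1 gap."""
    code_of = {a: i for i, a in enumerate(ACTIVITY_CLASSES)}
    code_of["transition"] = 5
    code_of["interference"] = 6
    starts, ends, acts = labels.as_arrays()
    codes = np.full(recording.n_samples, -1, dtype=np.int8)
    if len(starts) == 0:
        return codes
    idx = np.searchsorted(starts, recording.t, side="right") - 1
    valid = (idx >= 0) & (recording.t < ends[np.clip(idx, 0, None)])
    act_codes = np.array([code_of[a] for a in acts], dtype=np.int8)
    codes[valid] = act_codes[idx[valid]]
    return codes


def segment_windows(
    recording: AccelRecording,
    labels: LabelTrack,
    window_s: float = 5.0,
    stride_s: float | None = None,
) -> WindowSet:
    """Cut trailing fixed-duration windows and label them.

    A window is labeled with the activity covering its final sample (the
    most-recent-activity rule).  Any window containing transition samples is
    excluded (and tallied), then interference, then unlabeled gaps.
    """
    fs = recording.sampling_rate_hz
    win_n = window_samples(window_s, fs)
    stride_n = win_n if stride_s is None else window_samples(stride_s, fs)
    if stride_n < 1:
        raise ValidationError("stride must span at least one sample")
    excluded = dict.fromkeys(_EXCLUSION_KEYS, 0)
    if win_n > recording.n_samples:
        log.warning(
            "window (%d samples) longer than recording (%d samples) for %s",
            win_n, recording.n_samples, recording.subject_id,
        )
        return WindowSet(
            recording.subject_id, window_s, fs,
            np.empty((0, win_n, 3)), np.empty(0, dtype=object),
            np.empty(0), np.empty(0, dtype=int), excluded,
        )
    codes = _label_codes(recording, labels)
    xyz = recording.axes()
    starts = np.arange(0, recording.n_samples - win_n + 1, stride_n)
    kept_X, kept_labels, kept_t, kept_idx = [], [], [], []
    for i0 in starts:
        sl = codes[i0 : i0 + win_n]
        if np.any(sl == 5):
            excluded["transition"] += 1
            continue
        if np.any(sl == 6):
            excluded["interference"] += 1
            continue
        if np.any(sl == -1):
            excluded["unlabeled"] += 1
            continue
        end = i0 + win_n - 1
        kept_X.append(xyz[i0 : i0 + win_n])
        kept_labels.append(ACTIVITY_CLASSES[sl[-1]])
        kept_t.append(recording.t[end])
        kept_idx.append(end)
    X = np.stack(kept_X) if kept_X else np.empty((0, win_n, 3))
    return WindowSet(
        subject_id=recording.subject_id,
        window_s=window_s,
        sampling_rate_hz=fs,
        X=X,
        labels=np.array(kept_labels, dtype=object),
        end_times=np.array(kept_t, dtype=float),
        end_indices=np.array(kept_idx, dtype=int),
        excluded_counts=excluded,
    )
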