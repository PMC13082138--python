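"""Binary active/inactive classification from movement-intensity metrics.

Two window-level intensity metrics are supported:

* ``magnitude_median`` — the 5-second centered rolling median of the
  band-passed vector magnitude, thresholded at 0.07 g by default.  Lying,
  sitting and standing count as inactive; walking and jogging as active.
* ``mad`` — the Mean Amplitude Deviation, mean(|m - mean(m)|) over the same
  rolling window, with the literature cut-point of 47.73 mG (0.04773 g),
  kept as a baseline for comparison.

A sample (or window) is active when its metric value strictly exceeds the
threshold; a value exactly at the threshold is inactive.

Threshold calibration scans a fixed 0.001 g grid over the pooled window
values and picks the threshold minimizing the number of misclassified
windows (inactive windows above it plus active windows at or below it),
breaking ties toward the smaller threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import ACTIVITY_CLASSES, AccelRecording, LabelTrack, ValidationError
from . import preprocessing
from .preprocessing import FilterSpec, MagnitudeSeries, WindowSet

#: Activity classes mapped to the active state; the rest are inactive.
ACTIVE_CLASSES = ("walking", "jogging")

#: Literature MAD cut-point, printed as 47.73 mG.
MAD_THRESHOLD_MG = 47.73

CALIBRATION_GRID_STEP_G = 0.001


@dataclass(frozen=True)
class CutpointConfig:
    threshold_g: float = 0.07
    window_s: float = 5.0
    metric: str = "magnitude_median"  # or "mad"
    mad_threshold_g: float = MAD_THRESHOLD_MG / 1000.0

    def validate(self) -> "CutpointConfig":
        if self.threshold_g <= 0 or self.window_s <= 0:
            raise ValidationError("threshold_g and window_s must be positive")
        if self.metric not in ("magnitude_median", "mad"):
            raise ValidationError(f"unknown metric {self.metric!r}")
        return self

    @property
    def effective_threshold(self) -> float:
        return self.threshold_g if self.metric == "magnitude_median" else self.mad_threshold_g


@dataclass
class BinarySeries:
    """Per-sample (or per-window) active/inactive states."""

    t: np.ndarray
    active: np.ndarray  # bool


def rolling_mad(series: MagnitudeSeries, window_s: float = 5.0) -> MagnitudeSeries:
    """Centered rolling Mean Amplitude Deviation: mean(|m - mean(window)|)."""
    n = preprocessing.window_samples(window_s, series.sampling_rate_hz)
    if n < 3:
        raise ValidationError("rolling window must span at least 3 samples")

    def mad(w, axis=None):
        w = np.asarray(w, dtype=float)
        if axis is None:
            return np.mean(np.abs(w - np.mean(w)))
        return np.mean(np.abs(w - np.mean(w, axis=axis, keepdims=True)), axis=axis)

    out = preprocessing._centered_window_stat(series.m, n, mad)
    return MagnitudeSeries(t=series.t, m=out, sampling_rate_hz=series.sampling_rate_hz)


def classify(series: MagnitudeSeries, config: CutpointConfig = CutpointConfig()) -> BinarySeries:
    """Threshold a metric series into active/inactive states.

    For ``metric="magnitude_median"`` the input is expected to already be a
    rolling-median magnitude series; for ``metric="mad"`` the input is a raw
    magnitude series and the rolling MAD is computed internally.
    """
    config.validate()
    if config.metric == "mad":
        series = rolling_mad(series, config.window_s)
    return BinarySeries(t=series.t, active=series.m > config.effective_threshold)


def _to_binary_truth(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels)
    if labels.dtype == bool:
        return labels
    unknown = set(np.unique(labels)) - set(ACTIVITY_CLASSES)
    if unknown:
        raise ValidationError(f"labels outside the activity vocabulary: {sorted(unknown)}")
    return np.isin(labels, ACTIVE_CLASSES)


def calibrate_threshold(values: np.ndarray, labels: np.ndarray) -> tuple[float, int]:
    """Pick the threshold minimizing misclassified windows on a fixed grid.

    Parameters
    ----------
    values : window-level metric values (rolling-median magnitude), in g.
    labels : five-class activity labels, or booleans (True = active).

    Returns
    -------
    (threshold, overlap_count) — the grid threshold with the fewest
    misclassified windows; ties go to the smaller threshold.
    """
    values = np.asarray(values, dtype=float)
    active = _to_binary_truth(labels)
    if active.all() or not active.any():
        raise ValidationError("cannot calibrate with a single class")
    step = CALIBRATION_GRID_STEP_G
    lo, hi = float(values.min()), float(values.max())
    grid = np.arange(np.floor(lo / step), np.floor(hi / step) + 1) * step
    # misclassified(th) = #(inactive with v > th) + #(active with v <= th)
    inact = np.sort(values[~active])
    act = np.sort(values[active])
    n_inact_above = len(inact) - np.searchsorted(inact, grid, side="right")
    n_act_below = np.searchsorted(act, grid, side="right")
    overlap = n_inact_above + n_act_below
    best = int(np.argmin(overlap))  # argmin takes the first (smallest) on ties
    return float(grid[best]), int(overlap[best])


def evaluate_binary(pred, truth) -> dict:
    """Confusion-matrix metrics with active as the positive class.

    Precision is reported as 0.0 when no positives are predicted, and
    F1 is 0.0 whenever precision or recall is 0.
    """
    p = pred.active if isinstance(pred, BinarySeries) else np.asarray(pred, dtype=bool)
    t = truth.active if isinstance(truth, BinarySeries) else _to_binary_truth(truth)
    if len(p) != len(t):
        raise ValidationError(f"length mismatch: pred {len(p)} vs truth {len(t)}")
    tp = int(np.sum(p & t))
    fp = int(np.sum(p & ~t))
    fn = int(np.sum(~p & t))
    tn = int(np.sum(~p & ~t))
    n = tp + fp + fn + tn
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return {
        "accuracy": (tp + tn) / n if n else 0.0,
        "precision": precision,
        "recall": recall,
        "f1": f1,
    }


# ---------------------------------------------------------------------------
# window-level pipeline
# ---------------------------------------------------------------------------


def window_metric_values(
    recording: AccelRecording,
    labels: LabelTrack,
    config: CutpointConfig = CutpointConfig(),
    filter_spec: FilterSpec = FilterSpec(),
) -> tuple[np.ndarray, np.ndarray, WindowSet]:
    """Per-window metric values and activity labels for one subject.

    Band-passes the recording, computes the configured rolling metric, cuts
    trailing windows, and reads the metric at each retained window's final
    sample.  Returns (values, labels, window_set).
    """
    config.validate()
    filtered = preprocessing.bandpass(recording, filter_spec)
    mag = preprocessing.magnitude(filtered)
    if config.metric == "magnitude_median":
        metric = preprocessing.rolling_median(mag, config.window_s)
    else:
        metric = rolling_mad(mag, config.window_s)
    ws = preprocessing.segment_windows(recording, labels, window_s=config.window_s)
    values = metric.m[ws.end_indices] if ws.n_windows else np.empty(0)
    return values, ws.labels, ws


def split_subjects(
    subject_ids, test_fraction: float = 0.2, seed: int = 0
) -> tuple[list, list]:
    """Seeded subject-level train/test split with no participant overlap."""
    ids = sorted(subject_ids)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    n_test = max(1, int(round(test_fraction * len(ids))))
    test = sorted(ids[i] for i in perm[:n_test])
    train = sorted(ids[i] for i in perm[n_test:])
    return train, test
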