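"""Resting heart rate, deviations, and their link to movement intensity.

A subject's resting baseline is the median device heart rate during lying or
sitting intervals that end before the first walking bout (when the subject
never walks, every lying/sitting interval qualifies).  Heart-rate deviation
is observed rate minus that baseline.  To test whether the rolling-magnitude
signal carries physiological information, each 5-second window during an
active (walking/jogging-labeled) period is paired with the heart-rate sample
nearest its end time (within 1 s), and the pooled pairs across subjects are
summarized with a Pearson correlation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import HeartRateSeries, LabelTrack, ValidationError
from . import preprocessing
from .cutpoint import ACTIVE_CLASSES
from .preprocessing import FilterSpec

log = logging.getLogger(__name__)


@dataclass
class VitalsResult:
    baselines: dict            # subject_id -> resting_hr_bpm
    pairs: pd.DataFrame        # subject_id, window_end_s, magnitude, hr_deviation_bpm
    r: float
    p: float
    n: int
    n_unpaired: int


def resting_baseline(hr: HeartRateSeries, labels: LabelTrack) -> float:
    """Median heart rate in lying/sitting intervals before the first walk."""
    first_walk = labels.first_walking_start()
    cut = np.inf if first_walk is None else first_walk
    mask = np.zeros(len(hr.t), dtype=bool)
    for s, e, a in labels.intervals:
        if a in ("lying", "sitting") and e <= cut:
            mask |= (hr.t >= s) & (hr.t < e)
    if not mask.any():
        raise ValidationError("no pre-walking rest period")
    return float(np.median(hr.hr_bpm[mask]))


def hr_deviation(hr: HeartRateSeries, baseline: float) -> np.ndarray:
    """Observed heart rate minus the subject's resting baseline."""
    return hr.hr_bpm - baseline


def correlate(
    cohort,
    window_s: float = 5.0,
    filter_spec: FilterSpec = FilterSpec(),
    pair_tolerance_s: float = 1.0,
    truncate_minutes: float | None = 20.0,
) -> VitalsResult:
    """Pooled Pearson correlation between rolling magnitude and HR deviation.

    Parameters
    ----------
    cohort : mapping subject_id -> (recording, labels, hr).

    Windows are the trailing 5-s activity windows whose truth label is
    walking or jogging; each contributes its rolling-median magnitude at the
    window end, paired with the nearest heart-rate sample within
    ``pair_tolerance_s``.  Unpairable windows are dropped and counted.
    """
    rows = []
    baselines = {}
    n_unpaired = 0
    for sid, (recording, labels, hr) in cohort.items():
        baseline = resting_baseline(hr, labels)
        baselines[sid] = baseline
        dev = hr_deviation(hr, baseline)
        rec, lab = recording, labels
        if truncate_minutes is not None:
            rec, lab = preprocessing.truncate_last(rec, lab, minutes=truncate_minutes)
        filtered = preprocessing.bandpass(rec, filter_spec)
        mag = preprocessing.rolling_median(preprocessing.magnitude(filtered), window_s)
        ws = preprocessing.segment_windows(rec, lab, window_s=window_s)
        for end_t, end_i, label in zip(ws.end_times, ws.end_indices, ws.labels):
            if label not in ACTIVE_CLASSES:
                continue
            j = int(np.argmin(np.abs(hr.t - end_t)))
            if abs(hr.t[j] - end_t) > pair_tolerance_s:
                n_unpaired += 1
                continue
            rows.append(
                {
                    "subject_id": sid,
                    "window_end_s": float(end_t),
                    "magnitude": float(mag.m[end_i]),
                    "hr_deviation_bpm": float(dev[j]),
                }
            )
    pairs = pd.DataFrame(rows)
    if len(pairs) < 3:
        raise ValidationError(f"only {len(pairs)} magnitude/HR pairs; need at least 3")
    r, p = stats.pearsonr(pairs["magnitude"], pairs["hr_deviation_bpm"])
    if n_unpaired:
        log.info("%d active windows had no heart-rate sample within tolerance", n_unpaired)
    return VitalsResult(
        baselines=baselines, pairs=pairs, r=float(r), p=float(p),
        n=len(pairs), n_unpaired=n_unpaired,
    )
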