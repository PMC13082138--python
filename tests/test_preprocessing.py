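"""Filtering, magnitude, rolling statistics, truncation, resampling, windowing."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from actipatch.io_formats import AccelRecording, LabelTrack, ValidationError
from actipatch import preprocessing as pp
from actipatch.preprocessing import FilterSpec, MagnitudeSeries


def _sine_recording(freq, fs=50.0, dur=120.0, amp=1.0, offset=0.0):
    t = np.arange(int(dur * fs)) / fs
    s = amp * np.sin(2 * np.pi * freq * t) + offset
    return AccelRecording("s", fs, t, s.copy(), s.copy(), s.copy())


def _amplitude(x):
    core = x[len(x) // 4 : -len(x) // 4]
    return (core.max() - core.min()) / 2


class TestBandpass:
    def test_passband_amplitude_preserved(self):
        rec = _sine_recording(1.0)
        out = pp.bandpass(rec, FilterSpec())
        assert _amplitude(out.x) == pytest.approx(1.0, rel=0.05)

    def test_stopband_attenuated_20db(self):
        # order-4 zero-phase at 10 Hz: analytic prototype response is ~-56 dB
        # per pass, so >=20 dB is a loose floor
        rec = _sine_recording(10.0)
        out = pp.bandpass(rec, FilterSpec())
        assert _amplitude(out.x) < 0.1

    def test_dc_removed(self):
        rec = _sine_recording(1.0, amp=0.0, offset=0.98)
        out = pp.bandpass(rec, FilterSpec())
        assert abs(out.x[len(out.x) // 2 :].mean()) < 1e-3

    @pytest.mark.parametrize("cutoff", [0.05, 2.0])
    def test_causal_gain_is_minus_3db_at_cutoffs(self, cutoff):
        rec = _sine_recording(cutoff, dur=1200.0)
        out = pp.bandpass(rec, FilterSpec(mode="causal"))
        # steady-state amplitude from the final quarter of a long sinusoid
        tail = out.x[-int(300 * 50) :]
        amp = np.sqrt(2) * np.sqrt(np.mean(tail**2))
        assert amp == pytest.approx(1 / np.sqrt(2), rel=0.02)

    def test_high_cut_at_nyquist_rejected(self):
        with pytest.raises(ValidationError, match="Nyquist"):
            pp.bandpass(_sine_recording(1.0), FilterSpec(high_hz=25.0))


class TestMagnitude:
    def test_three_four_five(self):
        rec = AccelRecording(
            "s", 50.0, np.array([0.0, 0.02]), np.array([3.0, 0.0]),
            np.array([4.0, 0.0]), np.array([0.0, 0.0]),
        )
        np.testing.assert_allclose(pp.magnitude(rec).m, [5.0, 0.0])

    @settings(deadline=None, max_examples=25)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_rotation_invariance(self, seed):
        rng = np.random.default_rng(seed)
        xyz = rng.normal(size=(40, 3))
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        t = np.arange(40) / 50.0
        rec = AccelRecording("s", 50.0, t, *(xyz[:, i] for i in range(3)))
        rot = rec.replace_axes(xyz @ q.T)
        np.testing.assert_allclose(pp.magnitude(rec).m, pp.magnitude(rot).m, atol=1e-9)


def _brute_centered(values, n, stat):
    left, right = (n - 1) // 2, n // 2
    return np.array(
        [stat(values[max(i - left, 0) : min(i + right + 1, len(values))])
         for i in range(len(values))]
    )


class TestRollingMedian:
    def test_constant_series_unchanged(self):
        s = MagnitudeSeries(np.arange(100) / 50, np.full(100, 0.3), 50.0)
        np.testing.assert_allclose(pp.rolling_median(s, 1.0).m, 0.3)

    def test_spike_robustness(self):
        rng = np.random.default_rng(0)
        m = rng.uniform(0.1, 0.2, 500)
        spikes = rng.choice(500, size=40, replace=False)  # < N/2 of any window
        m[spikes] = 50.0
        s = MagnitudeSeries(np.arange(500) / 50, m, 50.0)
        out = pp.rolling_median(s, 5.0)
        assert out.m.max() <= 0.2 + 1e-12

    @pytest.mark.parametrize("seed", range(5))
    @pytest.mark.parametrize("window_s", [0.1, 0.17, 5.0])
    def test_matches_brute_force_oracle(self, seed, window_s):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(30, 1000))
        m = rng.uniform(0, 1, n)
        s = MagnitudeSeries(np.arange(n) / 50, m, 50.0)
        got = pp.rolling_median(s, window_s).m
        want = _brute_centered(m, pp.window_samples(window_s, 50.0), np.median)
        np.testing.assert_array_equal(got, want)

    def test_short_window_rejected(self):
        s = MagnitudeSeries(np.arange(10) / 50, np.ones(10), 50.0)
        with pytest.raises(ValidationError, match="3 samples"):
            pp.rolling_median(s, 0.04)

    def test_causal_delay_is_half_window(self):
        # 5 s at 50 Hz: N = 250 samples, delay (N-1)/2 = 124.5 samples = 2.49 s
        assert pp.window_samples(5.0, 50.0) == 250
        assert pp.rolling_delay_samples(5.0, 50.0) == 124.5


class TestTruncateLast:
    def _long_recording(self, minutes):
        fs = 50.0
        n = int(minutes * 60 * fs)
        t = np.arange(n) / fs
        z = np.zeros(n)
        return AccelRecording("s", fs, t, z, z.copy(), z.copy())

    def test_thirty_minutes_cut_to_twenty(self):
        rec = self._long_recording(30)
        labels = LabelTrack("s", [(0.0, 1800.0, "sitting")])
        out, lab = pp.truncate_last(rec, labels, minutes=20)
        assert out.t[-1] == rec.t[-1]
        assert out.t[0] >= rec.t[-1] - 1200.0
        assert lab.intervals[0][0] == pytest.approx(rec.t[-1] - 1200.0)

    def test_short_recording_returned_whole(self):
        rec = self._long_recording(4.22)
        labels = LabelTrack("s", [(0.0, 253.2, "sitting")])
        out, lab = pp.truncate_last(rec, labels, minutes=20)
        assert out.n_samples == rec.n_samples
        assert lab.intervals == labels.intervals

    def test_label_clipped_at_boundary(self):
        rec = self._long_recording(25)
        labels = LabelTrack("s", [(0.0, 400.0, "lying"), (400.0, 1500.0, "sitting")])
        _out, lab = pp.truncate_last(rec, labels, minutes=20)
        cut = rec.t[-1] - 1200.0  # ~299.98 s: the lying interval spans it
        assert lab.intervals[0] == (pytest.approx(cut), 400.0, "lying")
        s, e, a = lab.intervals[1]
        assert (s, a) == (400.0, "sitting") and e == pytest.approx(rec.t[-1])


class TestResample:
    def test_native_rate_is_identity(self):
        rec = _sine_recording(1.0, dur=20.0)
        out = pp.resample(rec, 50.0)
        np.testing.assert_array_equal(out.x, rec.x)

    def test_downsample_preserves_low_frequency(self):
        rec = _sine_recording(1.0, dur=60.0)
        out = pp.resample(rec, 25.0)
        assert out.sampling_rate_hz == 25.0
        assert out.n_samples == rec.n_samples // 2 + rec.n_samples % 2
        assert _amplitude(out.x) == pytest.approx(1.0, rel=0.02)

    def test_anti_alias_removes_above_new_nyquist(self):
        # 3 Hz at a 5 Hz target: above the 2.5 Hz Nyquist, anti-aliased away
        rec = _sine_recording(3.0, dur=60.0)
        out = pp.resample(rec, 5.0)
        assert _amplitude(out.x) < 0.1

    def test_non_integer_ratio_rejected(self):
        with pytest.raises(ValidationError, match="integer"):
            pp.resample(_sine_recording(1.0), 15.0)


class TestSegmentWindows:
    def _recording(self, dur, fs=10.0):
        n = int(dur * fs)
        t = np.arange(n) / fs
        z = np.zeros(n)
        return AccelRecording("s", fs, t, z, z.copy(), z.copy())

    def test_pure_sitting_minute_gives_twelve_windows(self):
        rec = self._recording(60.0)
        ws = pp.segment_windows(rec, LabelTrack("s", [(0.0, 60.0, "sitting")]), 5.0)
        assert ws.n_windows == 12
        assert set(ws.labels) == {"sitting"}

    def test_most_recent_activity_rule(self):
        rec = self._recording(20.0)
        labels = LabelTrack("s", [(0.0, 7.0, "sitting"), (7.0, 20.0, "walking")])
        ws = pp.segment_windows(rec, labels, 5.0)
        # window [5, 10) spans both; the final sample lies in walking
        assert list(ws.labels) == ["sitting", "walking", "walking", "walking"]

    def test_transition_windows_excluded_and_counted(self):
        rec = self._recording(20.0)
        labels = LabelTrack(
            "s", [(0.0, 7.0, "sitting"), (7.0, 8.0, "transition"), (8.0, 20.0, "walking")]
        )
        ws = pp.segment_windows(rec, labels, 5.0)
        assert ws.excluded_counts["transition"] == 1
        assert list(ws.labels) == ["sitting", "walking", "walking"]

    def test_unlabeled_gap_excluded(self):
        rec = self._recording(15.0)
        labels = LabelTrack("s", [(0.0, 5.0, "sitting"), (10.0, 15.0, "walking")])
        ws = pp.segment_windows(rec, labels, 5.0)
        # window [5, 10) falls entirely in the gap; [10, 15) is walking
        assert ws.excluded_counts["unlabeled"] == 1
        assert list(ws.labels) == ["sitting", "walking"]

    def test_counts_partition_total_windows(self, tiny_cohort):
        rec, labels, _hr = next(iter(tiny_cohort.values()))
        ws = pp.segment_windows(rec, labels, 5.0)
        total = (rec.n_samples - ws.window_len) // ws.window_len + 1
        assert ws.n_windows + sum(ws.excluded_counts.values()) == total
        assert set(ws.labels) <= set(("lying", "sitting", "standing", "walking", "jogging"))

    def test_window_longer_than_recording_is_empty(self):
        rec = self._recording(3.0)
        ws = pp.segment_windows(rec, LabelTrack("s", [(0.0, 3.0, "sitting")]), 5.0)
        assert ws.n_windows == 0

    def test_window_len_after_resampling(self, tiny_cohort):
        rec, labels, _hr = next(iter(tiny_cohort.values()))
        for target in (5.0, 10.0, 25.0):
            out = pp.resample(rec, target)
            ws = pp.segment_windows(out, labels, 5.0)
            assert ws.window_len == round(5.0 * target)
            assert ws.X.shape[1:] == (ws.window_len, 3)
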