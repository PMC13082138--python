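"""Synthetic chest-patch cohort generator.

Generates labeled triaxial accelerometry plus a coupled 1 Hz heart-rate
stream with the statistical structure the analysis pipeline assumes, so
every module can be exercised at desk scale without the released recordings.

Design (all conventions are this generator's own and used consistently by
the tests):

* Device axes: x lateral, y along the trunk (up when upright), z out of the
  chest.  Gravity projects onto -y in upright postures and onto -z when
  lying.  Posture changes are cosine ramps, labeled ``transition``.
* Locomotion (walking/jogging) is a vertical sinusoid at a subject-specific
  step frequency plus a half-amplitude second harmonic, with 0.3x lateral
  crosstalk.  Jogging adds a stride-rate sub-harmonic at half the step
  frequency (left/right asymmetry), which keeps jogging visible below the
  2 Hz analysis band even though its step frequency lies above it.
* Static postures differ in their micro-movement signatures, as they do at
  the chest: all carry a breathing oscillation whose depth is a per-subject
  trait but whose rate is slower supine (0.12-0.18 Hz) than upright
  (0.30-0.45 Hz); sitting adds intermittent fidget bursts and standing
  continuous postural sway (0.3-1 Hz band-limited noise).  These signatures
  are what make the five classes separable after the 0.05-2 Hz band-pass
  removes the gravity offsets — and because they live at seconds-long time
  scales, windows much shorter than a breathing period genuinely cannot
  resolve them.
* Broadband noise above 2 Hz is injected on every axis on purpose: widening
  the filter's high cutoff then admits pure noise and degrades
  classification, giving the cutoff-sensitivity sweep a real effect to find.
* Heart rate is baseline + gain x (2-s-smoothed magnitude of the
  gravity-free signal) + AR(1) noise, sampled at 1 Hz.

Everything is deterministic given (config, seed): subject i draws from
``SeedSequence(seed, spawn_key=(i,))``.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
from scipy import signal
from scipy.ndimage import uniform_filter1d

from .io_formats import (
    AccelRecording,
    HeartRateSeries,
    LabelTrack,
    ValidationError,
    write_accel,
    write_hr,
    write_labels,
)

DEFAULT_SCHEDULE = (
    ("lying", 180.0),
    ("sitting", 360.0),
    ("standing", 180.0),
    ("walking", 300.0),
    ("jogging", 120.0),
)

_UPRIGHT_G = np.array([0.0, -1.0, 0.0])
_LYING_G = np.array([0.0, 0.0, -1.0])


@dataclass(frozen=True)
class GeneratorConfig:
    """Cohort-level generator settings; defaults define the study conditions."""

    n_subjects: int = 10
    seed: int = 0
    rate_hz: float = 50.0
    schedule: tuple = DEFAULT_SCHEDULE
    duration_jitter: float = 0.3           # +-30% per-block duration jitter
    transition_s: tuple = (3.0, 8.0)
    walking_freq_hz: tuple = (1.4, 2.2)
    jogging_freq_hz: tuple = (2.4, 3.2)
    walking_amp_g: tuple = (0.25, 0.45)
    jogging_amp_g: tuple = (0.6, 1.0)
    stride_subharmonic_frac: float = 0.4   # jogging stride line at f/2
    lateral_crosstalk: float = 0.3         # lateral/vertical ratio at the step rate
    static_noise_sd_g: float = 0.01
    fidget_rate_per_min: float = 2.0
    fidget_dur_s: tuple = (1.0, 3.0)
    fidget_amp_g: tuple = (0.05, 0.15)
    fidget_band_hz: tuple = (0.5, 3.0)
    sway_sd_g: float = 0.015
    sway_band_hz: tuple = (0.3, 1.0)
    breathing_amp_g: tuple = (0.012, 0.024)  # per-subject depth draw
    breathing_freq_lying_hz: tuple = (0.12, 0.18)
    breathing_freq_upright_hz: tuple = (0.30, 0.45)
    hf_noise_sd_g: float = 0.02
    hf_cut_hz: float = 2.0
    hr_baseline_bpm: tuple = (65.0, 5.0)   # Normal(mean, sd)
    hr_gain_bpm_per_g: float = 60.0
    hr_noise_sd_bpm: float = 2.0
    hr_noise_phi: float = 0.8
    interference_per_subject: int = 1
    interference_dur_s: tuple = (4.0, 8.0)
    interference_amp_g: float = 0.3
    #: Designed active/inactive boundary of the 5-s rolling-median magnitude:
    #: fidget bursts top static windows out just below this level while the
    #: locomotion floor sits well above it.
    separation_point_g: float = 0.07

    def validate(self) -> "GeneratorConfig":
        if self.n_subjects < 1:
            raise ValidationError("n_subjects must be positive")
        total = sum(d for _a, d in self.schedule)
        if total > 24 * 3600:
            raise ValidationError("schedule exceeds 24 h")
        for a, d in self.schedule:
            if d <= 0:
                raise ValidationError(f"non-positive duration for block {a!r}")
        for f in (*self.walking_freq_hz, *self.jogging_freq_hz):
            if f >= self.rate_hz / 2:
                raise ValidationError("locomotion frequency above the Nyquist frequency")
        return self


def _subject_rng(config: GeneratorConfig, subject_index: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed, spawn_key=(subject_index,))
    )


def _draw_params(rng: np.random.Generator, config: GeneratorConfig) -> dict:
    """Subject-level scalar draws (fixed order: keeps manifests reproducible)."""
    u = lambda lohi: float(rng.uniform(*lohi))
    jitter = lambda d: float(
        d * rng.uniform(1.0 - config.duration_jitter, 1.0 + config.duration_jitter)
    )
    params = {
        "block_durations_s": [jitter(d) for _a, d in config.schedule],
        "transition_durations_s": [u(config.transition_s) for _ in range(len(config.schedule) - 1)],
        "walking_freq_hz": u(config.walking_freq_hz),
        "jogging_freq_hz": u(config.jogging_freq_hz),
        "walking_amp_g": u(config.walking_amp_g),
        "jogging_amp_g": u(config.jogging_amp_g),
        "breathing_freq_lying_hz": u(config.breathing_freq_lying_hz),
        "breathing_freq_upright_hz": u(config.breathing_freq_upright_hz),
        "breathing_amp_g": u(config.breathing_amp_g),
        "hr_baseline_bpm": float(
            rng.normal(config.hr_baseline_bpm[0], config.hr_baseline_bpm[1])
        ),
    }
    return params


def _band_noise(rng, n, fs, band, order=2):
    """Unit-sd band-limited Gaussian noise."""
    w = rng.standard_normal(n)
    sos = signal.butter(order, band, btype="bandpass", fs=fs, output="sos")
    out = signal.sosfiltfilt(sos, w)
    sd = out.std()
    return out / sd if sd > 0 else out


def _locomotion_axes(t, freq, amp, lateral, phases, stride_frac=0.0):
    """Vertical (y) and lateral (x) locomotion components.

    Walking: vertical sinusoid at the step frequency plus a half-amplitude
    second harmonic, with lateral crosstalk at the step frequency.  Jogging
    (``stride_frac > 0``) shares that structure at its (faster) step
    frequency and adds a stride-rate sub-harmonic at half the step
    frequency from left/right asymmetry.
    """
    y = amp * np.sin(2 * np.pi * freq * t + phases[0])
    y += 0.5 * amp * np.sin(4 * np.pi * freq * t + phases[1])
    if stride_frac > 0:
        y += stride_frac * amp * np.sin(np.pi * freq * t + phases[2])
    x = lateral * amp * np.sin(2 * np.pi * freq * t + phases[3])
    return x, y


def generate_subject(
    config: GeneratorConfig, subject_index: int
) -> tuple[AccelRecording, LabelTrack, HeartRateSeries]:
    """Deterministically synthesize one subject's recording, labels and HR."""
    config.validate()
    rng = _subject_rng(config, subject_index)
    params = _draw_params(rng, config)
    fs = config.rate_hz
    sid = f"s{subject_index + 1:02d}"

    # --- timeline: blocks with transitions in between -----------------------
    blocks = []  # (activity, start_s, end_s)
    cursor = 0.0
    for i, (activity, _nominal) in enumerate(config.schedule):
        if i > 0:
            tdur = params["transition_durations_s"][i - 1]
            blocks.append(("transition", cursor, cursor + tdur))
            cursor += tdur
        bdur = params["block_durations_s"][i]
        blocks.append((activity, cursor, cursor + bdur))
        cursor += bdur
    total_s = cursor
    n = int(round(total_s * fs))
    t = np.arange(n) / fs

    # --- posture weights (cosine ramps across transitions) ------------------
    activity_blocks = [b for b in blocks if b[0] != "transition"]
    weights = np.zeros((len(activity_blocks), n))
    for bi, (activity, s, e) in enumerate(activity_blocks):
        w = ((t >= s) & (t < e)).astype(float)
        # ramp in over the preceding transition, out over the following one
        prev = next((b for b in blocks if b[0] == "transition" and abs(b[2] - s) < 1e-9), None)
        nxt = next((b for b in blocks if b[0] == "transition" and abs(b[1] - e) < 1e-9), None)
        if prev is not None:
            ts, te = prev[1], prev[2]
            m = (t >= ts) & (t < te)
            w[m] = 0.5 * (1 - np.cos(np.pi * (t[m] - ts) / (te - ts)))
        if nxt is not None:
            ts, te = nxt[1], nxt[2]
            m = (t >= ts) & (t < te)
            w[m] = 0.5 * (1 + np.cos(np.pi * (t[m] - ts) / (te - ts)))
        weights[bi] = w
    wsum = weights.sum(axis=0)
    wsum[wsum == 0] = 1.0
    weights /= wsum

    gravity = np.zeros((n, 3))
    for bi, (activity, _s, _e) in enumerate(activity_blocks):
        gvec = _LYING_G if activity == "lying" else _UPRIGHT_G
        gravity += weights[bi][:, None] * gvec

    # --- dynamic components --------------------------------------------------
    dyn = np.zeros((n, 3))
    breathing_phase = rng.uniform(0, 2 * np.pi)
    # respiratory rate is slower supine than upright; the depth is a
    # subject-level trait, so telling the postures apart requires resolving
    # the oscillation itself rather than its instantaneous scale
    amp_br = params["breathing_amp_g"]
    breathing_lying = amp_br * np.sin(
        2 * np.pi * params["breathing_freq_lying_hz"] * t + breathing_phase
    )
    breathing_upright = amp_br * np.sin(
        2 * np.pi * params["breathing_freq_upright_hz"] * t + breathing_phase
    )
    fidget_events = []
    for bi, (activity, s, e) in enumerate(activity_blocks):
        w = weights[bi]
        if activity in ("walking", "jogging"):
            freq = params[f"{activity}_freq_hz"]
            amp = params[f"{activity}_amp_g"]
            phases = rng.uniform(0, 2 * np.pi, size=4)
            stride = config.stride_subharmonic_frac if activity == "jogging" else 0.0
            lx, ly = _locomotion_axes(t, freq, amp, config.lateral_crosstalk, phases, stride)
            dyn[:, 0] += w * lx
            dyn[:, 1] += w * ly
            dyn[:, 2] += w * breathing_upright
        else:
            breathing = breathing_lying if activity == "lying" else breathing_upright
            dyn[:, 2] += w * breathing
            if activity == "standing":
                dyn[:, 0] += w * config.sway_sd_g * _band_noise(rng, n, fs, config.sway_band_hz)
                dyn[:, 2] += w * config.sway_sd_g * _band_noise(rng, n, fs, config.sway_band_hz)
            if activity in ("sitting", "standing"):
                dur_min = (e - s) / 60.0
                n_fidgets = rng.poisson(config.fidget_rate_per_min * dur_min)
                for _ in range(n_fidgets):
                    fdur = rng.uniform(*config.fidget_dur_s)
                    famp = rng.uniform(*config.fidget_amp_g)
                    fstart = rng.uniform(s, max(s, e - fdur))
                    i0 = int(fstart * fs)
                    i1 = min(int((fstart + fdur) * fs), n)
                    if i1 - i0 < 4:
                        continue
                    env = np.hanning(i1 - i0)
                    burst = _band_noise(rng, i1 - i0, fs, config.fidget_band_hz)
                    dyn[i0:i1, 0] += famp * env * burst
                    burst2 = _band_noise(rng, i1 - i0, fs, config.fidget_band_hz)
                    dyn[i0:i1, 2] += 0.6 * famp * env * burst2
                    fidget_events.append((activity, fstart, fdur, famp))

    # sensor noise: in-band white noise plus deliberate broadband >2 Hz noise
    dyn += rng.normal(0.0, config.static_noise_sd_g, size=(n, 3))
    hf = rng.normal(0.0, config.hf_noise_sd_g, size=(n, 3))
    sos_hp = signal.butter(4, config.hf_cut_hz, btype="highpass", fs=fs, output="sos")
    dyn += signal.sosfiltfilt(sos_hp, hf, axis=0)

    # --- labels (partition of [0, total); interference carved out of sitting)
    intervals = [(s, e, a) for a, s, e in blocks]
    for _ in range(config.interference_per_subject):
        sit = next(b for b in activity_blocks if b[0] == "sitting")
        idur = rng.uniform(*config.interference_dur_s)
        istart = rng.uniform(sit[1] + 5.0, sit[2] - idur - 5.0)
        i0, i1 = int(istart * fs), int((istart + idur) * fs)
        env = np.hanning(i1 - i0)
        dyn[i0:i1] += (
            config.interference_amp_g
            * env[:, None]
            * rng.standard_normal((i1 - i0, 3))
        )
        new = []
        for s, e, a in intervals:
            if a == "sitting" and s <= istart and istart + idur <= e:
                new.extend(
                    [(s, istart, "sitting"), (istart, istart + idur, "interference"),
                     (istart + idur, e, "sitting")]
                )
            else:
                new.append((s, e, a))
        intervals = new
    intervals.sort(key=lambda iv: iv[0])

    xyz = gravity + dyn
    recording = AccelRecording(
        subject_id=sid, sampling_rate_hz=fs, t=t,
        x=xyz[:, 0], y=xyz[:, 1], z=xyz[:, 2],
    ).validate()
    labels = LabelTrack(sid, intervals).validate()

    # --- heart rate ----------------------------------------------------------
    mag_dyn = np.linalg.norm(dyn, axis=1)
    smoothed = uniform_filter1d(mag_dyn, size=max(int(2 * fs), 1))
    hr_t = np.arange(0.0, t[-1], 1.0)
    idx = np.minimum((hr_t * fs).astype(int), n - 1)
    ar = np.empty(len(hr_t))
    innov_sd = config.hr_noise_sd_bpm * math.sqrt(1 - config.hr_noise_phi**2)
    e_prev = rng.normal(0.0, config.hr_noise_sd_bpm)
    for k in range(len(hr_t)):
        e_prev = config.hr_noise_phi * e_prev + rng.normal(0.0, innov_sd)
        ar[k] = e_prev
    hr = params["hr_baseline_bpm"] + config.hr_gain_bpm_per_g * smoothed[idx] + ar
    hr_series = HeartRateSeries(sid, hr_t, np.maximum(hr, 35.0)).validate()

    recording._params = dict(params, subject_id=sid, n_fidgets=len(fidget_events))
    return recording, labels, hr_series


def generate_cohort(config: GeneratorConfig, outdir) -> Path:
    """Write the full cohort as CSV triples plus a manifest of drawn parameters."""
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {"config": _config_dict(config), "subjects": {}}
    for i in range(config.n_subjects):
        rec, labels, hr = generate_subject(config, i)
        write_accel(rec, outdir / f"{rec.subject_id}_accel.csv")
        write_labels(labels, outdir / f"{rec.subject_id}_labels.csv")
        write_hr(hr, outdir / f"{rec.subject_id}_hr.csv")
        manifest["subjects"][rec.subject_id] = rec._params
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return outdir


def generate_cohort_data(config: GeneratorConfig) -> dict:
    """In-memory cohort: subject_id -> (recording, labels, hr)."""
    config.validate()
    out = {}
    for i in range(config.n_subjects):
        rec, labels, hr = generate_subject(config, i)
        out[rec.subject_id] = (rec, labels, hr)
    return out


def _config_dict(config: GeneratorConfig) -> dict:
    d = asdict(config)
    d["schedule"] = [list(b) for b in config.schedule]
    return d


# ---------------------------------------------------------------------------
# closed-form expectations used as recovery ground truth
# ---------------------------------------------------------------------------


def _clean_block_levels(freq, amp, stride_frac, lateral, fs, filter_spec=None):
    """Deterministic intensity levels of a clean locomotion block.

    Returns (v_filtered, v_raw): the steady-state 5-s rolling-median
    magnitude after the analysis band-pass, and the mean raw dynamic
    magnitude driving the heart-rate coupling.
    """
    from . import preprocessing
    from .preprocessing import FilterSpec

    filter_spec = filter_spec or FilterSpec()
    dur = 40.0
    t = np.arange(int(dur * fs)) / fs
    x, y = _locomotion_axes(t, freq, amp, lateral, phases=np.zeros(4), stride_frac=stride_frac)
    xyz = np.column_stack([x, y, np.zeros_like(x)])
    sos = filter_spec.sos(fs)
    filt = signal.sosfiltfilt(sos, xyz, axis=0)
    mag_f = np.linalg.norm(filt, axis=1)
    med = preprocessing._centered_window_stat(mag_f, int(round(5.0 * fs)), np.median)
    core = slice(int(10 * fs), int(30 * fs))
    v_filtered = float(np.median(med[core]))
    mag_r = np.linalg.norm(xyz, axis=1)
    v_raw = float(mag_r[core].mean())
    return v_filtered, v_raw


def expected_pairs_correlation(config: GeneratorConfig) -> float:
    """Expected pooled Pearson correlation between the rolling-magnitude
    metric and heart-rate deviation over active windows.

    Computed from the generator's own design: the deterministic per-block
    intensity levels implied by each subject's drawn locomotion parameters
    (signal variance across pooled active windows) against the stationary
    AR(1) heart-rate noise variance:

        rho = cov(v_f, G v_r) / sqrt(var(v_f) * (G^2 var(v_r) + sd_noise^2))
    """
    config.validate()
    vf, vr, wts = [], [], []
    for i in range(config.n_subjects):
        rng = _subject_rng(config, i)
        params = _draw_params(rng, config)
        for bi, (activity, _d) in enumerate(config.schedule):
            if activity not in ("walking", "jogging"):
                continue
            stride = config.stride_subharmonic_frac if activity == "jogging" else 0.0
            f, r = _clean_block_levels(
                params[f"{activity}_freq_hz"], params[f"{activity}_amp_g"],
                stride, config.lateral_crosstalk, config.rate_hz,
            )
            vf.append(f)
            vr.append(r)
            wts.append(params["block_durations_s"][bi] / 5.0)
    vf = np.array(vf)
    vh = config.hr_gain_bpm_per_g * np.array(vr)
    w = np.array(wts) / np.sum(wts)
    mf, mh = np.sum(w * vf), np.sum(w * vh)
    var_f = np.sum(w * (vf - mf) ** 2)
    var_h = np.sum(w * (vh - mh) ** 2)
    cov = np.sum(w * (vf - mf) * (vh - mh))
    return float(cov / math.sqrt(var_f * (var_h + config.hr_noise_sd_bpm**2)))
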