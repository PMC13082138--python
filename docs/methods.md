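# Methods

This note records the models and procedures `actipatch` implements, the
numerical choices behind them, and what the synthetic test bed does and does
not establish.

## Signal model and preprocessing

The package operates on chest-patch triaxial accelerometry sampled at a
nominal 50 Hz, in units of g, together with interval activity labels
(lying, sitting, standing, walking, jogging, plus transition and
interference markers) and the device's 1 Hz heart-rate stream.

Each axis is band-pass filtered with a Butterworth design, 0.05–2 Hz by
default: the low edge removes sensor drift and the (otherwise dominant)
gravity offset, the high edge removes device and environment vibration
while keeping gait fundamentals. The filter order is 4; offline analyses
use zero-phase forward–backward filtering (effective order
8, no phase delay), and a single-pass causal mode is provided for streaming
use, where the −3 dB points sit at the cutoffs. Recordings are truncated to
their final 20 minutes before filtering — truncation first confines
boundary effects to a span that is discarded anyway and is cheaper; the
alternative order would differ only in edge transients.

Sampling-rate reduction (to 25, 10 or 5 Hz) is integer-factor decimation
preceded by an 8th-order zero-phase Butterworth low-pass at 0.8× the new
Nyquist frequency. The anti-alias filter matters: without it, the
sensitivity grid would conflate information loss with aliasing artifacts.

The movement-intensity signal is the vector magnitude √(x²+y²+z²) of the
filtered axes, smoothed by a centered rolling median of width
N = round(5 s × fs) (N = 250 at 50 Hz). Edges use the truncated available
window down to one sample. Consumed causally, the centered statistic lags
by (N−1)/2 samples — 2.49 s at the default setting — which is the method's
end-to-end latency in a streaming deployment. The median (rather than a
mean) makes the statistic robust to spike artifacts: fewer than N/2
contaminated samples cannot move it outside the range of the clean data.

Windows are trailing, fixed-duration (default 5 s), non-overlapping
(stride = window; configurable). A window takes the label of the interval
covering its final sample — the most-recent-activity rule. Windows
containing any transition-labeled samples are excluded and tallied, then
interference, then unlabeled gaps. Exclusion (rather than relabeling) keeps
both classifiers trained and evaluated on well-defined states; the tallies
make the amount of excluded data auditable.

## Cut-point classification

A sample (or window) is *active* when the rolling-median magnitude strictly
exceeds a threshold, 0.07 g by default; a value exactly at the threshold is
inactive (the tie is documented and tested rather than left to float
formatting). Lying, sitting and standing map to inactive; walking and
jogging to active. The threshold is interpreted on the *filtered* magnitude
(gravity removed) — applying it to raw magnitude would shift the scale by
~1 g and is a configuration error, not a supported mode.

Calibration scans candidate thresholds on a fixed 0.001 g grid spanning the
pooled window values and minimizes the count of misclassified windows
(inactive above + active at-or-below), breaking ties toward the smaller
threshold. A fixed grid is reproducible and independent of histogram
binning choices; 0.001 g is an order of magnitude finer than any
separation the data can support.

The Mean Amplitude Deviation baseline — mean(|m − mean(m)|) over the same
5-s rolling window, with the literature cut-point of 47.73 mG — is kept as
a comparison method behind the same interface.

Binary evaluation reports accuracy, precision, recall and F1 with active as
the positive class, at window level. When no positives are predicted,
precision is reported as 0.00 (not NaN), so a degenerate all-inactive
classifier scores 0 rather than propagating undefined values.

## CNN activity classifier

The five-class classifier is a 1-D convolutional network over
(window_len × 3) filtered acceleration windows: three convolution blocks
(32×11, 64×7 with max-pool 2 after each of the first two, then 64×3),
global average pooling over time, a 64-unit ReLU layer with dropout 0.3,
and a softmax output. The first kernel spans 0.22 s at 50 Hz so that early
layers resolve the 1–3 Hz band where gait and posture signatures live;
global average pooling makes the head independent of window length, so one
architecture serves the whole window/rate grid. The network and its
training loop are implemented directly on NumPy (im2col convolutions,
hand-written backpropagation, Adam) and are fully deterministic given the
config seed.

Training minimizes class-weighted cross-entropy with inverse-frequency
weights w_c = N/(K·N_c) (so w_c·N_c is constant across present classes),
30 epochs, batch 64, Adam at 1e-3. There is no early stopping or inner
validation split; the outer leave-one-subject-out loop is the only
evaluation protocol. Per-channel standardization statistics are computed on
each training fold only and stored with the model, which makes the folds
leakage-free by construction; a hash audit in the test suite verifies that
no test window ever appears in its fold's training set.

Leave-one-subject-out cross-validation (LOOCV) holds out each subject in
turn; per-fold seeds are config.seed + fold index. Metrics use
support-weighted averaging, under which weighted recall is algebraically
identical to overall accuracy — the suite asserts this identity on random
instances. Per-class F1 across folds is pooled (one confusion matrix over
all folds), not averaged fold-wise, so rare classes are not dominated by
high-variance per-fold estimates.

## Sensitivity analyses and the mixed model

The window × rate grid re-runs the full LOOCV per combination (windows 1,
2, 4, 5, 8, 12 s; rates 5, 10, 25, 50 Hz; windows are cut *after*
resampling, so window_len = window × rate). Scores are reported per
subject, in percent, in a long-format table; a grid cell whose pipeline
fails (e.g., 1 s × 5 Hz = 5 samples, too short for the conv stack) is
recorded as missing, never imputed. The high-cutoff sweep re-runs LOOCV
with the band-pass upper edge at 2, 5, 10, 15 and 20 Hz.

The metric table feeds a linear mixed model
`score ~ C(window, ref=12 s) + C(rate, ref=50 Hz) + C(metric, ref=F1)` with
a random intercept per subject, estimated by REML with Wald z tests and
±1.96·SE intervals. Stacking all four metrics into one response with a
metric fixed effect induces correlation between rows of the same
(subject, cell); this mirrors the analysis design the table is meant to
reproduce and is acknowledged rather than corrected. A parameter-recovery
simulation (known additive effects, subject SD 8, residual SD 3) verifies
~95% CI coverage of injected window/rate effects.

## Resting vitals

A subject's resting heart rate is the median of heart-rate samples inside
lying/sitting intervals that end before the first walking interval (all
lying/sitting intervals when the subject never walks). Deviations are
observed minus baseline. Each 5-s window whose truth label is walking or
jogging contributes a (rolling-magnitude at window end, deviation at the
nearest heart-rate sample within 1 s) pair; pairs pool across subjects into
a single Pearson correlation with the exact t-based p-value. Truth labels,
not cut-point predictions, define the active periods, keeping this analysis
independent of the classifier being evaluated. Window-end pairing matches
the trailing-label convention.

## Synthetic cohort

The generator emulates the structure of a small chest-patch study: by
default 10 subjects, each with lying 3 min → sitting 6 min → standing
3 min → walking 5 min → jogging 2 min, ±30% per-block duration jitter,
3–8 s cosine-ramp transitions labeled `transition`, and one 4–8 s
`interference` segment carved out of the sitting block. Gravity lies along
−y upright and −z supine. Walking is a vertical sinusoid at a per-subject
step frequency (1.4–2.2 Hz) with a half-amplitude second harmonic and 0.3×
lateral crosstalk; jogging (2.4–3.2 Hz, amplitude 0.6–1 g) shares that
structure and adds a stride-rate sub-harmonic at half its step frequency,
which is what keeps jogging visible below a 2 Hz analysis band. Static
postures carry breathing along the chest normal — depth is a per-subject
trait (0.012–0.024 g) while the rate separates postures (0.12–0.18 Hz
supine vs 0.30–0.45 Hz upright) — plus sparse fidget bursts (2/min, 1–3 s,
0.05–0.15 g band-limited noise) during sitting and standing, and
continuous 0.3–1 Hz postural sway while standing. All axes receive white
sensor noise (0.01 g) and deliberate broadband noise above 2 Hz (0.02 g).
Heart rate is a per-subject baseline (Normal(65, 5) bpm) plus
60 bpm/g × the 2-s-smoothed gravity-free magnitude plus AR(1) noise
(stationary SD 2 bpm, φ = 0.8), at 1 Hz.

These choices give the cohort the statistical structure the analyses
assume, each placed deliberately:

* the fidget envelope tops static rolling-median windows out just below
  0.07 g while the locomotion floor sits well above it, so 0.07 g is the
  generator's designed separation point and calibration should recover it;
* breathing-rate (not depth) posture coding means 1-s windows genuinely
  cannot distinguish lying from quiet sitting while 12-s windows can —
  short windows must lose accuracy;
* fast walkers (step rate above 2 Hz) survive the 50 Hz analysis band in
  attenuated form but are nearly erased by the 5 Hz anti-alias chain —
  lower sampling rates must lose accuracy;
* the >2 Hz broadband noise is invisible at the default 2 Hz cutoff but
  floods in when the cutoff widens — raising the cutoff must lose accuracy;
* the heart-rate coupling admits a semi-analytic expected Pearson
  correlation (from the deterministic per-block intensity levels against
  the AR(1) noise variance) that the empirical pooled r must match.

What the generator does *not* emulate: biomechanically realistic gait
(impact transients, harmonics above the second, cadence variability within
a block), device-specific noise spectra, orientation drift, label error,
and missing data. Passing recovery tests therefore demonstrates that the
pipeline implements its stated computations correctly and recovers known
structure — not that the reported performance levels transfer to real
recordings, whose headline numbers are expected to be substantially lower.

## Problem sizes and determinism

The study-scale checks use 10 subjects (~19 min each nominal) for the
default-configuration analyses and 6 subjects for the one-factor-at-a-time
degradation sweeps; these sizes give stable margins for every direction
check while keeping a full run at desk scale. Every stochastic component —
generator draws (via `SeedSequence(seed, spawn_key=(subject,))`), weight
initialization, batch shuffling, dropout — is driven by explicit seeds, and
identical configurations reproduce byte-identical cohorts and training
trajectories.

## Known limitations

* The CNN runs on a NumPy backend: single-threaded, CPU-only, adequate for
  cohort sizes in the tens of subjects but not for large-scale training.
* Pure-tone locomotion makes the filtered walking amplitude of fast
  walkers (~2.2 Hz) approach the cut-point threshold; real gait, with its
  broadband content, is less sensitive to the exact high cutoff.
* The mixed model treats the four stacked metrics as exchangeable
  responses; its SEs inherit the within-cell correlation noted above.
* Transition windows are excluded end to end, so all reported metrics
  describe stable-state classification; behavior on transitional data is
  explicitly out of scope.
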