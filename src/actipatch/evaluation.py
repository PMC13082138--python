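"""Metrics, sensitivity sweeps, and the mixed-effects analysis.

Classification quality is summarized with support-weighted averaging:
per-class precision/recall/F1 are averaged with weights N_c / N, which makes
weighted recall identical to overall accuracy.  Per-class F1 across
cross-validation folds is pooled (one confusion matrix over all folds), not
averaged fold-wise.

The window-size x sampling-rate sensitivity grid re-runs the LOOCV pipeline
per combination and emits a long-format table of per-subject scores in
percent, which feeds a linear mixed model

    score ~ C(window, ref=12 s) + C(rate, ref=50 Hz) + C(metric, ref=F1)

with a random intercept per subject, estimated by REML with Wald z
inference.  Stacking all four metrics into one response with a metric fixed
effect induces within-cell correlation between rows; that is a deliberate
property of this design, documented rather than corrected.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import (
    accuracy_score,
    confusion_matrix as _sk_confusion,
    f1_score,
    precision_recall_fscore_support,
)

from .io_formats import ACTIVITY_CLASSES, ValidationError
from . import cnn_classifier, preprocessing
from .cnn_classifier import CnnConfig, FoldResult
from .preprocessing import FilterSpec

log = logging.getLogger(__name__)

METRIC_NAMES = ("accuracy", "precision", "recall", "f1")


# ---------------------------------------------------------------------------
# weighted metrics
# ---------------------------------------------------------------------------


def weighted_metrics(y_true, y_pred) -> dict:
    """Support-weighted accuracy / precision / recall / F1 over the five classes.

    Per-class precision undefined because a class was never predicted
    contributes 0 (with a warning).
    """
    y_true = np.asarray(y_true, dtype=object)
    y_pred = np.asarray(y_pred, dtype=object)
    if y_true.size == 0:
        raise ValidationError("cannot compute metrics on empty label vectors")
    if y_true.shape != y_pred.shape:
        raise ValidationError("y_true and y_pred must have equal length")
    present = [c for c in ACTIVITY_CLASSES if np.any(y_true == c)]
    unpredicted = [c for c in present if not np.any(y_pred == c)]
    if unpredicted:
        log.warning("classes never predicted (precision counted as 0): %s", unpredicted)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        precision, recall, f1, _ = precision_recall_fscore_support(
            y_true, y_pred, labels=list(ACTIVITY_CLASSES), average="weighted", zero_division=0
        )
    return {
        "accuracy": float(accuracy_score(y_true, y_pred)),
        "precision": float(precision),
        "recall": float(recall),
        "f1": float(f1),
    }


def _pool_folds(folds: Sequence[FoldResult]):
    if len(folds) == 0:
        raise ValidationError("need at least one fold")
    y_true = np.concatenate([np.asarray(f.y_true, dtype=object) for f in folds])
    y_pred = np.concatenate([np.asarray(f.y_pred, dtype=object) for f in folds])
    return y_true, y_pred


def per_class_f1(folds: Sequence[FoldResult]) -> dict:
    """One F1 per class from the confusion matrix pooled over all folds.

    A class absent from the pooled truth is reported as NaN.
    """
    y_true, y_pred = _pool_folds(folds)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        scores = f1_score(
            y_true, y_pred, labels=list(ACTIVITY_CLASSES), average=None, zero_division=0
        )
    out = {}
    for c, s in zip(ACTIVITY_CLASSES, scores):
        out[c] = float(s) if np.any(y_true == c) else float("nan")
    return out


def confusion_matrix(y_true, y_pred) -> pd.DataFrame:
    """5x5 counts; rows are truth, columns prediction, fixed class order."""
    m = _sk_confusion(
        np.asarray(y_true, dtype=object),
        np.asarray(y_pred, dtype=object),
        labels=list(ACTIVITY_CLASSES),
    )
    return pd.DataFrame(m, index=list(ACTIVITY_CLASSES), columns=list(ACTIVITY_CLASSES))


# ---------------------------------------------------------------------------
# cohort plumbing shared by the sweeps
# ---------------------------------------------------------------------------


def build_cohort_windows(
    subjects: Mapping[str, tuple],
    window_s: float,
    rate_hz: float,
    filter_spec: FilterSpec = FilterSpec(),
    truncate_minutes: float | None = 20.0,
) -> dict:
    """(recording, labels) per subject -> (windows, labels) per subject.

    Applies truncation, band-pass filtering, resampling to ``rate_hz``, then
    windowing — in that order, so window_len = round(window_s * rate_hz).
    """
    cohort = {}
    for sid, (recording, labels) in subjects.items():
        rec, lab = recording, labels
        if truncate_minutes is not None:
            rec, lab = preprocessing.truncate_last(rec, lab, minutes=truncate_minutes)
        rec = preprocessing.bandpass(rec, filter_spec)
        rec = preprocessing.resample(rec, rate_hz)
        ws = preprocessing.segment_windows(rec, lab, window_s=window_s)
        cohort[sid] = (ws.X.astype(np.float32), ws.labels)
    return cohort


def run_loocv(
    subjects: Mapping[str, tuple],
    config: CnnConfig,
    filter_spec: FilterSpec = FilterSpec(),
    truncate_minutes: float | None = 20.0,
) -> list[FoldResult]:
    """Convenience wrapper: preprocess a raw cohort and run LOOCV."""
    cohort = build_cohort_windows(
        subjects, config.window_s, config.rate_hz, filter_spec, truncate_minutes
    )
    return cnn_classifier.loocv(cohort, config)


# ---------------------------------------------------------------------------
# sensitivity analyses
# ---------------------------------------------------------------------------


def sensitivity_grid(
    subjects: Mapping[str, tuple],
    windows: Sequence[float] = (1, 2, 4, 5, 8, 12),
    rates: Sequence[float] = (5, 10, 25, 50),
    config: CnnConfig = CnnConfig(),
    filter_spec: FilterSpec = FilterSpec(),
) -> pd.DataFrame:
    """Per-subject weighted scores (percent) for every window x rate cell.

    Returns a long-format table with columns
    (subject_id, window_s, rate_hz, metric, score).  A cell whose pipeline
    raises is recorded as missing, never fabricated.
    """
    if len(subjects) < 3:
        raise ValidationError("sensitivity grid needs at least 3 subjects")
    rows = []
    for w in windows:
        for r in rates:
            from dataclasses import replace

            cell_cfg = replace(config, window_s=float(w), rate_hz=float(r))
            try:
                folds = run_loocv(subjects, cell_cfg, filter_spec)
            except ValidationError as err:
                log.warning("grid cell (%ss, %sHz) failed: %s", w, r, err)
                continue
            for fr in folds:
                for metric in METRIC_NAMES:
                    rows.append(
                        {
                            "subject_id": fr.held_out_subject,
                            "window_s": float(w),
                            "rate_hz": float(r),
                            "metric": metric,
                            "score": 100.0 * fr.metrics[metric],
                        }
                    )
    return pd.DataFrame(rows)


def cutoff_sensitivity(
    subjects: Mapping[str, tuple],
    high_cuts: Sequence[float] = (2, 5, 10, 15, 20),
    config: CnnConfig = CnnConfig(),
    low_hz: float = 0.05,
) -> pd.DataFrame:
    """Pooled weighted metrics of the CNN LOOCV per high-frequency cutoff."""
    native = min(s[0].sampling_rate_hz for s in subjects.values())
    rows = []
    for cut in high_cuts:
        if cut >= native / 2:
            raise ValidationError(
                f"cutoff {cut} Hz is not below the Nyquist frequency {native / 2} Hz"
            )
        spec = FilterSpec(low_hz=low_hz, high_hz=float(cut))
        folds = run_loocv(subjects, config, spec)
        y_true, y_pred = _pool_folds(folds)
        row = {"high_hz": float(cut)}
        row.update(weighted_metrics(y_true, y_pred))
        rows.append(row)
    return pd.DataFrame(rows)


def render_heatmaps(table: pd.DataFrame, outdir) -> list:
    """Mean-over-subjects heatmap PNG per metric (side artifact; CSV is primary)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for metric in METRIC_NAMES:
        sub = table[table["metric"] == metric]
        if sub.empty:
            continue
        pivot = sub.pivot_table(index="window_s", columns="rate_hz", values="score")
        fig, ax = plt.subplots(figsize=(5, 4))
        im = ax.imshow(pivot.to_numpy(), aspect="auto", origin="lower", cmap="viridis")
        ax.set_xticks(range(len(pivot.columns)), [f"{c:g}" for c in pivot.columns])
        ax.set_yticks(range(len(pivot.index)), [f"{i:g}" for i in pivot.index])
        ax.set_xlabel("sampling rate (Hz)")
        ax.set_ylabel("window size (s)")
        ax.set_title(f"weighted {metric} (%)")
        fig.colorbar(im, ax=ax)
        path = outdir / f"heatmap_{metric}.png"
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
        paths.append(path)
    return paths


# ---------------------------------------------------------------------------
# mixed-effects model
# ---------------------------------------------------------------------------


@dataclass
class MixedModelResult:
    """Fixed-effect table and subject random-intercept variance."""

    fixed_effects: pd.DataFrame  # term, beta, se, z, p, ci_low, ci_high
    group_var: float
    converged: bool
    singular: bool
    n_obs: int

    def to_dict(self) -> dict:
        return {
            "fixed_effects": self.fixed_effects.to_dict(orient="records"),
            "group_var": self.group_var,
            "converged": self.converged,
            "singular": self.singular,
            "n_obs": self.n_obs,
        }


def mixed_effects(
    table: pd.DataFrame,
    window_ref: float = 12.0,
    rate_ref: float = 50.0,
    metric_ref: str = "f1",
) -> MixedModelResult:
    """Fit score ~ window + rate + metric with a random intercept per subject.

    Scores are expected in percent.  Estimated by REML; Wald z tests and
    ±1.96·SE confidence intervals.  A singular random-effect fit is flagged,
    never silently accepted.
    """
    import statsmodels.formula.api as smf

    required = {"subject_id", "window_s", "rate_hz", "metric", "score"}
    if not required.issubset(table.columns):
        raise ValidationError(f"metric table must have columns {sorted(required)}")
    if table["subject_id"].nunique() < 3:
        raise ValidationError("mixed model needs at least 3 subjects")
    formula = (
        f"score ~ C(window_s, Treatment({window_ref})) "
        f"+ C(rate_hz, Treatment({rate_ref})) "
        f"+ C(metric, Treatment('{metric_ref}'))"
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(formula, data=table, groups=table["subject_id"])
        fit = model.fit(reml=True)
    k_fe = model.k_fe
    names = fit.model.exog_names[:k_fe]
    beta = np.asarray(fit.fe_params)
    se = np.asarray(fit.bse[:k_fe])
    z = beta / se
    from scipy import stats

    p = 2 * stats.norm.sf(np.abs(z))
    fixed = pd.DataFrame(
        {
            "term": names,
            "beta": beta,
            "se": se,
            "z": z,
            "p": p,
            "ci_low": beta - 1.96 * se,
            "ci_high": beta + 1.96 * se,
        }
    )
    group_var = float(np.asarray(fit.cov_re)[0, 0])
    singular = group_var < 1e-8
    if singular:
        log.warning("mixed model: singular random-effect fit (group variance ~ 0)")
    return MixedModelResult(
        fixed_effects=fixed,
        group_var=group_var,
        converged=bool(fit.converged),
        singular=singular,
        n_obs=len(table),
    )


# ---------------------------------------------------------------------------
# simulation for parameter-recovery checks
# ---------------------------------------------------------------------------


def simulate_scores(
    window_effects: Mapping[float, float],
    rate_effects: Mapping[float, float],
    metric_effects: Mapping[str, float] | None = None,
    n_subjects: int = 10,
    intercept: float = 85.0,
    subject_sd: float = 8.0,
    resid_sd: float = 3.0,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Draw a synthetic metric table with known additive fixed effects.

    Reference levels (effect 0) must be included in the mappings.  Used to
    verify that :func:`mixed_effects` recovers injected window/rate effects.
    """
    rng = rng or np.random.default_rng(0)
    metric_effects = metric_effects or dict.fromkeys(METRIC_NAMES, 0.0)
    rows = []
    for s in range(n_subjects):
        u = rng.normal(0.0, subject_sd)
        for w, bw in window_effects.items():
            for r, br in rate_effects.items():
                for m, bm in metric_effects.items():
                    rows.append(
                        {
                            "subject_id": f"sim{s:02d}",
                            "window_s": float(w),
                            "rate_hz": float(r),
                            "metric": m,
                            "score": intercept + u + bw + br + bm
                            + rng.normal(0.0, resid_sd),
                        }
                    )
    return pd.DataFrame(rows)


def recovery_simulation(
    n_replicates: int = 100,
    window_effects: Mapping[float, float] | None = None,
    rate_effects: Mapping[float, float] | None = None,
    n_subjects: int = 8,
    subject_sd: float = 8.0,
    resid_sd: float = 3.0,
    seed: int = 0,
) -> float:
    """Fraction of injected window/rate effects falling inside their 95% CI.

    Runs light replicates of :func:`simulate_scores` + :func:`mixed_effects`
    and returns the average CI coverage of the non-reference effects.
    """
    window_effects = window_effects or {12.0: 0.0, 5.0: -3.0, 1.0: -10.0}
    rate_effects = rate_effects or {50.0: 0.0, 5.0: -8.0}
    rng = np.random.default_rng(seed)
    hits = 0
    total = 0
    for _ in range(n_replicates):
        table = simulate_scores(
            window_effects, rate_effects,
            n_subjects=n_subjects, subject_sd=subject_sd, resid_sd=resid_sd, rng=rng,
        )
        res = mixed_effects(table)
        fe = res.fixed_effects.set_index("term")
        for label, effects, ref in (
            ("window_s", window_effects, 12.0),
            ("rate_hz", rate_effects, 50.0),
        ):
            for level, beta_true in effects.items():
                if level == ref:
                    continue
                term = f"C({label}, Treatment({ref}))[T.{level}]"
                row = fe.loc[term]
                hits += int(row["ci_low"] <= beta_true <= row["ci_high"])
                total += 1
    return hits / total
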