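"""Weighted metrics, pooling, confusion matrices, sweeps, mixed model."""

import numpy as np
import pandas as pd
import pytest

from actipatch import evaluation as ev
from actipatch.cnn_classifier import CnnConfig, FoldResult
from actipatch.io_formats import ACTIVITY_CLASSES, ValidationError

CLASSES = list(ACTIVITY_CLASSES)


def _random_labels(rng, n, k=3):
    pool = CLASSES[:k]
    return (
        rng.choice(pool, size=n).astype(object),
        rng.choice(pool, size=n).astype(object),
    )


def _brute_metrics(y_true, y_pred):
    """Independent confusion-count computation of the weighted metrics."""
    n = len(y_true)
    acc = np.mean(y_true == y_pred)
    prec = rec = f1 = 0.0
    for c in CLASSES:
        support = np.sum(y_true == c)
        if support == 0:
            continue
        tp = np.sum((y_true == c) & (y_pred == c))
        predicted = np.sum(y_pred == c)
        p_c = tp / predicted if predicted else 0.0
        r_c = tp / support
        f_c = 2 * p_c * r_c / (p_c + r_c) if p_c + r_c else 0.0
        w = support / n
        prec += w * p_c
        rec += w * r_c
        f1 += w * f_c
    return {"accuracy": acc, "precision": prec, "recall": rec, "f1": f1}


class TestWeightedMetrics:
    def test_perfect_predictions(self):
        y = np.array(["lying", "sitting", "walking"] * 4, dtype=object)
        m = ev.weighted_metrics(y, y)
        assert all(v == 1.0 for v in m.values())

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        y_true, y_pred = _random_labels(rng, int(rng.integers(5, 60)))
        got = ev.weighted_metrics(y_true, y_pred)
        want = _brute_metrics(y_true, y_pred)
        for k in want:
            assert got[k] == pytest.approx(want[k], abs=1e-12)

    @pytest.mark.parametrize("seed", range(10))
    def test_weighted_recall_equals_accuracy(self, seed):
        rng = np.random.default_rng(100 + seed)
        y_true, y_pred = _random_labels(rng, 40, k=5)
        m = ev.weighted_metrics(y_true, y_pred)
        assert m["recall"] == pytest.approx(m["accuracy"], abs=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            ev.weighted_metrics([], [])


def _fold(y_true, y_pred, sid="s"):
    y_true = np.asarray(y_true, dtype=object)
    y_pred = np.asarray(y_pred, dtype=object)
    n = len(y_true)
    return FoldResult(sid, y_true, y_pred, np.full((n, 5), 0.2))


class TestPerClassF1:
    def test_single_fold_matches_direct(self):
        rng = np.random.default_rng(0)
        y_true, y_pred = _random_labels(rng, 30, k=5)
        fold = _fold(y_true, y_pred)
        got = ev.per_class_f1([fold])
        from sklearn.metrics import f1_score

        want = f1_score(y_true, y_pred, labels=CLASSES, average=None, zero_division=0)
        for c, w in zip(CLASSES, want):
            assert got[c] == pytest.approx(w)

    def test_pooled_between_fold_values(self):
        # one perfect fold, one all-wrong fold with disjoint errors
        f1 = _fold(["walking"] * 10, ["walking"] * 10, "a")
        f2 = _fold(["walking"] * 10, ["sitting"] * 10, "b")
        pooled = ev.per_class_f1([f1, f2])
        assert 0.0 < pooled["walking"] < 1.0

    def test_absent_class_is_nan(self):
        out = ev.per_class_f1([_fold(["sitting"] * 5, ["sitting"] * 5)])
        assert np.isnan(out["jogging"])

    def test_perfect_folds_all_ones(self):
        folds = [_fold(CLASSES * 2, CLASSES * 2, s) for s in "ab"]
        assert all(v == 1.0 for v in ev.per_class_f1(folds).values())


class TestConfusionMatrix:
    def test_row_sums_are_supports_and_trace_is_accuracy(self):
        rng = np.random.default_rng(1)
        y_true, y_pred = _random_labels(rng, 50, k=5)
        cm = ev.confusion_matrix(y_true, y_pred)
        for c in CLASSES:
            assert cm.loc[c].sum() == np.sum(y_true == c)
        acc = np.trace(cm.to_numpy()) / 50
        assert acc == pytest.approx(ev.weighted_metrics(y_true, y_pred)["accuracy"])

    def test_constant_prediction_fills_one_column(self):
        y_true = np.array(CLASSES * 3, dtype=object)
        y_pred = np.array(["lying"] * 15, dtype=object)
        cm = ev.confusion_matrix(y_true, y_pred)
        assert cm["lying"].sum() == 15
        assert cm.drop(columns="lying").to_numpy().sum() == 0


class TestMixedEffects:
    def test_recovers_known_effects(self):
        rng = np.random.default_rng(42)
        table = ev.simulate_scores(
            {12.0: 0.0, 1.0: -10.0}, {50.0: 0.0, 5.0: -8.0},
            n_subjects=10, subject_sd=8.0, resid_sd=2.0, rng=rng,
        )
        res = ev.mixed_effects(table)
        fe = res.fixed_effects.set_index("term")
        w = fe.loc["C(window_s, Treatment(12.0))[T.1.0]"]
        r = fe.loc["C(rate_hz, Treatment(50.0))[T.5.0]"]
        assert w["ci_low"] <= -10.0 <= w["ci_high"]
        assert r["ci_low"] <= -8.0 <= r["ci_high"]
        assert res.group_var > 10.0  # subject variance is found

    def test_metric_contrasts_identical_when_recall_equals_accuracy(self):
        rng = np.random.default_rng(3)
        rows = []
        for s in range(6):
            for w in (5.0, 12.0):
                base = 80 + rng.normal(0, 5)
                scores = {"f1": base, "precision": base + 5,
                          "accuracy": base - 3, "recall": base - 3}
                for m, v in scores.items():
                    rows.append({"subject_id": f"s{s}", "window_s": w,
                                 "rate_hz": 50.0, "metric": m, "score": v})
        res = ev.mixed_effects(pd.DataFrame(rows))
        fe = res.fixed_effects.set_index("term")
        acc = fe.loc["C(metric, Treatment('f1'))[T.accuracy]", "beta"]
        rec = fe.loc["C(metric, Treatment('f1'))[T.recall]", "beta"]
        assert acc == pytest.approx(rec, abs=1e-8)

    def test_zero_effect_type_i_calibration(self):
        rng = np.random.default_rng(7)
        n_sig = 0
        total = 0
        for _ in range(15):
            table = ev.simulate_scores(
                {12.0: 0.0, 5.0: 0.0}, {50.0: 0.0, 25.0: 0.0},
                n_subjects=8, resid_sd=3.0, rng=rng,
            )
            fe = ev.mixed_effects(table).fixed_effects
            contrasts = fe[fe["term"].str.contains("window_s|rate_hz")]
            n_sig += int((np.abs(contrasts["z"]) >= 1.96).sum())
            total += len(contrasts)
        assert n_sig / total < 0.15  # ~5% nominal

    def test_too_few_subjects_rejected(self):
        table = ev.simulate_scores({12.0: 0.0}, {50.0: 0.0}, n_subjects=2)
        with pytest.raises(ValidationError, match="3 subjects"):
            ev.mixed_effects(table)


@pytest.fixture(scope="module")
def tiny_subjects(tiny_cohort):
    return {sid: (rec, lab) for sid, (rec, lab, _hr) in tiny_cohort.items()}


class TestSweeps:
    def test_grid_cardinality_and_scores_in_percent(self, tiny_subjects):
        cfg = CnnConfig(epochs=2, seed=0)
        table = ev.sensitivity_grid(
            tiny_subjects, windows=(2, 5), rates=(25, 50), config=cfg
        )
        assert len(table) == 2 * 2 * len(tiny_subjects) * 4
        assert table["score"].between(0, 100).all()
        assert set(table["metric"]) == set(ev.METRIC_NAMES)

    def test_grid_cell_reproduces_standalone_loocv(self, tiny_subjects):
        cfg = CnnConfig(epochs=2, seed=0)
        table = ev.sensitivity_grid(tiny_subjects, windows=(5,), rates=(50,), config=cfg)
        folds = ev.run_loocv(tiny_subjects, CnnConfig(window_s=5.0, rate_hz=50.0,
                                                      epochs=2, seed=0))
        for fr in folds:
            cell = table[(table.subject_id == fr.held_out_subject) & (table.metric == "f1")]
            assert cell["score"].iloc[0] == pytest.approx(100 * fr.metrics["f1"])

    def test_cutoff_sweep_rows_and_nyquist_guard(self, tiny_subjects):
        cfg = CnnConfig(epochs=2, seed=0)
        table = ev.cutoff_sensitivity(tiny_subjects, high_cuts=(2.0, 10.0), config=cfg)
        assert list(table["high_hz"]) == [2.0, 10.0]
        with pytest.raises(ValidationError, match="Nyquist"):
            ev.cutoff_sensitivity(tiny_subjects, high_cuts=(25.0,), config=cfg)

    def test_heatmaps_rendered(self, tiny_subjects, tmp_path):
        cfg = CnnConfig(epochs=1, seed=0)
        table = ev.sensitivity_grid(tiny_subjects, windows=(5,), rates=(50,), config=cfg)
        paths = ev.render_heatmaps(table, tmp_path)
        assert len(paths) == 4 and all(p.exists() for p in paths)
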