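"""Five-class 1D-CNN activity classifier with leave-one-subject-out evaluation.

The reference architecture maps a (window_len x 3) acceleration window to
five class probabilities through stacked 1-D convolution blocks
(convolution -> ReLU -> optional max-pool), global average pooling over
time, one dense hidden layer with dropout, and a softmax output.  Training
minimizes class-weighted cross-entropy with inverse-frequency weights
(w_c = N / (K * N_c)) so underrepresented activities contribute
proportionally, using Adam.  Per-channel standardization statistics are
computed on the training fold only and stored with the model, which keeps
leave-one-subject-out folds leakage-free by construction.

The network is implemented directly on NumPy (im2col convolutions and
hand-written backpropagation); everything — architecture, epochs, batch
size, learning rate, dropout, seed — is driven by :class:`CnnConfig` and
fully deterministic given the seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .io_formats import ACTIVITY_CLASSES, ValidationError

log = logging.getLogger(__name__)

CLASS_TO_INDEX = {c: i for i, c in enumerate(ACTIVITY_CLASSES)}

#: Minimum samples per window for the default conv stack.
MIN_WINDOW_SAMPLES = 8


@dataclass(frozen=True)
class CnnConfig:
    window_s: float = 5.0
    rate_hz: float = 50.0
    #: (filters, kernel, pool) per block.  The first kernel spans 0.22 s at
    #: 50 Hz so early layers can resolve the 1-3 Hz structure that separates
    #: gait and posture signatures.
    conv_blocks: tuple = ((32, 11, 2), (64, 7, 2), (64, 3, 0))
    dense_units: int = 64
    dropout: float = 0.3
    epochs: int = 30
    batch_size: int = 64
    learning_rate: float = 1e-3
    seed: int = 0

    @property
    def window_len(self) -> int:
        return int(round(self.window_s * self.rate_hz))

    def validate(self) -> "CnnConfig":
        if self.window_len < MIN_WINDOW_SAMPLES:
            raise ValidationError(
                f"window of {self.window_len} samples is too short for the conv "
                f"stack (need >= {MIN_WINDOW_SAMPLES}); use a longer window, a higher "
                "rate, or smaller kernels"
            )
        for f, k, p in self.conv_blocks:
            if f < 1 or k < 1 or p < 0:
                raise ValidationError("conv_blocks entries must be positive")
        if not (0 <= self.dropout < 1):
            raise ValidationError("dropout must be in [0, 1)")
        if min(self.dense_units, self.epochs, self.batch_size) < 1:
            raise ValidationError("dense_units, epochs and batch_size must be positive")
        return self


def class_weights(labels: Sequence[str]) -> dict:
    """Inverse-frequency weights w_c = N_total / (K_present * N_c).

    Classes absent from the labels get weight 0 (and are logged); the
    identity w_c * N_c = N / K holds across present classes.
    """
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValidationError("cannot compute class weights for an empty label set")
    total = labels.size
    counts = {c: int(np.sum(labels == c)) for c in ACTIVITY_CLASSES}
    present = [c for c, n in counts.items() if n > 0]
    weights = {}
    for c in ACTIVITY_CLASSES:
        if counts[c] > 0:
            weights[c] = total / (len(present) * counts[c])
        else:
            weights[c] = 0.0
            log.info("class %r absent from training labels; weight set to 0", c)
    return weights


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(B, L, C) -> (B, L, C*k) patches with same-length zero padding."""
    b, l, c = x.shape
    pl = (k - 1) // 2
    xp = np.zeros((b, l + k - 1, c), dtype=x.dtype)
    xp[:, pl : pl + l] = x
    v = sliding_window_view(xp, k, axis=1)  # (B, L, C, k)
    return np.ascontiguousarray(v).reshape(b, l, c * k)


def _col2im(dcol: np.ndarray, k: int, l: int, c: int) -> np.ndarray:
    """Adjoint of :func:`_im2col`."""
    b = dcol.shape[0]
    pl = (k - 1) // 2
    d4 = dcol.reshape(b, l, c, k)
    dxp = np.zeros((b, l + k - 1, c), dtype=dcol.dtype)
    for j in range(k):
        dxp[:, j : j + l] += d4[:, :, :, j]
    return dxp[:, pl : pl + l]


class Cnn1d:
    """The NumPy 1-D CNN.  Build via :func:`build_model`."""

    def __init__(self, config: CnnConfig, n_channels: int = 3, n_classes: int = 5):
        config.validate()
        self.config = config
        self.n_channels = n_channels
        self.n_classes = n_classes
        self.norm_mean = np.zeros(n_channels, dtype=np.float32)
        self.norm_std = np.ones(n_channels, dtype=np.float32)
        rng = np.random.default_rng(config.seed)
        self.params: dict[str, np.ndarray] = {}
        c = n_channels
        for i, (f, k, _p) in enumerate(config.conv_blocks):
            self.params[f"convW{i}"] = rng.normal(
                0.0, np.sqrt(2.0 / (c * k)), size=(c * k, f)
            ).astype(np.float32)
            self.params[f"convb{i}"] = np.zeros(f, dtype=np.float32)
            c = f
        self.params["W1"] = rng.normal(
            0.0, np.sqrt(2.0 / c), size=(c, config.dense_units)
        ).astype(np.float32)
        self.params["b1"] = np.zeros(config.dense_units, dtype=np.float32)
        self.params["W2"] = rng.normal(
            0.0, np.sqrt(2.0 / config.dense_units), size=(config.dense_units, n_classes)
        ).astype(np.float32)
        self.params["b2"] = np.zeros(n_classes, dtype=np.float32)
        self._adam_m = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_v = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_t = 0

    @property
    def n_parameters(self) -> int:
        return sum(int(v.size) for v in self.params.values())

    # -- forward / backward -------------------------------------------------

    def _standardize(self, x: np.ndarray) -> np.ndarray:
        return ((x - self.norm_mean) / self.norm_std).astype(np.float32)

    def _forward(self, x: np.ndarray, train: bool = False, rng=None):
        cache = {"conv": []}
        h = x
        for i, (f, k, p) in enumerate(self.config.conv_blocks):
            col = _im2col(h, k)
            z = col @ self.params[f"convW{i}"] + self.params[f"convb{i}"]
            a = np.maximum(z, 0.0)
            blk = {"in_shape": h.shape, "col": col, "relu_mask": z > 0, "pool": None}
            if p >= 2:
                b, l, ch = a.shape
                lp = (l // p) * p
                ar = a[:, :lp].reshape(b, l // p, p, ch)
                idx = ar.argmax(axis=2)
                a = np.take_along_axis(ar, idx[:, :, None, :], axis=2)[:, :, 0, :]
                blk["pool"] = (idx, l, ch, p)
            cache["conv"].append(blk)
            h = a
        cache["gap_len"] = h.shape[1]
        g = h.mean(axis=1)
        z1 = g @ self.params["W1"] + self.params["b1"]
        a1 = np.maximum(z1, 0.0)
        if train and self.config.dropout > 0:
            mask = (rng.random(a1.shape) >= self.config.dropout).astype(np.float32)
            a1d = a1 * mask / (1.0 - self.config.dropout)
        else:
            mask = None
            a1d = a1
        logits = a1d @ self.params["W2"] + self.params["b2"]
        logits = logits - logits.max(axis=1, keepdims=True)
        e = np.exp(logits)
        probs = e / e.sum(axis=1, keepdims=True)
        cache.update(g=g, relu1=z1 > 0, a1d=a1d, mask=mask, probs=probs)
        return probs, cache

    def _backward(self, cache, dlogits) -> dict:
        grads = {}
        grads["W2"] = cache["a1d"].T @ dlogits
        grads["b2"] = dlogits.sum(axis=0)
        da1 = dlogits @ self.params["W2"].T
        if cache["mask"] is not None:
            da1 = da1 * cache["mask"] / (1.0 - self.config.dropout)
        dz1 = da1 * cache["relu1"]
        grads["W1"] = cache["g"].T @ dz1
        grads["b1"] = dz1.sum(axis=0)
        dg = dz1 @ self.params["W1"].T
        l_gap = cache["gap_len"]
        dh = np.repeat(dg[:, None, :] / l_gap, l_gap, axis=1)
        for i in range(len(self.config.conv_blocks) - 1, -1, -1):
            blk = cache["conv"][i]
            _f, k, _p = self.config.conv_blocks[i]
            if blk["pool"] is not None:
                idx, l, ch, p = blk["pool"]
                b = dh.shape[0]
                dar = np.zeros((b, l // p, p, ch), dtype=dh.dtype)
                np.put_along_axis(dar, idx[:, :, None, :], dh[:, :, None, :], axis=2)
                da = np.zeros((b, l, ch), dtype=dh.dtype)
                da[:, : (l // p) * p] = dar.reshape(b, (l // p) * p, ch)
            else:
                da = dh
            dz = da * blk["relu_mask"]
            col = blk["col"]
            grads[f"convW{i}"] = (
                col.reshape(-1, col.shape[2]).T @ dz.reshape(-1, dz.shape[2])
            )
            grads[f"convb{i}"] = dz.sum(axis=(0, 1))
            dcol = dz @ self.params[f"convW{i}"].T
            _b, l_in, c_in = blk["in_shape"]
            dh = _col2im(dcol, k, l_in, c_in)
        return grads

    def _adam_step(self, grads, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self._adam_t += 1
        t = self._adam_t
        for k, g in grads.items():
            m = self._adam_m[k]
            v = self._adam_v[k]
            m += (1 - beta1) * (g - m)
            v += (1 - beta2) * (g * g - v)
            mhat = m / (1 - beta1**t)
            vhat = v / (1 - beta2**t)
            self.params[k] -= lr * mhat / (np.sqrt(vhat) + eps)

    # -- persistence --------------------------------------------------------

    def state_dict(self) -> dict:
        out = {f"param_{k}": v for k, v in self.params.items()}
        out["norm_mean"] = self.norm_mean
        out["norm_std"] = self.norm_std
        return out

    def save(self, path) -> None:
        np.savez(path, **self.state_dict())

    def load_state(self, state: Mapping[str, np.ndarray]) -> None:
        for k in self.params:
            self.params[k] = np.asarray(state[f"param_{k}"], dtype=np.float32)
        self.norm_mean = np.asarray(state["norm_mean"], dtype=np.float32)
        self.norm_std = np.asarray(state["norm_std"], dtype=np.float32)


def build_model(config: CnnConfig, n_channels: int = 3, n_classes: int = 5) -> Cnn1d:
    """Construct an untrained model; same config and seed give identical weights."""
    return Cnn1d(config, n_channels=n_channels, n_classes=n_classes)


# ---------------------------------------------------------------------------
# training / inference
# ---------------------------------------------------------------------------


def _encode_labels(labels: Sequence[str]) -> np.ndarray:
    try:
        return np.array([CLASS_TO_INDEX[l] for l in labels], dtype=np.int64)
    except KeyError as err:
        raise ValidationError(f"label {err.args[0]!r} outside the activity vocabulary") from None


def train(model: Cnn1d, windows: np.ndarray, labels: Sequence[str],
          config: CnnConfig | None = None) -> tuple[Cnn1d, list]:
    """Train in place; returns (model, per-epoch mean loss history).

    Standardization statistics are fit on ``windows`` (the training fold)
    and stored on the model.
    """
    config = config or model.config
    X = np.asarray(windows, dtype=np.float32)
    if X.ndim != 3 or X.shape[1] != config.window_len or X.shape[2] != model.n_channels:
        raise ValidationError(
            f"training windows of shape {X.shape} do not match the model input "
            f"({config.window_len} x {model.n_channels})"
        )
    y = _encode_labels(labels)
    if np.unique(y).size < 2:
        raise ValidationError("cannot train on single-class data")
    model.norm_mean = X.mean(axis=(0, 1)).astype(np.float32)
    model.norm_std = np.maximum(X.std(axis=(0, 1)), 1e-6).astype(np.float32)
    Xs = model._standardize(X)
    cw = class_weights(np.asarray(labels))
    w = np.array([cw[ACTIVITY_CLASSES[i]] for i in y], dtype=np.float32)
    rng = np.random.default_rng(config.seed + 1)
    n = len(y)
    history = []
    for _epoch in range(config.epochs):
        order = rng.permutation(n)
        losses = []
        for i0 in range(0, n, config.batch_size):
            idx = order[i0 : i0 + config.batch_size]
            xb, yb, wb = Xs[idx], y[idx], w[idx]
            probs, cache = model._forward(xb, train=True, rng=rng)
            p_true = np.clip(probs[np.arange(len(yb)), yb], 1e-12, None)
            loss = float(np.mean(wb * -np.log(p_true)))
            losses.append(loss)
            dlogits = probs.copy()
            dlogits[np.arange(len(yb)), yb] -= 1.0
            dlogits *= wb[:, None] / len(yb)
            grads = model._backward(cache, dlogits.astype(np.float32))
            model._adam_step(grads, config.learning_rate)
        history.append(float(np.mean(losses)))
    return model, history


def predict(model: Cnn1d, windows: np.ndarray, batch_size: int = 512):
    """Per-window class probabilities and argmax labels.

    Ties in the probabilities break toward the earlier class in the
    canonical order (lying < sitting < standing < walking < jogging).
    """
    X = np.asarray(windows, dtype=np.float32)
    if X.ndim != 3 or X.shape[1] != model.config.window_len or X.shape[2] != model.n_channels:
        raise ValidationError(
            f"windows of shape {X.shape} do not match the model input "
            f"({model.config.window_len} x {model.n_channels})"
        )
    Xs = model._standardize(X)
    chunks = []
    for i0 in range(0, len(Xs), batch_size):
        probs, _ = model._forward(Xs[i0 : i0 + batch_size], train=False)
        chunks.append(probs)
    probs = np.concatenate(chunks) if chunks else np.empty((0, model.n_classes))
    idx = probs.argmax(axis=1)
    labels = np.array([ACTIVITY_CLASSES[i] for i in idx], dtype=object)
    return probs, labels


# ---------------------------------------------------------------------------
# leave-one-subject-out cross-validation
# ---------------------------------------------------------------------------


@dataclass
class FoldResult:
    """Predictions and weighted metrics for one held-out subject."""

    held_out_subject: str
    y_true: np.ndarray
    y_pred: np.ndarray
    probabilities: np.ndarray
    metrics: dict = field(default_factory=dict)
    loss_history: list = field(default_factory=list)


def loocv(cohort: Mapping[str, tuple], config: CnnConfig,
          keep_models: bool = False) -> list[FoldResult]:
    """Leave-one-subject-out cross-validation.

    ``cohort`` maps subject id to (windows, labels).  One fold per subject;
    the held-out subject's windows never enter that fold's training set or
    standardization statistics.  The fold trained with seed
    ``config.seed + fold_index`` (subjects in sorted order).
    """
    subjects = sorted(cohort)
    if len(subjects) < 3:
        raise ValidationError("LOOCV needs at least 3 subjects")
    from .evaluation import weighted_metrics  # local import: evaluation drives loocv too

    results = []
    for fold_idx, held_out in enumerate(subjects):
        X_test, y_test = cohort[held_out]
        if len(y_test) == 0:
            log.warning("subject %s has no retained windows; fold skipped", held_out)
            continue
        X_train = np.concatenate([cohort[s][0] for s in subjects if s != held_out])
        y_train = np.concatenate(
            [np.asarray(cohort[s][1], dtype=object) for s in subjects if s != held_out]
        )
        fold_config = replace(config, seed=config.seed + fold_idx)
        model = build_model(fold_config)
        model, history = train(model, X_train, y_train, fold_config)
        probs, y_pred = predict(model, np.asarray(X_test, dtype=np.float32))
        fr = FoldResult(
            held_out_subject=held_out,
            y_true=np.asarray(y_test, dtype=object),
            y_pred=y_pred,
            probabilities=probs,
            metrics=weighted_metrics(y_test, y_pred),
            loss_history=history,
        )
        if keep_models:
            fr.model = model  # type: ignore[attr-defined]
        results.append(fr)
    return results
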