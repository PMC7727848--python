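"""Two-layer stacked LSTM emotion classifier.

Architecture: ``LSTM(input_dim -> hidden) -> LSTM(hidden -> hidden) ->
last time step -> dropout -> fully connected (hidden -> num_classes) ->
softmax``.  No batch normalization anywhere; inputs (correlations in
[-1, 1]) are used unnormalized.

Implemented directly on NumPy: forward pass, full backpropagation through
time, and RMSProp.  Training is bitwise-reproducible under a fixed seed.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .features import FeatureSequence, LabeledExample, examples_to_arrays

__all__ = [
    "ModelConfig",
    "TrainConfig",
    "TrainedModel",
    "build_model",
    "train",
    "predict",
    "predict_batch",
    "extract_emotional_features",
]

_GATES = 4  # input, forget, cell, output


@dataclass(frozen=True)
class ModelConfig:
    input_dim: int
    num_classes: int
    hidden_dim: int = 256
    dropout_p: float = 0.5
    num_lstm_layers: int = 2

    def __post_init__(self) -> None:
        if self.input_dim < 1:
            raise ValueError("input_dim must be >= 1")
        if self.hidden_dim < 1:
            raise ValueError("hidden_dim must be >= 1")
        if self.num_classes < 2:
            raise ValueError("num_classes must be >= 2")
        if not 0.0 <= self.dropout_p < 1.0:
            raise ValueError("dropout_p must be in [0, 1)")
        if self.num_lstm_layers != 2:
            raise ValueError("the architecture is a two-layer stacked LSTM")


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 0.001
    batch_size: int = 240
    max_epochs: int = 30
    optimizer: str = "rmsprop"
    seed: int = 0
    early_stop_patience: int | None = None
    # RMSProp defaults (not specified beyond the learning rate; these are
    # the common framework defaults and are recorded in the training log).
    rms_decay: float = 0.9
    rms_epsilon: float = 1e-7

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.optimizer != "rmsprop":
            raise ValueError(f"unsupported optimizer {self.optimizer!r}")


@dataclass
class TrainedModel:
    """Model parameters plus config and per-epoch training log."""

    params: dict[str, np.ndarray]
    config: ModelConfig
    training_log: list[dict] = field(default_factory=list)
    seed: int = 0

    def save_log(self, path: str | Path) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        if not self.training_log:
            path.write_text("")
            return
        with open(path, "w", newline="") as f:
            writer = csv.DictWriter(f, fieldnames=list(self.training_log[0]))
            writer.writeheader()
            writer.writerows(self.training_log)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


def _orthogonal(rng: np.random.Generator, n: int, cols: int) -> np.ndarray:
    """Block-orthogonal recurrent initializer: ``cols/n`` orthogonal blocks."""
    blocks = []
    for _ in range(cols // n):
        a = rng.standard_normal((n, n))
        q, r = np.linalg.qr(a)
        q *= np.sign(np.diag(r))
        blocks.append(q)
    return np.concatenate(blocks, axis=1)


def build_model(config: ModelConfig, seed: int = 0) -> TrainedModel:
    """Initialize an untrained model.

    Kernels are Glorot-uniform, recurrent weights orthogonal, biases zero
    except the forget gate (1.0), all drawn from ``seed``.
    """
    rng = np.random.default_rng(seed)
    H = config.hidden_dim
    params: dict[str, np.ndarray] = {}
    for layer, in_dim in enumerate([config.input_dim, H]):
        params[f"W{layer}"] = _glorot(rng, in_dim, _GATES * H)
        params[f"U{layer}"] = _orthogonal(rng, H, _GATES * H)
        b = np.zeros(_GATES * H)
        b[H : 2 * H] = 1.0  # forget-gate bias
        params[f"b{layer}"] = b
    params["Wfc"] = _glorot(rng, H, config.num_classes)
    params["bfc"] = np.zeros(config.num_classes)
    return TrainedModel(params=params, config=config, seed=seed)


def _lstm_forward(x, W, U, b):
    """Run one LSTM layer over a batch.

    Parameters: ``x`` (B, N, D), kernel ``W`` (D, 4H), recurrent ``U``
    (H, 4H), bias ``b`` (4H,).  Returns hidden states (B, N, H) and the
    per-step cache needed for backprop.
    """
    B, N, _ = x.shape
    H = U.shape[0]
    h = np.zeros((B, N, H))
    h_prev = np.zeros((B, H))
    c_prev = np.zeros((B, H))
    cache = []
    for t in range(N):
        z = x[:, t] @ W + h_prev @ U + b
        i = _sigmoid(z[:, :H])
        f = _sigmoid(z[:, H : 2 * H])
        g = np.tanh(z[:, 2 * H : 3 * H])
        o = _sigmoid(z[:, 3 * H :])
        c = f * c_prev + i * g
        tc = np.tanh(c)
        h[:, t] = o * tc
        cache.append((x[:, t], h_prev, c_prev, i, f, g, o, tc))
        h_prev = h[:, t]
        c_prev = c
    return h, cache


def _lstm_backward(dh_out, cache, W, U):
    """Backprop one LSTM layer.

    ``dh_out`` (B, N, H) is the gradient w.r.t. the layer's hidden states
    from above.  Returns (dx, dW, dU, db).
    """
    B, N, H = dh_out.shape
    dW = np.zeros_like(W)
    dU = np.zeros_like(U)
    db = np.zeros(U.shape[1])
    dx = np.empty((B, N, W.shape[0]))
    dh_next = np.zeros((B, H))
    dc_next = np.zeros((B, H))
    for t in range(N - 1, -1, -1):
        x_t, h_prev, c_prev, i, f, g, o, tc = cache[t]
        dh = dh_out[:, t] + dh_next
        do = dh * tc
        dc = dh * o * (1.0 - tc * tc) + dc_next
        di = dc * g
        df = dc * c_prev
        dg = dc * i
        dc_next = dc * f
        dz = np.concatenate(
            [
                di * i * (1.0 - i),
                df * f * (1.0 - f),
                dg * (1.0 - g * g),
                do * o * (1.0 - o),
            ],
            axis=1,
        )
        dW += x_t.T @ dz
        dU += h_prev.T @ dz
        db += dz.sum(axis=0)
        dx[:, t] = dz @ W.T
        dh_next = dz @ U.T
    return dx, dW, dU, db


def _forward(params, X, dropout_mask=None):
    """Full forward pass; returns (probs, caches) for a (B, N, D) batch."""
    h1, cache1 = _lstm_forward(X, params["W0"], params["U0"], params["b0"])
    h2, cache2 = _lstm_forward(h1, params["W1"], params["U1"], params["b1"])
    last = h2[:, -1]
    dropped = last * dropout_mask if dropout_mask is not None else last
    logits = dropped @ params["Wfc"] + params["bfc"]
    logits = logits - logits.max(axis=1, keepdims=True)
    ex = np.exp(logits)
    probs = ex / ex.sum(axis=1, keepdims=True)
    return probs, (cache1, cache2, h2.shape, dropped)


def _backward(params, X, probs, y_onehot, caches, dropout_mask=None):
    """Cross-entropy gradient for all parameters (mean over the batch)."""
    cache1, cache2, h2_shape, dropped = caches
    B, N, H = h2_shape
    dlogits = (probs - y_onehot) / B
    grads = {
        "Wfc": dropped.T @ dlogits,
        "bfc": dlogits.sum(axis=0),
    }
    dlast = dlogits @ params["Wfc"].T
    if dropout_mask is not None:
        dlast = dlast * dropout_mask
    dh2 = np.zeros((B, N, H))
    dh2[:, -1] = dlast
    dh1, grads["W1"], grads["U1"], grads["b1"] = _lstm_backward(
        dh2, cache2, params["W1"], params["U1"]
    )
    _, grads["W0"], grads["U0"], grads["b0"] = _lstm_backward(
        dh1, cache1, params["W0"], params["U0"]
    )
    return grads


def _loss(probs: np.ndarray, y: np.ndarray) -> float:
    return float(-np.log(np.clip(probs[np.arange(len(y)), y], 1e-12, None)).mean())


def train(
    model: TrainedModel,
    examples: list[LabeledExample] | tuple[np.ndarray, np.ndarray],
    cfg: TrainConfig,
    validation: tuple[np.ndarray, np.ndarray] | None = None,
) -> TrainedModel:
    """Train in place with RMSProp on mini-batches of shuffled examples.

    ``examples`` is either a list of :class:`LabeledExample` or a
    pre-stacked ``(X, y)`` pair.  With ``validation`` and
    ``early_stop_patience`` set, the parameters giving the best validation
    loss are restored at the end.
    """
    X, y = examples if isinstance(examples, tuple) else examples_to_arrays(examples)
    cfgm = model.config
    if X.ndim != 3 or X.shape[2] != cfgm.input_dim:
        raise ValueError(
            f"input shape {X.shape} does not match input_dim {cfgm.input_dim}"
        )
    if y.min() < 0 or y.max() >= cfgm.num_classes:
        raise ValueError("label out of range for num_classes")
    rng = np.random.default_rng(cfg.seed)
    eye = np.eye(cfgm.num_classes)
    rms = {k: np.zeros_like(v) for k, v in model.params.items()}
    n = len(X)
    best_val = np.inf
    best_params = None
    stall = 0
    for epoch in range(cfg.max_epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        epoch_hits = 0
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            Xb, yb = X[idx], y[idx]
            mask = None
            if cfgm.dropout_p > 0:
                keep = 1.0 - cfgm.dropout_p
                mask = (
                    rng.random((len(idx), cfgm.hidden_dim)) < keep
                ).astype(float) / keep
            probs, caches = _forward(model.params, Xb, mask)
            grads = _backward(model.params, Xb, probs, eye[yb], caches, mask)
            for k, g in grads.items():
                rms[k] = cfg.rms_decay * rms[k] + (1.0 - cfg.rms_decay) * g * g
                model.params[k] -= (
                    cfg.learning_rate * g / (np.sqrt(rms[k]) + cfg.rms_epsilon)
                )
            epoch_loss += _loss(probs, yb) * len(idx)
            epoch_hits += int((probs.argmax(axis=1) == yb).sum())
        record = {
            "epoch": epoch,
            "loss": epoch_loss / n,
            "accuracy": epoch_hits / n,
            "learning_rate": cfg.learning_rate,
            "rms_decay": cfg.rms_decay,
            "rms_epsilon": cfg.rms_epsilon,
        }
        if validation is not None:
            vp = predict_batch(model, validation[0])
            record["val_loss"] = _loss(vp, validation[1])
            record["val_accuracy"] = float(
                (vp.argmax(axis=1) == validation[1]).mean()
            )
            if record["val_loss"] < best_val:
                best_val = record["val_loss"]
                best_params = {k: v.copy() for k, v in model.params.items()}
                stall = 0
            else:
                stall += 1
        model.training_log.append(record)
        if (
            cfg.early_stop_patience is not None
            and validation is not None
            and stall > cfg.early_stop_patience
        ):
            break
    if best_params is not None:
        model.params = best_params
    return model


def predict_batch(model: TrainedModel, X: np.ndarray) -> np.ndarray:
    """Class probabilities for a (B, N, input_dim) batch; dropout disabled."""
    if X.ndim != 3 or X.shape[2] != model.config.input_dim:
        raise ValueError(
            f"input shape {X.shape} does not match input_dim "
            f"{model.config.input_dim}"
        )
    probs, _ = _forward(model.params, X)
    return probs


def predict(model: TrainedModel, seq: FeatureSequence | np.ndarray) -> np.ndarray:
    """Class probabilities for one feature sequence."""
    v = seq.vectors if isinstance(seq, FeatureSequence) else np.asarray(seq)
    return predict_batch(model, v[None])[0]


def extract_emotional_features(
    model: TrainedModel, seq: FeatureSequence | np.ndarray
) -> np.ndarray:
    """Last-time-step hidden state of the second LSTM layer (before
    dropout and the fully connected head); length ``hidden_dim``."""
    v = seq.vectors if isinstance(seq, FeatureSequence) else np.asarray(seq)
    if v.ndim == 2:
        v = v[None]
    if v.shape[2] != model.config.input_dim:
        raise ValueError("input dim mismatch")
    h1, _ = _lstm_forward(v, model.params["W0"], model.params["U0"], model.params["b0"])
    h2, _ = _lstm_forward(h1, model.params["W1"], model.params["U1"], model.params["b1"])
    out = h2[:, -1]
    return out[0] if out.shape[0] == 1 else out
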