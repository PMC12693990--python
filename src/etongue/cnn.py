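"""A self-contained NumPy 1D-CNN for multichannel voltammetric signals.

Architecture (fixed defaults): four convolution stages with 32/32/64/64
kernels of sizes 16/8/4/2, all stride 2, ReLU activation and 'same' padding,
each followed by max pooling of size 2 and stride 1 ('valid'); then flatten,
dropout 0.3 and a dense softmax head with one unit per vintage class.
Training minimizes categorical cross-entropy with Adam at learning rate 0.001,
batch size 32.  For a 10080 x 1 input the sequence lengths evolve
10080 -> 5040 -> 5039 -> 2520 -> 2519 -> 1260 -> 1259 -> 630 -> 629
(convolutions halve with ceiling; each pool shrinks by one).

The engine is deliberately small: im2col convolutions backed by BLAS matrix
products in float32, explicit backpropagation, and a single seeded
``numpy.random.Generator`` driving weight initialization (uniform fan-in),
epoch shuffling and dropout masks — identical config + data + seed reproduce
bit-identical weights.  The size-2/stride-1 pooling is retained verbatim from
the protocol even though it is a near-no-op (it shortens each sequence by one
sample).
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ConvLayerSpec",
    "CNNConfig",
    "SoftmaxOutput",
    "relu",
    "softmax",
    "build_cnn",
    "train_cnn",
    "predict_proba",
    "CNNModel",
    "TrainedCNN",
]


def relu(x):
    """Elementwise max(0, x)."""
    return np.maximum(0, x)


def softmax(z: np.ndarray) -> np.ndarray:
    """Row-wise softmax, numerically stabilized by subtracting the row max."""
    z = np.asarray(z, dtype=np.float64)
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


@dataclass(frozen=True)
class ConvLayerSpec:
    n_kernels: int
    kernel_size: int
    stride: int = 2
    activation: str = "relu"
    padding: str = "same"

    def __post_init__(self) -> None:
        if self.kernel_size < 1 or self.stride < 1:
            raise ValueError("kernel_size and stride must be >= 1")
        if self.activation != "relu":
            raise ValueError(f"unsupported activation {self.activation!r}")
        if self.padding not in ("same", "valid"):
            raise ValueError(f"unsupported padding {self.padding!r}")


_DEFAULT_CONV = (
    ConvLayerSpec(32, 16),
    ConvLayerSpec(32, 8),
    ConvLayerSpec(64, 4),
    ConvLayerSpec(64, 2),
)


@dataclass(frozen=True)
class CNNConfig:
    """Hyperparameter bundle; defaults are the tuned protocol values."""

    conv_layers: tuple[ConvLayerSpec, ...] = _DEFAULT_CONV
    pool_size: int = 2
    pool_stride: int = 1
    dropout_rate: float = 0.3
    n_classes: int = 5
    optimizer: str = "adam"
    learning_rate: float = 0.001
    loss: str = "categorical_crossentropy"
    batch_size: int = 32
    epochs: int = 100
    input_layout: str = "concat_1ch"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValueError(f"n_classes must be >= 2, got {self.n_classes}")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError(f"dropout_rate must be in [0, 1), got {self.dropout_rate}")
        if self.optimizer != "adam":
            raise ValueError(f"unsupported optimizer {self.optimizer!r}")
        if self.loss != "categorical_crossentropy":
            raise ValueError(f"unsupported loss {self.loss!r}")
        if self.input_layout not in ("concat_1ch", "multi_6ch"):
            raise ValueError(f"unknown input_layout {self.input_layout!r}")


@dataclass(frozen=True)
class SoftmaxOutput:
    """Per-row class probabilities and the argmax label (ties -> lowest index)."""

    probabilities: np.ndarray
    predicted_label: object


# ---------------------------------------------------------------------------
# layers


def _same_pad(L: int, k: int, s: int) -> tuple[int, int, int]:
    """(out_length, pad_left, pad_right) for 'same' padding at stride s."""
    out = -(-L // s)  # ceil
    total = max((out - 1) * s + k - L, 0)
    left = total // 2
    return out, left, total - left


class _Conv1D:
    """Convolution + ReLU; weights (in_ch * k, filters), 'same' padding.

    Weight rows are ordered channel-major then tap-minor, matching the natural
    memory order of the sliding-window view, so im2col needs no transpose.
    """

    def __init__(self, spec: ConvLayerSpec, in_ch: int, rng: np.random.Generator):
        self.spec = spec
        self.in_ch = in_ch
        k, f = spec.kernel_size, spec.n_kernels
        fan_in = k * in_ch
        limit = math.sqrt(6.0 / fan_in)  # uniform fan-in (He-style) init
        self.W = rng.uniform(-limit, limit, size=(fan_in, f)).astype(np.float32)
        self.b = np.zeros(f, dtype=np.float32)
        self._cache = None
        self._col_bufs: dict[tuple, np.ndarray] = {}  # reused im2col buffers

    def params(self):
        return [self.W, self.b]

    def out_length(self, L: int) -> int:
        return _same_pad(L, self.spec.kernel_size, self.spec.stride)[0]

    def n_params(self) -> int:
        return self.W.size + self.b.size

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        B, L, C = x.shape
        k, s = self.spec.kernel_size, self.spec.stride
        out, pl, pr = _same_pad(L, k, s)
        xp = np.pad(x, ((0, 0), (pl, pr), (0, 0))) if (pl or pr) else x
        # windows arrive as (B, n_positions, C, k); flatten last two dims
        # channel-major to match the weight layout; buffer reused across steps
        wv = np.lib.stride_tricks.sliding_window_view(xp, k, axis=1)
        key = (B, out)
        buf = self._col_bufs.get(key)
        if buf is None:
            buf = self._col_bufs.setdefault(
                key, np.empty((B, out, C, k), dtype=np.float32)
            )
        np.copyto(buf, wv[:, :: s])
        cols = buf.reshape(B * out, C * k)
        z = cols @ self.W + self.b
        mask = z > 0
        y = np.where(mask, z, 0).reshape(B, out, -1)
        if training:
            self._cache = (cols, mask, (B, L, out, pl, pr))
        return y

    def backward(self, dy: np.ndarray, need_dx: bool = True):
        cols, mask, (B, L, out, pl, pr) = self._cache
        self._cache = None
        k, s = self.spec.kernel_size, self.spec.stride
        dz = dy.reshape(B * out, -1).astype(np.float32, copy=False)
        dz = dz * mask
        dW = cols.T @ dz
        db = dz.sum(axis=0)
        dx = None
        if need_dx:
            dcols = (dz @ self.W.T).reshape(B, out, self.in_ch, k)
            dxp = np.zeros((B, L + pl + pr, self.in_ch), dtype=np.float32)
            for j in range(k):
                dxp[:, j : j + s * (out - 1) + 1 : s] += dcols[:, :, :, j]
            dx = dxp[:, pl : pl + L]
        return dx, [dW, db]


class _MaxPool21:
    """Max pooling, window ``size`` stride ``stride`` ('valid')."""

    def __init__(self, size: int = 2, stride: int = 1):
        if size != 2 or stride != 1:
            raise ValueError("only the protocol pooling (size 2, stride 1) is implemented")
        self._cache = None

    def out_length(self, L: int) -> int:
        return L - 1

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        a, b = x[:, :-1], x[:, 1:]
        left = a >= b  # ties -> left sample, deterministic
        y = np.where(left, a, b)
        if training:
            self._cache = (left, x.shape)
        return y

    def backward(self, dy: np.ndarray):
        left, shape = self._cache
        self._cache = None
        dx = np.empty(shape, dtype=np.float32)
        contrib = np.where(left, dy, 0).astype(np.float32, copy=False)
        dx[:, :-1] = contrib
        dx[:, -1] = 0
        dx[:, 1:] += dy - contrib
        return dx


class _Dense:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        limit = math.sqrt(6.0 / n_in)
        self.W = rng.uniform(-limit, limit, size=(n_in, n_out)).astype(np.float32)
        self.b = np.zeros(n_out, dtype=np.float32)
        self._cache = None

    def params(self):
        return [self.W, self.b]

    def n_params(self) -> int:
        return self.W.size + self.b.size

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if training:
            self._cache = x
        return x @ self.W + self.b

    def backward(self, dy: np.ndarray):
        x = self._cache
        self._cache = None
        dW = x.T @ dy
        db = dy.sum(axis=0)
        dx = dy @ self.W.T
        return dx, [dW.astype(np.float32, copy=False), db.astype(np.float32, copy=False)]


class _Adam:
    def __init__(self, params: list[np.ndarray], lr: float):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = 0.9, 0.999, 1e-7
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        c1 = 1 - b1**self.t
        c2 = 1 - b2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * np.square(g)
            p -= self.lr * (m / c1) / (np.sqrt(v / c2) + self.eps)


# ---------------------------------------------------------------------------
# model


@dataclass(frozen=True)
class LayerAudit:
    name: str
    layer_type: str
    output_length: int
    output_channels: int
    n_params: int


class CNNModel:
    """Built (possibly untrained) network for a fixed input geometry."""

    def __init__(self, cfg: CNNConfig, input_length: int, n_channels: int):
        self.cfg = cfg
        self.input_length = input_length
        self.n_channels = n_channels
        self.rng = np.random.default_rng(int(cfg.seed))

        audits: list[LayerAudit] = []
        layers: list = []
        L, C = input_length, n_channels
        for i, spec in enumerate(cfg.conv_layers, start=1):
            if L < 2:
                raise ValueError(
                    f"input too short: sequence length {L} reaching conv{i} "
                    f"(kernel {spec.kernel_size}); need input_length >= 16"
                )
            conv = _Conv1D(spec, C, self.rng)
            L = conv.out_length(L)
            C = spec.n_kernels
            layers.append(conv)
            audits.append(LayerAudit(f"conv{i}", "conv1d+relu", L, C, conv.n_params()))
            pool = _MaxPool21(cfg.pool_size, cfg.pool_stride)
            if L < 2:
                raise ValueError(f"input too short: length {L} reaching pool{i}")
            L = pool.out_length(L)
            layers.append(pool)
            audits.append(LayerAudit(f"pool{i}", "maxpool(2,1)", L, C, 0))
        flat = L * C
        audits.append(LayerAudit("flatten", "flatten", flat, 1, 0))
        audits.append(LayerAudit("dropout", f"dropout({cfg.dropout_rate})", flat, 1, 0))
        dense = _Dense(flat, cfg.n_classes, self.rng)
        layers.append(dense)
        audits.append(LayerAudit("dense", "dense+softmax", cfg.n_classes, 1, dense.n_params()))

        self.layers = layers
        self._audits = audits
        self.flat_dim = flat
        self.dense = dense

    # -- audit -------------------------------------------------------------
    def audit(self) -> pd.DataFrame:
        """Static shape/parameter table (available before any training)."""
        return pd.DataFrame([a.__dict__ for a in self._audits])

    @property
    def n_params(self) -> int:
        return sum(a.n_params for a in self._audits)

    def _params(self) -> list[np.ndarray]:
        out = []
        for layer in self.layers:
            if hasattr(layer, "params"):
                out.extend(layer.params())
        return out

    # -- forward/backward --------------------------------------------------
    def _forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        h = np.ascontiguousarray(x, dtype=np.float32)
        for layer in self.layers[:-1]:
            h = layer.forward(h, training)
        B = h.shape[0]
        h = h.reshape(B, -1)
        if training and self.cfg.dropout_rate > 0:
            keep = 1.0 - self.cfg.dropout_rate
            mask = (self.rng.random(h.shape) < keep).astype(np.float32) / keep
            self._drop_mask = mask
            h = h * mask
        else:
            self._drop_mask = None
        return self.dense.forward(h, training)

    def _backward(self, dlogits: np.ndarray) -> list[np.ndarray]:
        grads_rev: list[np.ndarray] = []
        dx, g = self.dense.backward(dlogits.astype(np.float32, copy=False))
        grads_rev.extend(reversed(g))
        if self._drop_mask is not None:
            dx = dx * self._drop_mask
        # reshape back to the last conv/pool output
        last_len = self._audits[-4].output_length  # pool4 length
        last_ch = self._audits[-4].output_channels
        dx = dx.reshape(-1, last_len, last_ch)
        body = self.layers[:-1]
        for idx in range(len(body) - 1, -1, -1):
            layer = body[idx]
            if isinstance(layer, _MaxPool21):
                dx = layer.backward(dx)
            else:
                need_dx = idx > 0
                dx, g = layer.backward(dx, need_dx=need_dx)
                grads_rev.extend(reversed(g))
        return list(reversed(grads_rev))

    def predict_logits(self, x: np.ndarray, batch: int = 128) -> np.ndarray:
        outs = [self._forward(x[i : i + batch], training=False) for i in range(0, len(x), batch)]
        return np.concatenate(outs, axis=0)

    def weights_digest(self) -> str:
        """SHA-256 over all weight bytes, for determinism checks."""
        h = hashlib.sha256()
        for p in self._params():
            h.update(np.ascontiguousarray(p).tobytes())
        return h.hexdigest()


def build_cnn(cfg: CNNConfig, input_length: int, n_channels: int) -> CNNModel:
    """Construct the network and its static shape/parameter audit."""
    return CNNModel(cfg, input_length, n_channels)


@dataclass
class TrainedCNN:
    """Trained model with its class order and per-epoch training trace."""

    model: CNNModel
    class_labels: tuple  # ascending
    trace: pd.DataFrame

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return softmax(self.model.predict_logits(x))

    def predict(self, x: np.ndarray) -> np.ndarray:
        probs = self.predict_proba(x)
        idx = probs.argmax(axis=1)  # argmax ties -> lowest class index
        return np.asarray(self.class_labels)[idx]


def _one_hot(y: np.ndarray, classes: Sequence) -> np.ndarray:
    lookup = {c: i for i, c in enumerate(classes)}
    out = np.zeros((len(y), len(classes)), dtype=np.float32)
    for r, label in enumerate(y):
        out[r, lookup[label]] = 1.0
    return out


def train_cnn(
    cfg: CNNConfig,
    x: np.ndarray,
    y: np.ndarray,
    model: CNNModel | None = None,
    accum_chunk: int = 4,
) -> TrainedCNN:
    """Train on a batch tensor ``x`` (N, length, channels) with labels ``y``.

    Classes are one-hot encoded in ascending label order.  Returns the trained
    model plus a per-epoch trace (mean minibatch loss, training accuracy).
    ``accum_chunk`` controls how many samples are backpropagated at a time
    within each minibatch (gradient accumulation); it changes memory locality
    only, not the optimization trajectory.
    """
    x = np.asarray(x)
    if x.ndim != 3 or len(x) == 0:
        raise ValueError(f"x must be a non-empty (N, length, channels) tensor, got {x.shape}")
    y = np.asarray(y)
    if len(y) != len(x):
        raise ValueError(f"labels length {len(y)} != batch size {len(x)}")
    classes = tuple(sorted(set(y.tolist())))
    if len(classes) < 2:
        raise ValueError(f"need >= 2 classes to train, got {classes}")
    if model is None:
        model = build_cnn(cfg, x.shape[1], x.shape[2])
    if (x.shape[1], x.shape[2]) != (model.input_length, model.n_channels):
        raise ValueError(
            f"input shape {x.shape[1:]} does not match built network "
            f"({model.input_length}, {model.n_channels})"
        )
    if len(classes) != cfg.n_classes:
        raise ValueError(
            f"{len(classes)} classes present but cfg.n_classes = {cfg.n_classes}"
        )

    Y = _one_hot(y, classes)
    x32 = np.ascontiguousarray(x, dtype=np.float32)
    opt = _Adam(model._params(), cfg.learning_rate)
    rng = model.rng
    n = len(x32)
    eps = 1e-12
    # each minibatch gradient is accumulated over small cache-resident chunks;
    # the Adam step per minibatch is identical to a single-pass evaluation
    rows = []
    for epoch in range(1, cfg.epochs + 1):
        order = rng.permutation(n)
        losses = []
        correct = 0
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            bn = len(idx)
            batch_grads = None
            batch_loss = 0.0
            for cs in range(0, bn, accum_chunk):
                cidx = idx[cs : cs + accum_chunk]
                xb, yb = x32[cidx], Y[cidx]
                logits = model._forward(xb, training=True)
                probs = softmax(logits)
                batch_loss += float(-(yb * np.log(probs + eps)).sum())
                correct += int((probs.argmax(1) == yb.argmax(1)).sum())
                grads = model._backward((probs - yb) / bn)
                if batch_grads is None:
                    batch_grads = grads
                else:
                    for acc, g in zip(batch_grads, grads):
                        acc += g
            losses.append(batch_loss / bn)
            opt.step(batch_grads)
        rows.append(
            {"epoch": epoch, "loss": float(np.mean(losses)), "accuracy": correct / n}
        )
    trace = pd.DataFrame(rows)
    return TrainedCNN(model=model, class_labels=classes, trace=trace)


def predict_proba(trained: TrainedCNN, x: np.ndarray) -> list[SoftmaxOutput]:
    """Per-row class probabilities and argmax label for a batch tensor."""
    x = np.asarray(x)
    if x.ndim != 3 or x.shape[1:] != (trained.model.input_length, trained.model.n_channels):
        raise ValueError(
            f"input shape {x.shape} incompatible with network "
            f"(N, {trained.model.input_length}, {trained.model.n_channels})"
        )
    probs = trained.predict_proba(x)
    labels = np.asarray(trained.class_labels)[probs.argmax(axis=1)]
    return [SoftmaxOutput(probabilities=p, predicted_label=l) for p, l in zip(probs, labels)]
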