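"""A compact numpy convolutional classifier for GAF feature images.

The architecture is five 3x3 same-padded convolution layers with ReLU
activations, three 2x2 max-pooling layers (after convolutions 1, 3 and
5), and two fully connected layers ending in five class scores:

    conv16 - pool - conv32 - conv32 - pool - conv64 - conv64 - pool
    - fc128 - fc5

Training minimizes softmax cross-entropy with Adam.  Everything is plain
numpy (float32, im2col-based convolutions), so training is reproducible
bit-for-bit under a fixed seed and needs no accelerator.  Inputs are
8-bit images normalized to [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from stepgait.evaluation import EvaluationReport, classification_report
from stepgait.gaf_imaging import GAFImage
from stepgait.signal_model import GaitActivity

N_CLASSES = len(GaitActivity)


@dataclass(frozen=True)
class CNNConfig:
    """Architecture and training settings.

    The layer census (5 convolutions, 3 poolings, 2 fully connected) is
    fixed; channel widths, the FC width and the optimizer are the smallest
    conventional instantiation consistent with it.
    """

    side: int = 64
    conv_channels: tuple[int, ...] = (16, 32, 32, 64, 64)
    kernel_size: int = 3
    pool_after: tuple[int, ...] = (0, 2, 4)  # indices of convs followed by 2x2 max-pool
    fc_width: int = 128
    epochs: int = 30
    batch_size: int = 32
    learning_rate: float = 1e-3
    train_fraction: float = 0.8
    validation_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.side % 8 != 0:
            raise ValueError("image side must be divisible by 8 (three 2x2 poolings)")
        if len(self.conv_channels) != 5 or len(self.pool_after) != 3:
            raise ValueError("the architecture preset is 5 convolutions and 3 poolings")

    @property
    def layer_census(self) -> tuple[int, int, int]:
        """(convolution, pooling, fully connected) layer counts."""
        return (len(self.conv_channels), len(self.pool_after), 2)


# ---------------------------------------------------------------------------
# layer primitives (NCHW, float32)
# ---------------------------------------------------------------------------


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(B, C, H, W) -> (B, H*W, C*k*k) patches under same-padding."""
    pad = k // 2
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    windows = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
    b, c, h, w, _, _ = windows.shape
    return np.ascontiguousarray(windows.transpose(0, 2, 3, 1, 4, 5)).reshape(b, h * w, c * k * k)


class _Conv:
    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator):
        fan_in = c_in * k * k
        scale = np.sqrt(2.0 / fan_in)  # He initialization for ReLU networks
        self.W = (rng.standard_normal((fan_in, c_out)) * scale).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.k = k
        self.c_in = c_in
        self.c_out = c_out

    @property
    def params(self):
        return [self.W, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        b, _, h, w = x.shape
        self._cols = _im2col(x, self.k)
        out = self._cols @ self.W + self.b
        return out.reshape(b, h, w, self.c_out).transpose(0, 3, 1, 2)

    def backward(self, dout: np.ndarray) -> tuple[np.ndarray, list[np.ndarray]]:
        b, _, h, w = dout.shape
        dflat = dout.transpose(0, 2, 3, 1).reshape(b, h * w, self.c_out)
        dW = np.tensordot(self._cols, dflat, axes=([0, 1], [0, 1]))
        db = dflat.sum(axis=(0, 1))
        # dx as a same-padded convolution with the 180-degree-rotated kernel
        W_full = self.W.reshape(self.c_in, self.k, self.k, self.c_out)
        W_rot = W_full[:, ::-1, ::-1, :].transpose(3, 1, 2, 0).reshape(
            self.c_out * self.k * self.k, self.c_in
        )
        cols_back = _im2col(dflat.reshape(b, h, w, self.c_out).transpose(0, 3, 1, 2), self.k)
        dx = (cols_back @ W_rot).reshape(b, h, w, self.c_in).transpose(0, 3, 1, 2)
        return dx, [dW, db]


class _ReLU:
    params: list = []

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout: np.ndarray):
        return dout * self._mask, []


class _MaxPool2:
    params: list = []

    def forward(self, x: np.ndarray) -> np.ndarray:
        b, c, h, w = x.shape
        blocks = x.reshape(b, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        flat = blocks.reshape(b, c, h // 2, w // 2, 4)
        self._argmax = flat.argmax(axis=-1)
        self._shape = x.shape
        return np.take_along_axis(flat, self._argmax[..., None], axis=-1)[..., 0]

    def backward(self, dout: np.ndarray):
        b, c, h, w = self._shape
        dflat = np.zeros((b, c, h // 2, w // 2, 4), dtype=dout.dtype)
        np.put_along_axis(dflat, self._argmax[..., None], dout[..., None], axis=-1)
        dx = dflat.reshape(b, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(
            b, c, h, w
        )
        return dx, []


class _Flatten:
    params: list = []

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout: np.ndarray):
        return dout.reshape(self._shape), []


class _Dense:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / n_in)
        self.W = (rng.standard_normal((n_in, n_out)) * scale).astype(np.float32)
        self.b = np.zeros(n_out, dtype=np.float32)

    @property
    def params(self):
        return [self.W, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W + self.b

    def backward(self, dout: np.ndarray):
        dW = self._x.T @ dout
        db = dout.sum(axis=0)
        return dout @ self.W.T, [dW, db]


class CNNModel:
    """The five-conv / three-pool / two-FC classifier."""

    def __init__(self, config: CNNConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        layers: list = []
        c_in = 3
        for i, c_out in enumerate(config.conv_channels):
            layers.append(_Conv(c_in, c_out, config.kernel_size, rng))
            layers.append(_ReLU())
            if i in config.pool_after:
                layers.append(_MaxPool2())
            c_in = c_out
        layers.append(_Flatten())
        feat_side = config.side // (2 ** len(config.pool_after))
        layers.append(_Dense(c_in * feat_side * feat_side, config.fc_width, rng))
        layers.append(_ReLU())
        layers.append(_Dense(config.fc_width, N_CLASSES, rng))
        self.layers = layers
        self._adam_m = [np.zeros_like(p) for p in self.parameters()]
        self._adam_v = [np.zeros_like(p) for p in self.parameters()]
        self._adam_t = 0

    def parameters(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params]

    @property
    def layer_census(self) -> tuple[int, int, int]:
        conv = sum(isinstance(l, _Conv) for l in self.layers)
        pool = sum(isinstance(l, _MaxPool2) for l in self.layers)
        fc = sum(isinstance(l, _Dense) for l in self.layers)
        return (conv, pool, fc)

    def forward(self, x: np.ndarray) -> np.ndarray:
        out = x
        for layer in self.layers:
            out = layer.forward(out)
        return out

    def predict_logits(self, x: np.ndarray, batch_size: int = 128) -> np.ndarray:
        outs = [self.forward(x[i : i + batch_size]) for i in range(0, len(x), batch_size)]
        return np.concatenate(outs)

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.predict_logits(x).argmax(axis=1)

    def train_step(self, x: np.ndarray, y: np.ndarray, lr: float) -> float:
        logits = self.forward(x)
        loss, dlogits = _softmax_cross_entropy(logits, y)
        grads: list[np.ndarray] = []
        dout = dlogits
        for layer in reversed(self.layers):
            dout, layer_grads = layer.backward(dout)
            grads = layer_grads + grads
        self._adam_update(grads, lr)
        return loss

    def _adam_update(self, grads, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self._adam_t += 1
        t = self._adam_t
        for p, g, m, v in zip(self.parameters(), grads, self._adam_m, self._adam_v):
            g = g.astype(np.float32)
            m *= beta1
            m += (1 - beta1) * g
            v *= beta2
            v += (1 - beta2) * g * g
            m_hat = m / (1 - beta1**t)
            v_hat = v / (1 - beta2**t)
            p -= lr * m_hat / (np.sqrt(v_hat) + eps)


def _softmax_cross_entropy(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    z = logits - logits.max(axis=1, keepdims=True)
    exp = np.exp(z)
    probs = exp / exp.sum(axis=1, keepdims=True)
    n = len(y)
    loss = float(-np.mean(np.log(probs[np.arange(n), y] + 1e-12)))
    dlogits = probs
    dlogits[np.arange(n), y] -= 1.0
    return loss, (dlogits / n).astype(np.float32)


def build_model(config: CNNConfig) -> CNNModel:
    """Construct the classifier; initialization is deterministic under the seed."""
    return CNNModel(config)


# ---------------------------------------------------------------------------
# data handling, training, evaluation
# ---------------------------------------------------------------------------


@dataclass
class TrainingTrace:
    """Per-epoch training and validation loss."""

    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.train_loss)


def images_to_arrays(images: Sequence[GAFImage]) -> tuple[np.ndarray, np.ndarray]:
    """Stack images into (B, 3, N, N) float32 in [0, 1] plus label codes."""
    x = np.stack([img.pixels for img in images]).astype(np.float32) / 255.0
    x = x.transpose(0, 3, 1, 2)
    y = np.array([int(img.label) for img in images], dtype=int)
    return np.ascontiguousarray(x), y


def split_train_test(
    images: Sequence[GAFImage],
    fraction: float = 0.8,
    seed: int = 0,
    stratified: bool = True,
) -> tuple[list[GAFImage], list[GAFImage]]:
    """Random train/test split; disjoint and exhaustive.

    With ``stratified=True`` each class contributes round(fraction * count)
    training images, drawn uniformly at random.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must lie strictly between 0 and 1 (a test set is required)")
    rng = np.random.default_rng(seed)
    labels = np.array([int(img.label) for img in images])
    train_idx: list[int] = []
    if stratified:
        for code in np.unique(labels):
            idx = np.flatnonzero(labels == code)
            if len(idx) < 2:
                raise ValueError(
                    f"class {GaitActivity(code).name} has fewer than 2 images"
                )
            n_train = int(round(fraction * len(idx)))
            n_train = min(max(n_train, 1), len(idx) - 1)
            chosen = rng.choice(len(idx), size=n_train, replace=False)
            train_idx.extend(idx[chosen])
    else:
        n_train = int(round(fraction * len(images)))
        n_train = min(max(n_train, 1), len(images) - 1)
        train_idx = list(rng.choice(len(images), size=n_train, replace=False))
    train_set = set(train_idx)
    train = [images[i] for i in sorted(train_set)]
    test = [images[i] for i in range(len(images)) if i not in train_set]
    return train, test


def train(
    model: CNNModel,
    train_images: Sequence[GAFImage],
    config: CNNConfig | None = None,
) -> tuple[CNNModel, TrainingTrace]:
    """Train for ``config.epochs`` epochs; returns the model and loss trace.

    A validation share of the training partition (10% by default) is held
    out for the validation-loss curve.  Shuffling and the holdout are
    seeded, so runs are bit-for-bit reproducible.
    """
    config = config or model.config
    if len(train_images) == 0:
        raise ValueError("training set is empty")
    x, y = images_to_arrays(train_images)
    rng = np.random.default_rng(config.seed + 1)
    n_val = int(round(config.validation_fraction * len(x)))
    order = rng.permutation(len(x))
    val_idx, fit_idx = order[:n_val], order[n_val:]
    x_val, y_val = x[val_idx], y[val_idx]
    x_fit, y_fit = x[fit_idx], y[fit_idx]
    if len(x_fit) == 0:
        raise ValueError("training set too small for the validation holdout")

    trace = TrainingTrace()
    for _ in range(config.epochs):
        perm = rng.permutation(len(x_fit))
        loss_sum = 0.0
        for start in range(0, len(x_fit), config.batch_size):
            batch = perm[start : start + config.batch_size]
            loss = model.train_step(x_fit[batch], y_fit[batch], config.learning_rate)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {len(trace) + 1}: {loss}"
                )
            loss_sum += loss * len(batch)
        # sample-weighted so the epoch loss does not depend on the batch partition
        trace.train_loss.append(loss_sum / len(x_fit))
        if len(x_val) > 0:
            val_logits = model.predict_logits(x_val)
            val_loss, _ = _softmax_cross_entropy(val_logits, y_val)
        else:
            val_loss = float("nan")
        trace.val_loss.append(val_loss)
    return model, trace


def evaluate_model(
    model: CNNModel, test_images: Sequence[GAFImage], metadata: dict | None = None
) -> EvaluationReport:
    """Classification report of the model on a held-out image set."""
    if len(test_images) == 0:
        raise ValueError("test set is empty")
    x, y = images_to_arrays(test_images)
    y_pred = model.predict(x)
    meta = {"approach": "cnn", "n_test": len(test_images)}
    meta.update(metadata or {})
    return classification_report(y, y_pred, metadata=meta)
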