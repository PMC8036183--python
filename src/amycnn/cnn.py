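"""2D convolutional network for per-scan amyloid positivity.

The architecture is two convolution blocks — each [conv, ReLU, conv, ReLU,
2x2 max-pool, batch norm, dropout] — followed by global average pooling
(GAP) and a single sigmoid dense unit. All slices of a scan enter
as input channels, so the network outputs one positivity probability per
scan. The GAP head makes the model directly interpretable through class
activation maps: the logit is the spatial mean of a weighted sum of the
final feature maps plus the dense bias.

Implemented directly on numpy with explicit backpropagation (im2col
convolutions, exact layer-by-layer gradients) and a Keras-convention Adam
optimizer (learning-rate decay lr_t = lr / (1 + decay * t), epsilon 1e-7).
Training is full-batch by default: one optimizer step per epoch over the
whole training set. Everything stochastic (weight init, dropout masks,
shuffling) is driven by a single seed, so training is bit-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Callable

import numpy as np

from .dataprep import Dataset, SliceStack

_DTYPE = np.float32
_BN_EPS = 1e-3
_BN_MOMENTUM = 0.99
_ADAM_BETA1 = 0.9
_ADAM_BETA2 = 0.999
_ADAM_EPS = 1e-7


@dataclass
class CNNConfig:
    """Architecture and optimization hyperparameters.

    Defaults: 60% dropout after each
    max-pool, Adam with a low learning rate of 1e-5 and per-step decay of
    1e-6, and a batch size equal to the full training set.
    """

    conv_filters: tuple[int, int, int, int] = (32, 32, 64, 64)
    kernel_size: int = 3
    dropout_rate: float = 0.6
    learning_rate: float = 1e-5
    lr_decay: float = 1e-6
    epochs: int = 500
    batch_mode: str = "full_dataset"  # or "mini_batch"
    mini_batch_size: int = 32
    decision_threshold: float = 0.5
    rng_seed: int = 0

    def __post_init__(self) -> None:
        self.conv_filters = tuple(int(f) for f in self.conv_filters)
        if len(self.conv_filters) != 4 or any(f <= 0 for f in self.conv_filters):
            raise ValueError("conv_filters must be 4 positive integers")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.learning_rate <= 0 or self.lr_decay < 0:
            raise ValueError("invalid optimizer hyperparameters")
        if self.batch_mode not in ("full_dataset", "mini_batch"):
            raise ValueError("batch_mode must be full_dataset or mini_batch")
        if not 0.0 < self.decision_threshold < 1.0:
            raise ValueError("decision_threshold must be in (0, 1)")
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")


# ---------------------------------------------------------------------------
# Layers
# ---------------------------------------------------------------------------

class _Layer:
    params: dict
    grads: dict

    def __init__(self) -> None:
        self.params, self.grads = {}, {}

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, gout: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv2D(_Layer):
    """Same-padded stride-1 convolution via im2col."""

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator):
        super().__init__()
        self.c_in, self.c_out, self.k = c_in, c_out, k
        self.is_first = False  # first layer: input gradient not needed
        self._cache_x: np.ndarray | None = None
        self._cache_cols: np.ndarray | None = None
        fan_in, fan_out = k * k * c_in, k * k * c_out
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        self.params = {
            "W": rng.uniform(-limit, limit, (k * k * c_in, c_out)).astype(_DTYPE),
            "b": np.zeros(c_out, dtype=_DTYPE),
        }

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        n, h, w, c = x.shape
        k, p = self.k, self.k // 2
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
        cols = np.empty((n, h, w, k * k * c), dtype=_DTYPE)
        i = 0
        for di in range(k):
            for dj in range(k):
                cols[..., i * c:(i + 1) * c] = xp[:, di:di + h, dj:dj + w, :]
                i += 1
        return cols

    def forward(self, x, training):
        self._x_shape = x.shape
        # the first layer sees the same full-batch input every epoch when no
        # augmentation runs; reuse its im2col matrix in that case
        if self.is_first and x is self._cache_x:
            cols = self._cache_cols
        else:
            cols = self._im2col(x)
            cols = cols.reshape(-1, cols.shape[-1])
            if self.is_first and training:
                self._cache_x, self._cache_cols = x, cols
        self._cols = cols
        n, h, w, _ = x.shape
        out = cols @ self.params["W"] + self.params["b"]
        return out.reshape(n, h, w, self.c_out)

    def backward(self, gout):
        n, h, w, c = self._x_shape
        g = gout.reshape(-1, self.c_out)
        if g.dtype != _DTYPE:
            g = g.astype(_DTYPE)
        self.grads["W"] = self._cols.T @ g
        self.grads["b"] = g.sum(axis=0)
        cols, self._cols = self._cols, None
        if self.is_first:
            return None  # no layer below needs this gradient
        gcols = (g @ self.params["W"].T).reshape(n, h, w, -1)
        k, p = self.k, self.k // 2
        gxp = np.zeros((n, h + 2 * p, w + 2 * p, c), dtype=_DTYPE)
        i = 0
        for di in range(k):
            for dj in range(k):
                gxp[:, di:di + h, dj:dj + w, :] += gcols[..., i * c:(i + 1) * c]
                i += 1
        return gxp[:, p:p + h, p:p + w, :]


class BatchNorm(_Layer):
    """Per-channel batch normalization over (batch, height, width)."""

    def __init__(self, c: int):
        super().__init__()
        self.params = {
            "gamma": np.ones(c, dtype=_DTYPE),
            "beta": np.zeros(c, dtype=_DTYPE),
        }
        self.running_mean = np.zeros(c, dtype=_DTYPE)
        self.running_var = np.ones(c, dtype=_DTYPE)

    def forward(self, x, training):
        if training:
            mean = x.mean(axis=(0, 1, 2))
            var = x.var(axis=(0, 1, 2))
            self.running_mean = (_BN_MOMENTUM * self.running_mean
                                 + (1 - _BN_MOMENTUM) * mean).astype(_DTYPE)
            self.running_var = (_BN_MOMENTUM * self.running_var
                                + (1 - _BN_MOMENTUM) * var).astype(_DTYPE)
            self._inv_std = 1.0 / np.sqrt(var + _BN_EPS)
            self._xhat = (x - mean) * self._inv_std
            return self.params["gamma"] * self._xhat + self.params["beta"]
        inv = 1.0 / np.sqrt(self.running_var + _BN_EPS)
        return self.params["gamma"] * (x - self.running_mean) * inv \
            + self.params["beta"]

    def backward(self, gout):
        xhat, inv_std = self._xhat, self._inv_std
        m = gout.shape[0] * gout.shape[1] * gout.shape[2]
        self.grads["gamma"] = (gout * xhat).sum(axis=(0, 1, 2))
        self.grads["beta"] = gout.sum(axis=(0, 1, 2))
        g = self.params["gamma"] * inv_std / m * (
            m * gout
            - gout.sum(axis=(0, 1, 2))
            - xhat * (gout * xhat).sum(axis=(0, 1, 2))
        )
        self._xhat = None
        return g.astype(_DTYPE)


class ReLU(_Layer):
    def forward(self, x, training):
        self._mask = x > 0
        return x * self._mask

    def backward(self, gout):
        g = gout * self._mask
        self._mask = None
        return g


class MaxPool2(_Layer):
    """2x2 max pooling, stride 2; trailing odd rows/columns are dropped."""

    def forward(self, x, training):
        n, h, w, c = x.shape
        h2, w2 = h // 2, w // 2
        xt = x[:, :h2 * 2, :w2 * 2, :].reshape(n, h2, 2, w2, 2, c)
        xt = xt.transpose(0, 1, 3, 5, 2, 4).reshape(n, h2, w2, c, 4)
        self._argmax = xt.argmax(axis=-1)
        self._x_shape = x.shape
        return np.take_along_axis(xt, self._argmax[..., None], axis=-1)[..., 0]

    def backward(self, gout):
        n, h, w, c = self._x_shape
        h2, w2 = h // 2, w // 2
        g4 = np.zeros((n, h2, w2, c, 4), dtype=_DTYPE)
        np.put_along_axis(g4, self._argmax[..., None], gout[..., None], axis=-1)
        g = g4.reshape(n, h2, w2, c, 2, 2).transpose(0, 1, 4, 2, 5, 3) \
            .reshape(n, h2 * 2, w2 * 2, c)
        if (h2 * 2, w2 * 2) != (h, w):
            full = np.zeros((n, h, w, c), dtype=_DTYPE)
            full[:, :h2 * 2, :w2 * 2, :] = g
            g = full
        self._argmax = None
        return g


class Dropout(_Layer):
    """Inverted dropout; active only in training mode."""

    def __init__(self, rate: float, rng: np.random.Generator):
        super().__init__()
        self.rate, self.rng = rate, rng

    def forward(self, x, training):
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(_DTYPE) / keep
        return x * self._mask

    def backward(self, gout):
        if self._mask is None:
            return gout
        g = gout * self._mask
        self._mask = None
        return g


class GlobalAveragePool(_Layer):
    def forward(self, x, training):
        self._spatial = x.shape[1:3]
        return x.mean(axis=(1, 2))

    def backward(self, gout):
        h, w = self._spatial
        return np.broadcast_to(
            gout[:, None, None, :] / (h * w),
            (gout.shape[0], h, w, gout.shape[1]),
        ).astype(_DTYPE)


class Dense(_Layer):
    """Single-unit linear head; the sigmoid lives in the loss/predict path.

    Initialized to zero: a randomly initialized head would impose an
    arbitrary initial class prior (a logit offset of order |W|*|g|) that a
    very low learning rate cannot undo, whereas the zero head starts at
    probability 0.5 for every scan and lets the gradient build the decision
    boundary symmetrically between the classes. A single linear unit needs
    no random symmetry breaking.
    """

    def __init__(self, c_in: int, rng: np.random.Generator):
        super().__init__()
        self.params = {
            "W": np.zeros((c_in, 1), dtype=_DTYPE),
            "b": np.zeros(1, dtype=_DTYPE),
        }

    def forward(self, x, training):
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, gout):
        self.grads["W"] = self._x.T @ gout
        self.grads["b"] = gout.sum(axis=0)
        g = gout @ self.params["W"].T
        self._x = None
        return g


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=np.float64)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _bce(p: np.ndarray, y: np.ndarray) -> float:
    eps = 1e-12
    return float(-np.mean(y * np.log(p + eps) + (1 - y) * np.log(1 - p + eps)))


# ---------------------------------------------------------------------------
# Model
# ---------------------------------------------------------------------------

class TrainedModel:
    """The GAP-headed 2D CNN with its weights and training history.

    ``input_shape`` is (height, width, channels) where channels are the
    slices of the decomposition axis.
    """

    def __init__(self, input_shape: tuple[int, int, int], config: CNNConfig,
                 axis: str = ""):
        h, w, c = input_shape
        if h < 4 or w < 4:
            raise ValueError(
                f"input spatial dims {h}x{w} too small for two 2x2 poolings"
            )
        self.input_shape = (int(h), int(w), int(c))
        self.config = config
        self.axis = axis
        self.history: dict[str, list[float]] = {
            "loss": [], "accuracy": [], "val_loss": [], "val_accuracy": [],
        }
        self._rng = np.random.default_rng(config.rng_seed)
        f1, f2, f3, f4 = config.conv_filters
        k = config.kernel_size
        rng = self._rng
        # one batch norm per block, placed after the max-pool: the features
        # entering GAP are then zero-mean per channel over the batch, so the
        # sigmoid head starts centred between the classes — essential for
        # the very low learning rate to produce a usable decision boundary
        # within a few hundred full-batch steps
        self.layers: list[_Layer] = [
            Conv2D(c, f1, k, rng), ReLU(),
            Conv2D(f1, f2, k, rng), ReLU(),
            MaxPool2(), BatchNorm(f2), Dropout(config.dropout_rate, rng),
            Conv2D(f2, f3, k, rng), ReLU(),
            Conv2D(f3, f4, k, rng), ReLU(),
            MaxPool2(), BatchNorm(f4), Dropout(config.dropout_rate, rng),
            GlobalAveragePool(),
            Dense(f4, rng),
        ]
        self.layers[0].is_first = True
        self._adam_t = 0
        self._adam_m: list[dict] = [
            {k2: np.zeros_like(v) for k2, v in lyr.params.items()}
            for lyr in self.layers
        ]
        self._adam_v = [
            {k2: np.zeros_like(v) for k2, v in lyr.params.items()}
            for lyr in self.layers
        ]

    # -- forward paths ------------------------------------------------------

    def layer_sequence(self) -> list[str]:
        return [type(lyr).__name__ for lyr in self.layers]

    def n_params(self) -> int:
        return int(sum(v.size for lyr in self.layers
                       for v in lyr.params.values()))

    @property
    def gap_dense_weights(self) -> tuple[np.ndarray, float]:
        """Dense head as (weight vector over final feature maps, bias)."""
        dense = self.layers[-1]
        return dense.params["W"][:, 0].copy(), float(dense.params["b"][0])

    def _check_input(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=_DTYPE)
        if x.ndim == 3:
            x = x[None]
        if x.shape[1:] != self.input_shape:
            raise ValueError(
                f"input shape {x.shape[1:]} != model input {self.input_shape}"
            )
        return x

    def forward_logits(self, x: np.ndarray, training: bool = False
                       ) -> np.ndarray:
        x = self._check_input(x)
        for lyr in self.layers:
            if x.dtype != _DTYPE:
                x = x.astype(_DTYPE)
            x = lyr.forward(x, training)
        return x[:, 0].astype(np.float64)

    def feature_maps(self, x: np.ndarray) -> np.ndarray:
        """Final pre-GAP feature maps (N, h', w', C), inference mode."""
        x = self._check_input(x)
        for lyr in self.layers[:-2]:
            if x.dtype != _DTYPE:
                x = x.astype(_DTYPE)
            x = lyr.forward(x, training=False)
        return x

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return _sigmoid(self.forward_logits(x, training=False))

    # -- training -----------------------------------------------------------

    def _adam_step(self) -> None:
        cfg = self.config
        self._adam_t += 1
        t = self._adam_t
        lr = cfg.learning_rate / (1.0 + cfg.lr_decay * (t - 1))
        corr = np.sqrt(1.0 - _ADAM_BETA2 ** t) / (1.0 - _ADAM_BETA1 ** t)
        for lyr, m, v in zip(self.layers, self._adam_m, self._adam_v):
            for name, p in lyr.params.items():
                g = lyr.grads[name].astype(np.float32)
                m[name] = _ADAM_BETA1 * m[name] + (1 - _ADAM_BETA1) * g
                v[name] = _ADAM_BETA2 * v[name] + (1 - _ADAM_BETA2) * g * g
                p -= (lr * corr) * m[name] / (np.sqrt(v[name]) + _ADAM_EPS)

    def train_step(self, x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
        """One optimizer step on one batch; returns (loss, accuracy)."""
        logits = self.forward_logits(x, training=True)
        p = _sigmoid(logits)
        loss = _bce(p, y)
        acc = float(np.mean((p >= self.config.decision_threshold) == (y == 1)))
        gout = ((p - y) / len(y)).astype(_DTYPE)[:, None]
        g = gout
        for lyr in reversed(self.layers):
            g = lyr.backward(g)
        self._adam_step()
        return loss, acc


def build_model(input_shape: tuple[int, int, int], config: CNNConfig,
                axis: str = "") -> TrainedModel:
    """Construct the (untrained) GAP-headed 2D CNN."""
    return TrainedModel(input_shape, config, axis=axis)


def dataset_to_arrays(ds: Dataset) -> tuple[np.ndarray, np.ndarray]:
    """Stack a Dataset into (N, h, w, slices) inputs and a label vector."""
    if len(ds) == 0:
        raise ValueError("dataset is empty")
    xs, ys = [], []
    shape = ds.items[0][0].planes.shape
    for stack, label in ds.items:
        if stack.planes.shape != shape:
            raise ValueError("all slice stacks must share one shape")
        xs.append(np.moveaxis(stack.planes, 0, -1))
        ys.append(label)
    return (np.asarray(xs, dtype=_DTYPE), np.asarray(ys, dtype=np.float64))


def train(
    model: TrainedModel,
    train_ds: Dataset,
    val_ds: Dataset | None,
    config: CNNConfig | None = None,
    augment_fn: Callable[[SliceStack, int, int], SliceStack] | None = None,
) -> TrainedModel:
    """Train with binary cross-entropy and Adam.

    Full-batch mode performs one optimizer step per epoch on the entire
    training set. ``augment_fn(stack, item_index, epoch)``, when given, is
    applied to every training stack at the start of each epoch (transforms
    are resampled per epoch); validation data are never augmented.
    """
    config = config or model.config
    x_raw, y = dataset_to_arrays(train_ds)
    if val_ds is not None and len(val_ds) > 0:
        x_val, y_val = dataset_to_arrays(val_ds)
    else:
        x_val = y_val = None

    for epoch in range(config.epochs):
        if augment_fn is not None:
            aug_items = [
                (augment_fn(stack, i, epoch), label)
                for i, (stack, label) in enumerate(train_ds.items)
            ]
            x, _ = dataset_to_arrays(Dataset(items=aug_items))
        else:
            x = x_raw
        if config.batch_mode == "full_dataset":
            loss, acc = model.train_step(x, y)
        else:
            order = model._rng.permutation(len(y))
            losses, accs = [], []
            bs = config.mini_batch_size
            for lo in range(0, len(y), bs):
                sel = order[lo:lo + bs]
                l, a = model.train_step(x[sel], y[sel])
                losses.append(l * len(sel))
                accs.append(a * len(sel))
            loss, acc = sum(losses) / len(y), sum(accs) / len(y)
        model.history["loss"].append(loss)
        model.history["accuracy"].append(acc)
        if x_val is not None:
            p_val = model.predict_proba(x_val)
            model.history["val_loss"].append(_bce(p_val, y_val))
            model.history["val_accuracy"].append(
                float(np.mean((p_val >= config.decision_threshold)
                              == (y_val == 1))))
    if config.epochs > 0:
        recalibrate_batchnorm(model, x_raw)
        if x_val is not None:
            p_val = model.predict_proba(x_val)
            model.history["val_loss"][-1] = _bce(p_val, y_val)
            model.history["val_accuracy"][-1] = float(
                np.mean((p_val >= config.decision_threshold) == (y_val == 1)))
    for lyr in model.layers:
        if isinstance(lyr, Conv2D):
            lyr._cache_x = lyr._cache_cols = None
    return model


def recalibrate_batchnorm(model: TrainedModel, x: np.ndarray) -> None:
    """Replace BN running statistics with exact population statistics.

    One inference-mode sweep over the (training) set: each batch-norm layer
    receives the statistics of its own input under the final weights, layer
    by layer. This removes the residual mismatch the exponential moving
    average leaves behind, which matters here because the class separation
    built at a very low learning rate is small compared to that residual.
    """
    x = model._check_input(x)
    for lyr in model.layers[:-2]:
        if x.dtype != _DTYPE:
            x = x.astype(_DTYPE)
        if isinstance(lyr, BatchNorm):
            lyr.running_mean = x.mean(axis=(0, 1, 2)).astype(_DTYPE)
            lyr.running_var = x.var(axis=(0, 1, 2)).astype(_DTYPE)
        x = lyr.forward(x, training=False)


def predict(model: TrainedModel, stack: SliceStack | np.ndarray) -> float:
    """Positivity probability for one scan (inference mode)."""
    planes = stack.planes if isinstance(stack, SliceStack) else np.asarray(stack)
    x = np.moveaxis(planes, 0, -1)
    return float(model.predict_proba(x)[0])


# ---------------------------------------------------------------------------
# Serialization: weights as .npz + JSON metadata sidecar
# ---------------------------------------------------------------------------

def save_model(model: TrainedModel, path: str | Path) -> None:
    path = Path(path)
    arrays: dict[str, np.ndarray] = {}
    for i, lyr in enumerate(model.layers):
        for name, p in lyr.params.items():
            arrays[f"layer{i}_{name}"] = p
        if isinstance(lyr, BatchNorm):
            arrays[f"layer{i}_running_mean"] = lyr.running_mean
            arrays[f"layer{i}_running_var"] = lyr.running_var
    np.savez(path.with_suffix(".npz"), **arrays)
    meta = {
        "input_shape": list(model.input_shape),
        "axis": model.axis,
        "config": asdict(model.config),
        "history": model.history,
    }
    path.with_suffix(".json").write_text(json.dumps(meta))


def load_model(path: str | Path) -> TrainedModel:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    cfg_d = meta["config"]
    cfg_d["conv_filters"] = tuple(cfg_d["conv_filters"])
    config = CNNConfig(**cfg_d)
    model = TrainedModel(tuple(meta["input_shape"]), config, axis=meta["axis"])
    model.history = meta["history"]
    with np.load(path.with_suffix(".npz")) as data:
        for i, lyr in enumerate(model.layers):
            for name in lyr.params:
                lyr.params[name] = data[f"layer{i}_{name}"]
            if isinstance(lyr, BatchNorm):
                lyr.running_mean = data[f"layer{i}_running_mean"]
                lyr.running_var = data[f"layer{i}_running_var"]
    return model
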