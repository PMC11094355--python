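"""A compact CPU neural-network library for the five vigor classifiers.

Implements exactly the layer zoo the classifier architectures need — 2-D/1-D
convolutions (valid padding), max pooling, dense, dropout, batch
normalization and LSTM — with hand-written backpropagation on float64 numpy
arrays, plus SGD (with momentum) and Adam optimizers and a softmax
cross-entropy head.  Everything is seeded: weight initialization, dropout
masks and epoch shuffling all derive from explicit RNGs, so two runs with
the same seed produce bit-identical weights on CPU.

Array layouts: images are NHWC, 1-D signals are (N, L, C), sequences are
(N, T, F).  Image tensors enter LSTMs rows-as-timesteps: timestep = row
index, feature vector = the flattened (width x channels) row.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "ArchitectureSpec",
    "HyperParams",
    "TrainHistory",
    "DivergenceError",
    "Network",
    "build_model",
    "train_model",
    "predict_labels",
    "ARCHITECTURES",
]

ARCHITECTURES = ("cnn2d", "cnn1d", "lstm1d", "lstm_image", "cnn_lstm")


class DivergenceError(RuntimeError):
    """Raised when the training loss becomes non-finite."""

    def __init__(self, epoch: int):
        super().__init__(f"non-finite loss at epoch {epoch}")
        self.epoch = epoch


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


# ---------------------------------------------------------------------------
# Layers
# ---------------------------------------------------------------------------

class Layer:
    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def params(self) -> list[list[np.ndarray]]:
        """List of [value, grad] pairs (arrays updated in place)."""
        return []

    def out_shape(self, in_shape: tuple[int, ...]) -> tuple[int, ...]:
        raise NotImplementedError

    def describe(self) -> dict:
        raise NotImplementedError


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 activation: str = "linear"):
        limit = np.sqrt(6.0 / (n_in + n_out))
        self.W = rng.uniform(-limit, limit, size=(n_in, n_out))
        self.b = np.zeros(n_out)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self.activation = activation

    def forward(self, x, training):
        self._x = x
        z = x @ self.W + self.b
        if self.activation == "relu":
            self._z = z
            return np.maximum(z, 0.0)
        if self.activation == "elu":
            self._z = z
            return np.where(z > 0, z, np.expm1(z))
        return z

    def backward(self, grad):
        if self.activation == "relu":
            grad = grad * (self._z > 0)
        elif self.activation == "elu":
            grad = grad * np.where(self._z > 0, 1.0, np.exp(self._z))
        self.dW[...] = self._x.T @ grad
        self.db[...] = grad.sum(axis=0)
        return grad @ self.W.T

    def params(self):
        return [[self.W, self.dW], [self.b, self.db]]

    def out_shape(self, in_shape):
        return (self.W.shape[1],)

    def describe(self):
        d = {"op": "dense", "units": self.W.shape[1]}
        if self.activation != "linear":
            d["activation"] = self.activation
        return d


class Conv2D(Layer):
    """Valid-padding 2-D convolution on NHWC tensors, via im2col."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int,
                 rng: np.random.Generator):
        k = kernel
        fan_in = k * k * in_ch
        limit = np.sqrt(6.0 / (fan_in + out_ch))
        self.W = rng.uniform(-limit, limit, size=(k * k * in_ch, out_ch))
        self.b = np.zeros(out_ch)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self.k = k
        self.in_ch = in_ch
        self.out_ch = out_ch

    def forward(self, x, training):
        k = self.k
        n, h, w, c = x.shape
        win = sliding_window_view(x, (k, k), axis=(1, 2))  # n,oh,ow,c,k,k
        cols = win.transpose(0, 1, 2, 4, 5, 3).reshape(n, h - k + 1, w - k + 1, -1)
        self._cols = cols
        self._in_shape = x.shape
        return cols @ self.W + self.b

    def backward(self, grad):
        n, oh, ow, f = grad.shape
        k = self.k
        cols2 = self._cols.reshape(-1, self.W.shape[0])
        g2 = grad.reshape(-1, f)
        self.dW[...] = cols2.T @ g2
        self.db[...] = g2.sum(axis=0)
        dcols = (g2 @ self.W.T).reshape(n, oh, ow, k, k, self.in_ch)
        dx = np.zeros(self._in_shape)
        for i in range(k):
            for j in range(k):
                dx[:, i : i + oh, j : j + ow, :] += dcols[:, :, :, i, j, :]
        return dx

    def params(self):
        return [[self.W, self.dW], [self.b, self.db]]

    def out_shape(self, in_shape):
        h, w, c = in_shape
        return (h - self.k + 1, w - self.k + 1, self.out_ch)

    def describe(self):
        return {"op": "conv2d", "kernel": [self.k, self.k], "filters": self.out_ch}


class Conv1D(Layer):
    """Valid-padding 1-D convolution on (N, L, C) signals (kernel 1 x k)."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int,
                 rng: np.random.Generator):
        k = kernel
        fan_in = k * in_ch
        limit = np.sqrt(6.0 / (fan_in + out_ch))
        self.W = rng.uniform(-limit, limit, size=(k * in_ch, out_ch))
        self.b = np.zeros(out_ch)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self.k = k
        self.in_ch = in_ch
        self.out_ch = out_ch

    def forward(self, x, training):
        k = self.k
        n, length, c = x.shape
        win = sliding_window_view(x, k, axis=1)  # n, ol, c, k
        cols = win.transpose(0, 1, 3, 2).reshape(n, length - k + 1, -1)
        self._cols = cols
        self._in_shape = x.shape
        return cols @ self.W + self.b

    def backward(self, grad):
        n, ol, f = grad.shape
        k = self.k
        cols2 = self._cols.reshape(-1, self.W.shape[0])
        g2 = grad.reshape(-1, f)
        self.dW[...] = cols2.T @ g2
        self.db[...] = g2.sum(axis=0)
        dcols = (g2 @ self.W.T).reshape(n, ol, k, self.in_ch)
        dx = np.zeros(self._in_shape)
        for i in range(k):
            dx[:, i : i + ol, :] += dcols[:, :, i, :]
        return dx

    def params(self):
        return [[self.W, self.dW], [self.b, self.db]]

    def out_shape(self, in_shape):
        length, c = in_shape
        return (length - self.k + 1, self.out_ch)

    def describe(self):
        return {"op": "conv1d", "kernel": [1, self.k], "filters": self.out_ch}


class MaxPool2D(Layer):
    def __init__(self, size: int = 2):
        self.s = size

    def forward(self, x, training):
        s = self.s
        n, h, w, c = x.shape
        oh, ow = h // s, w // s
        xr = x[:, : oh * s, : ow * s, :].reshape(n, oh, s, ow, s, c)
        xr = xr.transpose(0, 1, 3, 2, 4, 5).reshape(n, oh, ow, s * s, c)
        self._idx = np.argmax(xr, axis=3)
        self._in_shape = x.shape
        return np.take_along_axis(xr, self._idx[:, :, :, None, :], axis=3)[
            :, :, :, 0, :
        ]

    def backward(self, grad):
        s = self.s
        n, oh, ow, c = grad.shape
        flat = np.zeros((n, oh, ow, s * s, c))
        np.put_along_axis(flat, self._idx[:, :, :, None, :], grad[:, :, :, None, :], axis=3)
        flat = flat.reshape(n, oh, ow, s, s, c).transpose(0, 1, 3, 2, 4, 5)
        dx = np.zeros(self._in_shape)
        dx[:, : oh * s, : ow * s, :] = flat.reshape(n, oh * s, ow * s, c)
        return dx

    def out_shape(self, in_shape):
        h, w, c = in_shape
        return (h // self.s, w // self.s, c)

    def describe(self):
        return {"op": "maxpool2d", "size": [self.s, self.s]}


class MaxPool1D(Layer):
    def __init__(self, size: int = 2):
        self.s = size

    def forward(self, x, training):
        s = self.s
        n, length, c = x.shape
        ol = length // s
        xr = x[:, : ol * s, :].reshape(n, ol, s, c)
        self._idx = np.argmax(xr, axis=2)
        self._in_shape = x.shape
        return np.take_along_axis(xr, self._idx[:, :, None, :], axis=2)[:, :, 0, :]

    def backward(self, grad):
        s = self.s
        n, ol, c = grad.shape
        flat = np.zeros((n, ol, s, c))
        np.put_along_axis(flat, self._idx[:, :, None, :], grad[:, :, None, :], axis=2)
        dx = np.zeros(self._in_shape)
        dx[:, : ol * s, :] = flat.reshape(n, ol * s, c)
        return dx

    def out_shape(self, in_shape):
        length, c = in_shape
        return (length // self.s, c)

    def describe(self):
        return {"op": "maxpool1d", "size": [1, self.s]}


class Dropout(Layer):
    def __init__(self, rate: float, rng: np.random.Generator):
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng

    def forward(self, x, training):
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, grad):
        return grad if self._mask is None else grad * self._mask

    def out_shape(self, in_shape):
        return in_shape

    def describe(self):
        return {"op": "dropout", "rate": self.rate}


class BatchNorm(Layer):
    """Batch normalization over the feature axis of (N, F) inputs."""

    def __init__(self, n_features: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = np.ones(n_features)
        self.beta = np.zeros(n_features)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.running_mean = np.zeros(n_features)
        self.running_var = np.ones(n_features)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x, training):
        if training:
            mean = x.mean(axis=0)
            var = x.var(axis=0)
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        self._std = np.sqrt(var + self.eps)
        self._xhat = (x - mean) / self._std
        self._training = training
        return self.gamma * self._xhat + self.beta

    def backward(self, grad):
        self.dgamma[...] = (grad * self._xhat).sum(axis=0)
        self.dbeta[...] = grad.sum(axis=0)
        if not self._training:
            return grad * self.gamma / self._std
        n = grad.shape[0]
        dxhat = grad * self.gamma
        return (
            dxhat - dxhat.mean(axis=0) - self._xhat * (dxhat * self._xhat).mean(axis=0)
        ) / self._std

    def params(self):
        return [[self.gamma, self.dgamma], [self.beta, self.dbeta]]

    def out_shape(self, in_shape):
        return in_shape

    def describe(self):
        return {"op": "batchnorm"}


class LSTM(Layer):
    """Single LSTM layer over (N, T, F); returns sequences or the final state."""

    def __init__(self, n_in: int, units: int, rng: np.random.Generator,
                 return_sequences: bool = False):
        h = units
        limit = np.sqrt(6.0 / (n_in + h))
        self.W = rng.uniform(-limit, limit, size=(n_in, 4 * h))
        lim_u = np.sqrt(6.0 / (h + h))
        self.U = rng.uniform(-lim_u, lim_u, size=(h, 4 * h))
        self.b = np.zeros(4 * h)
        self.b[h : 2 * h] = 1.0  # forget-gate bias
        self.dW = np.zeros_like(self.W)
        self.dU = np.zeros_like(self.U)
        self.db = np.zeros_like(self.b)
        self.units = h
        self.return_sequences = return_sequences

    def forward(self, x, training):
        n, T, F = x.shape
        h = self.units
        hs = np.zeros((n, T + 1, h))
        cs = np.zeros((n, T + 1, h))
        gates = np.empty((n, T, 4 * h))
        tanh_c = np.empty((n, T, h))
        for t in range(T):
            z = x[:, t] @ self.W + hs[:, t] @ self.U + self.b
            i = _sigmoid(z[:, :h])
            f = _sigmoid(z[:, h : 2 * h])
            g = np.tanh(z[:, 2 * h : 3 * h])
            o = _sigmoid(z[:, 3 * h :])
            c = f * cs[:, t] + i * g
            tc = np.tanh(c)
            hs[:, t + 1] = o * tc
            cs[:, t + 1] = c
            gates[:, t, :h] = i
            gates[:, t, h : 2 * h] = f
            gates[:, t, 2 * h : 3 * h] = g
            gates[:, t, 3 * h :] = o
            tanh_c[:, t] = tc
        self._x, self._hs, self._cs = x, hs, cs
        self._gates, self._tanh_c = gates, tanh_c
        return hs[:, 1:] if self.return_sequences else hs[:, -1]

    def backward(self, grad):
        x, hs, cs = self._x, self._hs, self._cs
        gates, tanh_c = self._gates, self._tanh_c
        n, T, F = x.shape
        h = self.units
        self.dW[...] = 0.0
        self.dU[...] = 0.0
        self.db[...] = 0.0
        dx = np.zeros_like(x)
        dh_next = np.zeros((n, h))
        dc_next = np.zeros((n, h))
        for t in range(T - 1, -1, -1):
            dh = dh_next + (grad[:, t] if self.return_sequences else 0.0)
            if not self.return_sequences and t == T - 1:
                dh = dh + grad
            i = gates[:, t, :h]
            f = gates[:, t, h : 2 * h]
            g = gates[:, t, 2 * h : 3 * h]
            o = gates[:, t, 3 * h :]
            tc = tanh_c[:, t]
            dc = dc_next + dh * o * (1.0 - tc * tc)
            do = dh * tc
            di = dc * g
            dg = dc * i
            df = dc * cs[:, t]
            dz = np.concatenate(
                [
                    di * i * (1 - i),
                    df * f * (1 - f),
                    dg * (1 - g * g),
                    do * o * (1 - o),
                ],
                axis=1,
            )
            self.dW += x[:, t].T @ dz
            self.dU += hs[:, t].T @ dz
            self.db += dz.sum(axis=0)
            dx[:, t] = dz @ self.W.T
            dh_next = dz @ self.U.T
            dc_next = dc * f
        return dx

    def params(self):
        return [[self.W, self.dW], [self.U, self.dU], [self.b, self.db]]

    def out_shape(self, in_shape):
        T, F = in_shape
        return (T, self.units) if self.return_sequences else (self.units,)

    def describe(self):
        return {"op": "lstm", "units": self.units}


class Flatten(Layer):
    def forward(self, x, training):
        self._in_shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._in_shape)

    def out_shape(self, in_shape):
        return (int(np.prod(in_shape)),)

    def describe(self):
        return {"op": "flatten"}


class RowsToSequence(Layer):
    """(N, H, W, C) image -> (N, T=H, F=W*C) sequence; rows are timesteps."""

    def forward(self, x, training):
        self._in_shape = x.shape
        n, h, w, c = x.shape
        return x.reshape(n, h, w * c)

    def backward(self, grad):
        return grad.reshape(self._in_shape)

    def out_shape(self, in_shape):
        h, w, c = in_shape
        return (h, w * c)

    def describe(self):
        return {"op": "rows_to_sequence"}


class SpectrumToSequence(Layer):
    """(N, w) spectrum -> (N, T=w, 1) sequence; bands are timesteps."""

    def forward(self, x, training):
        return x[:, :, None]

    def backward(self, grad):
        return grad[:, :, 0]

    def out_shape(self, in_shape):
        return (in_shape[0], 1)

    def describe(self):
        return {"op": "bands_to_sequence"}


class AddChannel(Layer):
    """(N, w) spectrum -> (N, w, 1) channelled signal for 1-D convolution."""

    forward = SpectrumToSequence.forward
    backward = SpectrumToSequence.backward
    out_shape = SpectrumToSequence.out_shape

    def describe(self):
        return {"op": "add_channel"}


# ---------------------------------------------------------------------------
# Network, loss, optimizers
# ---------------------------------------------------------------------------

def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class Network:
    def __init__(self, layers: list[Layer], n_classes: int):
        self.layers = layers
        self.n_classes = n_classes

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, training)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def params(self) -> list[list[np.ndarray]]:
        out = []
        for layer in self.layers:
            out.extend(layer.params())
        return out

    def loss_and_grad(self, x: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
        """Softmax cross-entropy; fills parameter gradients via backward."""
        logits = self.forward(x, training=True)
        probs = softmax(logits)
        n = x.shape[0]
        eps = 1e-12
        loss = -np.log(probs[np.arange(n), y] + eps).mean()
        grad = probs.copy()
        grad[np.arange(n), y] -= 1.0
        self.backward(grad / n)
        return float(loss), logits


class SGD:
    """Plain SGD with classical momentum (0.9 by default)."""

    def __init__(self, params, lr: float, momentum: float = 0.9):
        self.params = params
        self.lr = lr
        self.momentum = momentum
        self.v = [np.zeros_like(p) for p, _ in params]

    def step(self):
        for (p, g), v in zip(self.params, self.v):
            v *= self.momentum
            v -= self.lr * g
            p += v


class Adam:
    def __init__(self, params, lr: float, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p, _ in params]
        self.v = [np.zeros_like(p) for p, _ in params]
        self.t = 0

    def step(self):
        self.t += 1
        bc1 = 1.0 - self.b1**self.t
        bc2 = 1.0 - self.b2**self.t
        for (p, g), m, v in zip(self.params, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)


_OPTIMIZERS = {"sgd": SGD, "adam": Adam}


@dataclass
class HyperParams:
    """Training hyperparameters; lr and bs are the two tuned by the firefly
    optimizer."""

    lr: float = 0.001
    bs: int = 8
    epochs: int = 100
    optimizer: str = "sgd"
    lr_bounds: tuple[float, float] = (1e-6, 1.0)

    def __post_init__(self) -> None:
        lo, hi = self.lr_bounds
        if not lo <= self.lr <= hi:
            raise ValueError(f"lr {self.lr} outside bounds [{lo}, {hi}]")
        if self.bs < 1:
            raise ValueError("batch size must be >= 1")
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")
        if self.optimizer not in _OPTIMIZERS:
            raise ValueError(f"unknown optimizer {self.optimizer!r}")


@dataclass
class TrainHistory:
    train_loss: list[float] = field(default_factory=list)
    train_accuracy: list[float] = field(default_factory=list)  # percent
    test_loss: list[float] = field(default_factory=list)
    test_accuracy: list[float] = field(default_factory=list)  # percent

    def as_dict(self) -> dict:
        return {
            "train_loss": self.train_loss,
            "train_accuracy": self.train_accuracy,
            "test_loss": self.test_loss,
            "test_accuracy": self.test_accuracy,
        }


@dataclass
class ArchitectureSpec:
    """Declared layer inventory of a built model (for structural checks)."""

    name: str
    layers: list[dict]
    input_shape: tuple[int, ...]
    n_classes: int


# ---------------------------------------------------------------------------
# Architectures
# ---------------------------------------------------------------------------

def build_model(
    name: str,
    input_shape: tuple[int, ...],
    n_classes: int = 4,
    rng_seed: int = 0,
    lstm_units: int = 64,
) -> tuple[ArchitectureSpec, Network]:
    """Build one of the five named classifiers for the given input shape.

    ``input_shape`` excludes the batch axis: (h, w, channels) for image
    models, (n_bands,) for spectral models.  All models end in an
    ``n_classes``-way softmax head (the softmax itself lives in the loss /
    ``predict_labels``).
    """
    if name not in ARCHITECTURES:
        raise ValueError(f"unknown architecture {name!r}; choose from {ARCHITECTURES}")
    rng = np.random.default_rng(rng_seed)
    layers: list[Layer] = []

    def shape_after() -> tuple[int, ...]:
        s = input_shape
        for layer in layers:
            s = layer.out_shape(s)
        return s

    if name in ("cnn2d", "lstm_image", "cnn_lstm"):
        if len(input_shape) != 3:
            raise ValueError(f"{name} expects (h, w, channels) input, got {input_shape}")
    else:
        if len(input_shape) != 1:
            raise ValueError(f"{name} expects (n_bands,) input, got {input_shape}")

    if name == "cnn2d":
        layers.append(Conv2D(input_shape[2], 6, 5, rng))
        layers.append(MaxPool2D(2))
        layers.append(Conv2D(6, 16, 5, rng))
        layers.append(MaxPool2D(2))
        layers.append(Flatten())
        layers.append(Dense(shape_after()[0], 120, rng, activation="relu"))
        layers.append(Dense(120, n_classes, rng))
    elif name == "cnn1d":
        layers.append(AddChannel())
        layers.append(Conv1D(1, 8, 3, rng))
        layers.append(MaxPool1D(2))
        layers.append(Conv1D(8, 16, 3, rng))
        layers.append(MaxPool1D(2))
        layers.append(Flatten())
        layers.append(Dropout(0.2, rng))
        layers.append(Dense(shape_after()[0], 128, rng, activation="relu"))
        layers.append(Dropout(0.2, rng))
        layers.append(Dense(128, n_classes, rng))
    elif name == "lstm1d":
        layers.append(SpectrumToSequence())
        layers.append(Dropout(0.2, rng))
        layers.append(LSTM(1, lstm_units, rng, return_sequences=False))
        layers.append(Dropout(0.2, rng))
        layers.append(Dense(lstm_units, 64, rng, activation="relu"))
        layers.append(Dense(64, n_classes, rng))
    elif name == "lstm_image":
        layers.append(RowsToSequence())
        feat = shape_after()[1]
        layers.append(LSTM(feat, lstm_units, rng, return_sequences=True))
        layers.append(LSTM(lstm_units, lstm_units, rng, return_sequences=True))
        layers.append(LSTM(lstm_units, lstm_units, rng, return_sequences=False))
        layers.append(BatchNorm(lstm_units))
        layers.append(Dense(lstm_units, 64, rng, activation="elu"))
        layers.append(Dense(64, n_classes, rng))
    else:  # cnn_lstm
        layers.append(Conv2D(input_shape[2], 8, 3, rng))
        layers.append(Conv2D(8, 16, 3, rng))
        layers.append(RowsToSequence())
        feat = shape_after()[1]
        layers.append(LSTM(feat, lstm_units, rng, return_sequences=True))
        layers.append(LSTM(lstm_units, lstm_units, rng, return_sequences=False))
        layers.append(BatchNorm(lstm_units))
        layers.append(Dense(lstm_units, 128, rng, activation="elu"))
        layers.append(Dense(128, n_classes, rng))

    final = shape_after()
    if final != (n_classes,):
        raise ValueError(f"shape propagation failed: head produces {final}")
    described = [layer.describe() for layer in layers]
    described.append({"op": "softmax"})
    spec = ArchitectureSpec(name, described, tuple(input_shape), n_classes)
    return spec, Network(layers, n_classes)


# ---------------------------------------------------------------------------
# Training / prediction
# ---------------------------------------------------------------------------

def _evaluate(model: Network, X: np.ndarray, y: np.ndarray,
              batch: int = 64) -> tuple[float, float]:
    losses, correct = [], 0
    for s in range(0, len(X), batch):
        logits = model.forward(X[s : s + batch], training=False)
        probs = softmax(logits)
        yb = y[s : s + batch]
        losses.append(-np.log(probs[np.arange(len(yb)), yb] + 1e-12).sum())
        correct += int((np.argmax(logits, axis=1) == yb).sum())
    loss = float(np.sum(losses) / len(X))
    return loss, 100.0 * correct / len(X)


def train_model(
    model: Network,
    train: tuple[np.ndarray, np.ndarray],
    test: tuple[np.ndarray, np.ndarray] | None,
    hp: HyperParams,
    rng_seed: int = 0,
) -> tuple[Network, TrainHistory]:
    """Minimize softmax cross-entropy with the named optimizer.

    ``train``/``test`` are (inputs, integer labels). The history records
    loss and accuracy (percent) per epoch on both sets; shuffling is driven
    by ``rng_seed`` only.
    """
    Xtr, ytr = train
    ytr = np.asarray(ytr, dtype=int)
    rng = np.random.default_rng(rng_seed)
    opt = _OPTIMIZERS[hp.optimizer](model.params(), hp.lr)
    history = TrainHistory()
    for epoch in range(hp.epochs):
        order = rng.permutation(len(Xtr))
        for s in range(0, len(Xtr), hp.bs):
            idx = order[s : s + hp.bs]
            loss, _ = model.loss_and_grad(Xtr[idx], ytr[idx])
            if not np.isfinite(loss):
                raise DivergenceError(epoch)
            opt.step()
        tr_loss, tr_acc = _evaluate(model, Xtr, ytr)
        history.train_loss.append(tr_loss)
        history.train_accuracy.append(tr_acc)
        if test is not None:
            te_loss, te_acc = _evaluate(model, test[0], np.asarray(test[1], int))
            history.test_loss.append(te_loss)
            history.test_accuracy.append(te_acc)
    return model, history


def predict_labels(model: Network, inputs: np.ndarray,
                   batch: int = 64) -> tuple[np.ndarray, np.ndarray]:
    """Predicted class indices (argmax of softmax) plus class probabilities."""
    probs = []
    for s in range(0, len(inputs), batch):
        probs.append(softmax(model.forward(inputs[s : s + batch], training=False)))
    probs = np.concatenate(probs, axis=0)
    return np.argmax(probs, axis=1), probs
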