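"""Minimal CPU neural-network engine for the secondary classifiers.

Implements exactly the layer vocabulary the two sequence-classifier
grammars need — LSTM, 3x3 same-padding convolution, batch
normalization, dropout, dense softmax head — with manual
backpropagation and an Adam optimizer, in pure numpy.  The networks in
this package are small (tens of units, thousands of sequences), so a
vectorized CPU implementation is entirely adequate; gradients are
verified against central finite differences in the test suite.

Conventions follow the common deep-learning defaults: LSTM gate order
(input, forget, cell, output) with unit forget-gate bias and orthogonal
recurrent initialization; Glorot-uniform kernels; batch-norm over all
axes but the channel axis with eps 1e-3 and momentum 0.99 running
statistics; Adam with beta1 0.9, beta2 0.999, eps 1e-7; categorical
cross-entropy on a 2-unit softmax.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np


def _glorot_uniform(rng: np.random.Generator, shape, fan_in, fan_out) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


def _orthogonal(rng: np.random.Generator, rows: int, cols: int) -> np.ndarray:
    a = rng.standard_normal((max(rows, cols), min(rows, cols)))
    q, r = np.linalg.qr(a)
    q = q * np.sign(np.diag(r))
    return q.T if rows < cols else q


def _sigmoid(x):
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class Layer:
    """Base layer: ``params``/``grads`` are dicts of named arrays."""

    def __init__(self):
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    @property
    def n_params(self) -> int:
        return int(sum(p.size for p in self.params.values()))


class Dense(Layer):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        super().__init__()
        self.params = {
            "W": _glorot_uniform(rng, (d_in, d_out), d_in, d_out),
            "b": np.zeros(d_out),
        }

    def forward(self, x, training):
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dout):
        self.grads = {"W": self._x.T @ dout, "b": dout.sum(axis=0)}
        return dout @ self.params["W"].T


class Flatten(Layer):
    def forward(self, x, training):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


class Dropout(Layer):
    """Inverted dropout; identity at inference."""

    def __init__(self, rate: float, rng: np.random.Generator):
        super().__init__()
        if not 0 <= rate < 1:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self._rng = rng

    def forward(self, x, training):
        if not training or self.rate == 0:
            self._mask = None
            return x
        self._mask = (self._rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, dout):
        return dout if self._mask is None else dout * self._mask


class BatchNorm(Layer):
    """Normalize over every axis except the last (channel) axis.

    Applied to (B, T, C) LSTM output sequences this normalizes each
    feature over batch and time steps; applied to (B, H, W, C) it is
    standard spatial batch norm.  Running statistics are buffers, not
    trainable parameters.
    """

    def __init__(self, channels: int, momentum: float = 0.99, eps: float = 1e-3):
        super().__init__()
        self.params = {"gamma": np.ones(channels), "beta": np.zeros(channels)}
        self.buffers = {"mean": np.zeros(channels), "var": np.ones(channels)}
        self.momentum = momentum
        self.eps = eps

    def forward(self, x, training):
        axes = tuple(range(x.ndim - 1))
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            m = self.momentum
            self.buffers["mean"] = m * self.buffers["mean"] + (1 - m) * mean
            self.buffers["var"] = m * self.buffers["var"] + (1 - m) * var
        else:
            mean, var = self.buffers["mean"], self.buffers["var"]
        self._axes = axes
        self._m = int(np.prod([x.shape[a] for a in axes]))
        self._inv_std = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mean) * self._inv_std
        self._training = training
        return self.params["gamma"] * self._xhat + self.params["beta"]

    def backward(self, dout):
        axes = self._axes
        self.grads = {
            "gamma": (dout * self._xhat).sum(axis=axes),
            "beta": dout.sum(axis=axes),
        }
        dxhat = dout * self.params["gamma"]
        if not self._training:
            return dxhat * self._inv_std
        m = self._m
        return (
            self._inv_std
            / m
            * (
                m * dxhat
                - dxhat.sum(axis=axes)
                - self._xhat * (dxhat * self._xhat).sum(axis=axes)
            )
        )


class LSTM(Layer):
    """Single LSTM layer over (B, T, D) inputs; gate order i, f, g, o."""

    def __init__(self, d_in: int, units: int, rng: np.random.Generator,
                 return_sequences: bool = False):
        super().__init__()
        self.units = units
        self.return_sequences = return_sequences
        self.params = {
            "W": _glorot_uniform(rng, (d_in, 4 * units), d_in, units),
            "U": np.hstack([_orthogonal(rng, units, units) for _ in range(4)]),
            "b": np.zeros(4 * units),
        }
        self.params["b"][units : 2 * units] = 1.0  # unit forget bias

    def forward(self, x, training):
        B, T, _ = x.shape
        u = self.units
        W, U, b = self.params["W"], self.params["U"], self.params["b"]
        h = np.zeros((B, u))
        c = np.zeros((B, u))
        self._x = x
        self._cache = []
        hs = np.empty((B, T, u))
        xW = x @ W + b  # precompute input contributions
        for t in range(T):
            z = xW[:, t, :] + h @ U
            i = _sigmoid(z[:, :u])
            f = _sigmoid(z[:, u : 2 * u])
            g = np.tanh(z[:, 2 * u : 3 * u])
            o = _sigmoid(z[:, 3 * u :])
            c_prev = c
            c = f * c_prev + i * g
            tc = np.tanh(c)
            h_prev = h
            h = o * tc
            hs[:, t, :] = h
            self._cache.append((i, f, g, o, c_prev, tc, h_prev))
        self._hs = hs
        return hs if self.return_sequences else h

    def backward(self, dout):
        x = self._x
        B, T, D = x.shape
        u = self.units
        W, U = self.params["W"], self.params["U"]
        dW = np.zeros_like(W)
        dU = np.zeros_like(U)
        db = np.zeros(4 * u)
        dx = np.empty_like(x)
        dh_rec = np.zeros((B, u))
        dc = np.zeros((B, u))
        for t in range(T - 1, -1, -1):
            i, f, g, o, c_prev, tc, h_prev = self._cache[t]
            if self.return_sequences:
                dh = dout[:, t, :] + dh_rec
            else:
                dh = (dout if t == T - 1 else 0) + dh_rec
            do = dh * tc
            dc = dc + dh * o * (1 - tc * tc)
            di = dc * g
            dg = dc * i
            df = dc * c_prev
            dz = np.hstack(
                [di * i * (1 - i), df * f * (1 - f), dg * (1 - g * g), do * o * (1 - o)]
            )
            dW += x[:, t, :].T @ dz
            dU += h_prev.T @ dz
            db += dz.sum(axis=0)
            dx[:, t, :] = dz @ W.T
            dh_rec = dz @ U.T
            dc = dc * f
        self.grads = {"W": dW, "U": dU, "b": db}
        return dx


class Conv2D(Layer):
    """3x3 convolution, stride 1, same padding, on (B, H, W, C) tensors."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator, k: int = 3):
        super().__init__()
        if k % 2 != 1:
            raise ValueError("kernel size must be odd for same padding")
        self.k = k
        fan_in, fan_out = k * k * c_in, k * k * c_out
        self.params = {
            "W": _glorot_uniform(rng, (k, k, c_in, c_out), fan_in, fan_out),
            "b": np.zeros(c_out),
        }

    def forward(self, x, training):
        k, p = self.k, self.k // 2
        B, H, Wd, C = x.shape
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
        W = self.params["W"]
        out = np.tile(self.params["b"], (B, H, Wd, 1))
        for di in range(k):
            for dj in range(k):
                out += xp[:, di : di + H, dj : dj + Wd, :] @ W[di, dj]
        self._xp, self._shape = xp, (B, H, Wd, C)
        return out

    def backward(self, dout):
        k, p = self.k, self.k // 2
        B, H, Wd, C = self._shape
        W = self.params["W"]
        dW = np.zeros_like(W)
        dxp = np.zeros_like(self._xp)
        flat_dout = dout.reshape(-1, W.shape[3])
        for di in range(k):
            for dj in range(k):
                patch = self._xp[:, di : di + H, dj : dj + Wd, :]
                dW[di, dj] = patch.reshape(-1, C).T @ flat_dout
                dxp[:, di : di + H, dj : dj + Wd, :] += dout @ W[di, dj].T
        self.grads = {"W": dW, "b": dout.sum(axis=(0, 1, 2))}
        return dxp[:, p : p + H, p : p + Wd, :]


class Sequential:
    """Plain layer stack ending in 2-class logits."""

    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, training)
        return x

    def backward(self, dlogits: np.ndarray) -> np.ndarray:
        d = dlogits
        for layer in reversed(self.layers):
            d = layer.backward(d)
        return d

    @property
    def n_params(self) -> int:
        return sum(layer.n_params for layer in self.layers)

    def get_state(self) -> list:
        state = []
        for layer in self.layers:
            entry = {"params": copy.deepcopy(layer.params)}
            if hasattr(layer, "buffers"):
                entry["buffers"] = copy.deepcopy(layer.buffers)
            state.append(entry)
        return state

    def set_state(self, state: list) -> None:
        for layer, entry in zip(self.layers, state):
            layer.params = copy.deepcopy(entry["params"])
            if "buffers" in entry:
                layer.buffers = copy.deepcopy(entry["buffers"])


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy(logits: np.ndarray, onehot: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean categorical cross-entropy and gradient w.r.t. logits."""
    p = softmax(logits)
    n = len(logits)
    loss = -np.sum(onehot * np.log(np.clip(p, 1e-12, None))) / n
    return float(loss), (p - onehot) / n


class Adam:
    def __init__(self, model: Sequential, lr: float = 0.001,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-7):
        self.model = model
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [{k: np.zeros_like(v) for k, v in layer.params.items()}
                  for layer in model.layers]
        self.v = [{k: np.zeros_like(v) for k, v in layer.params.items()}
                  for layer in model.layers]

    def step(self) -> None:
        self.t += 1
        bc1 = 1 - self.b1**self.t
        bc2 = 1 - self.b2**self.t
        for layer, m, v in zip(self.model.layers, self.m, self.v):
            for k, p in layer.params.items():
                g = layer.grads[k]
                m[k] = self.b1 * m[k] + (1 - self.b1) * g
                v[k] = self.b2 * v[k] + (1 - self.b2) * g * g
                p -= self.lr * (m[k] / bc1) / (np.sqrt(v[k] / bc2) + self.eps)


@dataclass
class TrainLog:
    """Per-epoch history (1-based epochs) with early-stopping bookkeeping."""

    train_loss: list[float] = field(default_factory=list)
    train_acc: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_acc: list[float] = field(default_factory=list)
    best_epoch: int = 0
    stop_epoch: int = 0


def evaluate_loss(model: Sequential, x: np.ndarray, onehot: np.ndarray,
                  batch_size: int = 256) -> tuple[float, float]:
    """Mean loss and accuracy at inference (batch-norm uses running stats)."""
    losses, correct = [], 0
    for s in range(0, len(x), batch_size):
        sl = slice(s, min(s + batch_size, len(x)))
        logits = model.forward(x[sl], training=False)
        loss, _ = cross_entropy(logits, onehot[sl])
        losses.append(loss * (sl.stop - s))
        correct += int((logits.argmax(axis=1) == onehot[sl].argmax(axis=1)).sum())
    return float(np.sum(losses) / len(x)), correct / len(x)


def fit(
    model: Sequential,
    x_train: np.ndarray,
    y_train: np.ndarray,
    x_val: np.ndarray,
    y_val: np.ndarray,
    rng: np.random.Generator,
    batch_size: int = 16,
    learning_rate: float = 0.001,
    patience: int = 10,
    max_epochs: int = 200,
) -> TrainLog:
    """Train with Adam and early stopping on validation loss.

    Training halts once the validation loss has failed to improve for
    ``patience`` consecutive epochs (or at ``max_epochs``); the weights
    from the best-validation-loss epoch are restored.
    """
    if len(x_val) == 0:
        raise ValueError("validation set must be non-empty")
    onehot_train = np.eye(2)[np.asarray(y_train, dtype=int)]
    onehot_val = np.eye(2)[np.asarray(y_val, dtype=int)]
    opt = Adam(model, lr=learning_rate)
    log = TrainLog()
    best_loss = np.inf
    best_state = model.get_state()
    wait = 0
    for epoch in range(1, max_epochs + 1):
        order = rng.permutation(len(x_train))
        epoch_loss, epoch_correct = 0.0, 0
        for s in range(0, len(order), batch_size):
            idx = order[s : s + batch_size]
            logits = model.forward(x_train[idx], training=True)
            loss, dlogits = cross_entropy(logits, onehot_train[idx])
            model.backward(dlogits)
            opt.step()
            epoch_loss += loss * len(idx)
            epoch_correct += int(
                (logits.argmax(axis=1) == onehot_train[idx].argmax(axis=1)).sum()
            )
        val_loss, val_acc = evaluate_loss(model, x_val, onehot_val)
        log.train_loss.append(epoch_loss / len(order))
        log.train_acc.append(epoch_correct / len(order))
        log.val_loss.append(val_loss)
        log.val_acc.append(val_acc)
        if val_loss < best_loss:
            best_loss = val_loss
            best_state = model.get_state()
            log.best_epoch = epoch
            wait = 0
        else:
            wait += 1
        log.stop_epoch = epoch
        if wait >= patience:
            break
    model.set_state(best_state)
    return log
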