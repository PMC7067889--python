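"""Compact numpy neural-network core used by the feature extractors.

Implements exactly the pieces the model family needs — 1-D valid
convolution, ReLU, max pooling, dropout, a bidirectional LSTM, dense
layers, a sigmoid/binary-cross-entropy head and Adam — with analytic
gradients (verified against numerical differentiation in the test
suite).  Activations are ``(batch, length, channels)`` arrays.
"""

from __future__ import annotations

import numpy as np


class Param:
    """A trainable array with its gradient accumulator."""

    __slots__ = ("name", "value", "grad")

    def __init__(self, name: str, value: np.ndarray):
        self.name = name
        self.value = value
        self.grad = np.zeros_like(value)


def _glorot(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int, fan_out: int):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class Layer:
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def params(self) -> list[Param]:
        return []

    def out_length(self, t: int) -> int:
        """Sequence length after this layer (for shape planning)."""
        return t


class Conv1D(Layer):
    """Valid 1-D convolution over the length axis."""

    def __init__(self, in_channels: int, out_channels: int, kernel: int,
                 rng: np.random.Generator):
        if kernel < 1:
            raise ValueError("kernel must be >= 1")
        self.kernel = kernel
        self.in_channels = in_channels
        self.out_channels = out_channels
        fan_in, fan_out = kernel * in_channels, out_channels
        self.W = Param("W", _glorot(rng, (kernel * in_channels, out_channels),
                                    fan_in, fan_out))
        self.b = Param("b", np.zeros(out_channels))
        self._cache = None

    def out_length(self, t: int) -> int:
        if t < self.kernel:
            raise ValueError(f"input length {t} < kernel {self.kernel}")
        return t - self.kernel + 1

    def forward(self, x, train=False):
        b, t, c = x.shape
        to = self.out_length(t)
        # windows: (b, to, c, k) -> (b, to, k, c) -> (b*to, k*c)
        win = np.lib.stride_tricks.sliding_window_view(x, self.kernel, axis=1)
        cols = np.ascontiguousarray(win.transpose(0, 1, 3, 2)).reshape(b * to, -1)
        out = cols @ self.W.value + self.b.value
        self._cache = (cols, (b, t, c), to)
        return out.reshape(b, to, self.out_channels)

    def backward(self, dout):
        cols, (b, t, c), to = self._cache
        dflat = dout.reshape(b * to, self.out_channels)
        self.W.grad += cols.T @ dflat
        self.b.grad += dflat.sum(axis=0)
        dcols = (dflat @ self.W.value.T).reshape(b, to, self.kernel, c)
        dx = np.zeros((b, t, c))
        for i in range(self.kernel):
            dx[:, i : i + to, :] += dcols[:, :, i, :]
        return dx

    def params(self):
        return [self.W, self.b]


class ReLU(Layer):
    def forward(self, x, train=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class MaxPool1D(Layer):
    """Non-overlapping max pooling; a trailing remainder is dropped."""

    def __init__(self, pool: int):
        if pool < 1:
            raise ValueError("pool must be >= 1")
        self.pool = pool

    def out_length(self, t: int) -> int:
        if t < self.pool:
            raise ValueError(f"input length {t} < pool {self.pool}")
        return t // self.pool

    def forward(self, x, train=False):
        if self.pool == 1:
            self._passthrough = True
            return x
        self._passthrough = False
        b, t, c = x.shape
        to = t // self.pool
        xt = x[:, : to * self.pool, :].reshape(b, to, self.pool, c)
        self._argmax = xt.argmax(axis=2)
        self._shape = (b, t, c)
        return np.take_along_axis(xt, self._argmax[:, :, None, :], axis=2)[:, :, 0, :]

    def backward(self, dout):
        if self._passthrough:
            return dout
        b, t, c = self._shape
        to = dout.shape[1]
        dxt = np.zeros((b, to, self.pool, c))
        np.put_along_axis(dxt, self._argmax[:, :, None, :], dout[:, :, None, :], axis=2)
        dx = np.zeros((b, t, c))
        dx[:, : to * self.pool, :] = dxt.reshape(b, to * self.pool, c)
        return dx


class Dropout(Layer):
    def __init__(self, rate: float, rng: np.random.Generator):
        if not 0 <= rate < 1:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng

    def forward(self, x, train=False):
        if not train or self.rate == 0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.rate) / (1 - self.rate)
        return x * self._mask

    def backward(self, dout):
        return dout if self._mask is None else dout * self._mask


class _LstmDirection:
    """One LSTM direction; gate order (input, forget, cell, output)."""

    def __init__(self, in_channels: int, hidden: int, rng: np.random.Generator):
        h = hidden
        self.hidden = h
        self.Wx = Param("Wx", _glorot(rng, (in_channels, 4 * h), in_channels, h))
        self.Wh = Param("Wh", _glorot(rng, (h, 4 * h), h, h))
        b = np.zeros(4 * h)
        b[h : 2 * h] = 1.0  # forget-gate bias
        self.b = Param("b", b)

    def forward(self, x):
        b, t, _ = x.shape
        h = self.hidden
        self.x = x
        self.I = np.empty((b, t, h)); self.F = np.empty((b, t, h))
        self.G = np.empty((b, t, h)); self.O = np.empty((b, t, h))
        self.C = np.empty((b, t, h)); self.H = np.empty((b, t, h))
        xw = x @ self.Wx.value  # (b, t, 4h), hoisted out of the loop
        h_prev = np.zeros((b, h)); c_prev = np.zeros((b, h))
        for s in range(t):
            z = xw[:, s] + h_prev @ self.Wh.value + self.b.value
            i = sigmoid(z[:, :h]); f = sigmoid(z[:, h : 2 * h])
            g = np.tanh(z[:, 2 * h : 3 * h]); o = sigmoid(z[:, 3 * h :])
            c = f * c_prev + i * g
            h_prev = o * np.tanh(c)
            self.I[:, s], self.F[:, s], self.G[:, s], self.O[:, s] = i, f, g, o
            self.C[:, s] = c
            self.H[:, s] = h_prev
            c_prev = c
        return self.H

    def backward(self, dh_all):
        b, t, _ = self.x.shape
        h = self.hidden
        dx = np.zeros_like(self.x)
        dh_next = np.zeros((b, h)); dc_next = np.zeros((b, h))
        dz = np.empty((b, 4 * h))
        for s in reversed(range(t)):
            i, f, g, o = self.I[:, s], self.F[:, s], self.G[:, s], self.O[:, s]
            c = self.C[:, s]
            c_prev = self.C[:, s - 1] if s > 0 else np.zeros((b, h))
            h_prev = self.H[:, s - 1] if s > 0 else np.zeros((b, h))
            dh = dh_all[:, s] + dh_next
            tc = np.tanh(c)
            do = dh * tc
            dc = dh * o * (1 - tc**2) + dc_next
            di, df, dg = dc * g, dc * c_prev, dc * i
            dz[:, :h] = di * i * (1 - i)
            dz[:, h : 2 * h] = df * f * (1 - f)
            dz[:, 2 * h : 3 * h] = dg * (1 - g**2)
            dz[:, 3 * h :] = do * o * (1 - o)
            self.Wx.grad += self.x[:, s].T @ dz
            self.Wh.grad += h_prev.T @ dz
            self.b.grad += dz.sum(axis=0)
            dx[:, s] = dz @ self.Wx.value.T
            dh_next = dz @ self.Wh.value.T
            dc_next = dc * f
        return dx


class BiLSTM(Layer):
    """Bidirectional LSTM returning the full sequence of concatenated
    forward/backward hidden states: (b, t, 2*hidden)."""

    def __init__(self, in_channels: int, hidden: int, rng: np.random.Generator):
        self.fwd = _LstmDirection(in_channels, hidden, rng)
        self.bwd = _LstmDirection(in_channels, hidden, rng)
        self.hidden = hidden

    def forward(self, x, train=False):
        hf = self.fwd.forward(x)
        hb = self.bwd.forward(x[:, ::-1, :])[:, ::-1, :]
        return np.concatenate([hf, hb], axis=2)

    def backward(self, dout):
        h = self.hidden
        dxf = self.fwd.backward(dout[:, :, :h])
        dxb = self.bwd.backward(dout[:, ::-1, h:])[:, ::-1, :]
        return dxf + dxb

    def params(self):
        return [self.fwd.Wx, self.fwd.Wh, self.fwd.b,
                self.bwd.Wx, self.bwd.Wh, self.bwd.b]


class Flatten(Layer):
    def forward(self, x, train=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


class Dense(Layer):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        self.W = Param("W", _glorot(rng, (in_features, out_features),
                                    in_features, out_features))
        self.b = Param("b", np.zeros(out_features))

    def forward(self, x, train=False):
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, dout):
        self.W.grad += self._x.T @ dout
        self.b.grad += dout.sum(axis=0)
        return dout @ self.W.value.T

    def params(self):
        return [self.W, self.b]


class Adam:
    def __init__(self, params: list[Param], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self.m, self.v):
            m *= b1; m += (1 - b1) * p.grad
            v *= b2; v += (1 - b2) * p.grad**2
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0


def bce_with_logits(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean binary cross-entropy and its gradient w.r.t. the logits."""
    z = logits.ravel()
    loss = float(np.mean(np.logaddexp(0.0, z) - y * z))
    dz = (sigmoid(z) - y) / len(z)
    return loss, dz.reshape(logits.shape)


class SequentialClassifier:
    """A feed-forward stack ending in one logit, trained with Adam on
    binary cross-entropy.  Deterministic for a fixed rng."""

    def __init__(self, layers: list[Layer], learning_rate: float = 1e-3):
        self.layers = layers
        self.learning_rate = learning_rate
        self.optimizer = Adam(self.params(), lr=learning_rate)
        self.history: dict[str, list[float]] = {"loss": [], "val_loss": []}

    def params(self) -> list[Param]:
        return [p for layer in self.layers for p in layer.params()]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, dout: np.ndarray) -> None:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)

    def predict_proba(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        if len(x) == 0:
            return np.empty(0)
        probs = [
            sigmoid(self.forward(x[i : i + batch_size]).ravel())
            for i in range(0, len(x), batch_size)
        ]
        return np.concatenate(probs)

    def evaluate_loss(self, x: np.ndarray, y: np.ndarray,
                      batch_size: int = 256) -> float:
        total, n = 0.0, len(x)
        for i in range(0, n, batch_size):
            xb, yb = x[i : i + batch_size], y[i : i + batch_size]
            loss, _ = bce_with_logits(self.forward(xb), yb)
            total += loss * len(xb)
        return total / n

    def get_weights(self) -> list[np.ndarray]:
        return [p.value.copy() for p in self.params()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        for p, w in zip(self.params(), weights):
            p.value[...] = w

    def fit(
        self,
        x: np.ndarray,
        y: np.ndarray,
        epochs: int,
        batch_size: int,
        rng: np.random.Generator,
        validation: tuple[np.ndarray, np.ndarray] | None = None,
        patience: int | None = None,
    ) -> dict[str, list[float]]:
        """Minibatch training; optional early stopping on validation loss.

        With ``patience`` set (and validation data), training stops when
        the validation loss has not improved for that many epochs and
        the best weights are restored.
        """
        y = np.asarray(y, dtype=float)
        n = len(x)
        best_val, best_weights, stale = np.inf, None, 0
        for _ in range(epochs):
            order = rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, batch_size):
                idx = order[start : start + batch_size]
                xb, yb = x[idx], y[idx]
                self.optimizer.zero_grad()
                logits = self.forward(xb, train=True)
                loss, dlogits = bce_with_logits(logits, yb)
                self.backward(dlogits)
                self.optimizer.step()
                epoch_loss += loss * len(idx)
            self.history["loss"].append(epoch_loss / n)
            if validation is not None:
                val_loss = self.evaluate_loss(*validation)
                self.history["val_loss"].append(val_loss)
                if patience is not None:
                    if val_loss < best_val - 1e-12:
                        best_val, best_weights, stale = val_loss, self.get_weights(), 0
                    else:
                        stale += 1
                        if stale >= patience:
                            break
        if best_weights is not None:
            self.set_weights(best_weights)
        return self.history
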