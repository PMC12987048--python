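"""Minimal NumPy neural-network engine for 1-D convolutional classifiers.

Implements exactly the layer vocabulary the EEG models need — Conv1D
("same" padding, stride 1) via im2col, max pooling, batch normalization,
dropout, dense layers, global average pooling, and squeeze-and-excitation
gating — with hand-written backward passes, L2 weight regularization, the
Adam optimizer, and a class-weighted soft-label cross-entropy loss.

Computation is float32 throughout; all stochastic layers draw from an
explicitly passed numpy Generator so training is reproducible given a seed.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

DTYPE = np.float32


def _he_normal(rng: np.random.Generator, fan_in: int, shape) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(DTYPE)


class Layer:
    """Base layer: subclasses fill params/grads dicts and the two passes."""

    name: str = ""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}
        self.l2 = 0.0

    def forward(self, x, training=False, rng=None):  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, g):  # pragma: no cover - abstract
        raise NotImplementedError

    @property
    def param_count(self) -> int:
        return int(sum(p.size for p in self.params.values()))

    def l2_loss(self) -> float:
        if self.l2 == 0.0 or "W" not in self.params:
            return 0.0
        return float(self.l2 * np.sum(self.params["W"].astype(np.float64) ** 2))


class Conv1D(Layer):
    """1-D convolution, "same" padding, stride 1, optional ReLU.

    When is_input_layer is set (by Sequential) the backward pass skips the
    gradient with respect to the input, which no one consumes.
    """

    def __init__(self, in_ch: int, filters: int, kernel: int, l2: float = 0.0,
                 activation: str | None = "relu", rng: np.random.Generator | None = None,
                 name: str = "conv1d"):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.in_ch, self.filters, self.kernel = in_ch, filters, kernel
        self.activation = activation
        self.l2 = l2
        self.name = name
        self.is_input_layer = False
        self.params["W"] = _he_normal(rng, kernel * in_ch, (kernel * in_ch, filters))
        self.params["b"] = np.zeros(filters, dtype=DTYPE)

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        B, L, C = x.shape
        k = self.kernel
        left = (k - 1) // 2
        xp = np.zeros((B, L + k - 1, C), dtype=DTYPE)
        xp[:, left : left + L] = x
        cols = np.empty((B, L, k, C), dtype=DTYPE)
        for j in range(k):
            cols[:, :, j, :] = xp[:, j : j + L, :]
        return cols.reshape(B, L, k * C)

    def forward(self, x, training=False, rng=None):
        x = np.ascontiguousarray(x, dtype=DTYPE)
        self._shape = x.shape
        cols = self._im2col(x)
        self._cols = cols
        y = cols @ self.params["W"] + self.params["b"]
        if self.activation == "relu":
            self._mask = y > 0
            y = np.maximum(y, 0.0)
        return y

    def backward(self, g):
        B, L, C = self._shape
        k = self.kernel
        g = g.astype(DTYPE, copy=False)
        if self.activation == "relu":
            g = g * self._mask
        flat_cols = self._cols.reshape(B * L, k * C)
        flat_g = g.reshape(B * L, self.filters)
        self.grads["W"] = flat_cols.T @ flat_g + 2.0 * self.l2 * self.params["W"]
        self.grads["b"] = flat_g.sum(axis=0)
        self._cols = None
        if self.is_input_layer:
            return None
        gcols = (flat_g @ self.params["W"].T).reshape(B, L, k, C)
        left = (k - 1) // 2
        gxp = np.zeros((B, L + k - 1, C), dtype=DTYPE)
        for j in range(k):
            gxp[:, j : j + L, :] += gcols[:, :, j, :]
        return gxp[:, left : left + L, :]


class MaxPool1D(Layer):
    """Non-overlapping max pooling; trailing remainder samples are dropped."""

    def __init__(self, pool: int, name: str = "maxpool"):
        super().__init__()
        self.pool = pool
        self.name = name

    def forward(self, x, training=False, rng=None):
        B, L, C = x.shape
        Lo = L // self.pool
        self._shape = (B, L, C)
        xr = x[:, : Lo * self.pool].reshape(B, Lo, self.pool, C)
        # running pairwise max with first-winner tie-breaking (matches argmax)
        out = xr[:, :, 0, :].copy()
        idx = np.zeros((B, Lo, C), dtype=np.int8)
        for j in range(1, self.pool):
            xj = xr[:, :, j, :]
            better = xj > out
            np.copyto(out, xj, where=better)
            np.copyto(idx, np.int8(j), where=better)
        self._idx = idx
        return out

    def backward(self, g):
        B, L, C = self._shape
        Lo = L // self.pool
        gx = np.zeros((B, Lo, self.pool, C), dtype=DTYPE)
        for j in range(self.pool):
            gx[:, :, j, :] = g * (self._idx == j)
        out = np.zeros((B, L, C), dtype=DTYPE)
        out[:, : Lo * self.pool] = gx.reshape(B, Lo * self.pool, C)
        return out


class BatchNorm(Layer):
    """Batch normalization over the channel (last) axis.

    Works on (B, L, C) and (B, C); keeps exponential running statistics for
    inference.  The default momentum (0.9) adapts within tens of steps,
    suiting the small window counts of subject-level EEG cohorts; running
    stats are seeded from the first training batch.
    """

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-3,
                 name: str = "batchnorm"):
        super().__init__()
        self.momentum, self.eps = momentum, eps
        self.name = name
        self.params["gamma"] = np.ones(channels, dtype=DTYPE)
        self.params["beta"] = np.zeros(channels, dtype=DTYPE)
        self.running_mean = np.zeros(channels, dtype=DTYPE)
        self.running_var = np.ones(channels, dtype=DTYPE)
        self._initialized = False

    def forward(self, x, training=False, rng=None):
        self._shape = x.shape
        flat = x.reshape(-1, x.shape[-1]).astype(DTYPE, copy=False)
        if training:
            mean = flat.mean(axis=0)
            var = flat.var(axis=0)
            if not self._initialized:
                self.running_mean = mean.copy()
                self.running_var = var.copy()
                self._initialized = True
            else:
                m = self.momentum
                self.running_mean = m * self.running_mean + (1 - m) * mean
                self.running_var = m * self.running_var + (1 - m) * var
        else:
            mean, var = self.running_mean, self.running_var
        self._std = np.sqrt(var + self.eps)
        self._xhat = (flat - mean) / self._std
        y = self.params["gamma"] * self._xhat + self.params["beta"]
        self._training = training
        return y.reshape(self._shape)

    def backward(self, g):
        gf = g.reshape(-1, g.shape[-1]).astype(DTYPE, copy=False)
        n = gf.shape[0]
        self.grads["gamma"] = (gf * self._xhat).sum(axis=0)
        self.grads["beta"] = gf.sum(axis=0)
        if self._training:
            gxhat = gf * self.params["gamma"]
            gx = (
                gxhat
                - gxhat.mean(axis=0)
                - self._xhat * (gxhat * self._xhat).mean(axis=0)
            ) / self._std
        else:
            gx = gf * self.params["gamma"] / self._std
        return gx.reshape(self._shape)


class Dropout(Layer):
    """Inverted dropout; identity at inference."""

    def __init__(self, rate: float, name: str = "dropout"):
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.name = name

    def forward(self, x, training=False, rng=None):
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        if rng is None:
            raise ValueError("training-mode dropout needs an rng")
        self._mask = (rng.random(x.shape) >= self.rate).astype(DTYPE) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, g):
        return g if self._mask is None else g * self._mask


class Flatten(Layer):
    def __init__(self, name: str = "flatten"):
        super().__init__()
        self.name = name

    def forward(self, x, training=False, rng=None):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, g):
        return g.reshape(self._shape)


class GlobalAvgPool1D(Layer):
    def __init__(self, name: str = "gap"):
        super().__init__()
        self.name = name

    def forward(self, x, training=False, rng=None):
        self._L = x.shape[1]
        return x.mean(axis=1)

    def backward(self, g):
        return np.repeat(g[:, None, :], self._L, axis=1) / self._L


class Dense(Layer):
    def __init__(self, in_dim: int, units: int, l2: float = 0.0,
                 activation: str | None = None, rng: np.random.Generator | None = None,
                 name: str = "dense"):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.units, self.activation, self.l2 = units, activation, l2
        self.name = name
        self.params["W"] = _he_normal(rng, in_dim, (in_dim, units))
        self.params["b"] = np.zeros(units, dtype=DTYPE)

    def forward(self, x, training=False, rng=None):
        x = x.astype(DTYPE, copy=False)
        self._x = x
        y = x @ self.params["W"] + self.params["b"]
        if self.activation == "relu":
            self._mask = y > 0
            y = np.maximum(y, 0.0)
        return y

    def backward(self, g):
        g = g.astype(DTYPE, copy=False)
        if self.activation == "relu":
            g = g * self._mask
        self.grads["W"] = self._x.T @ g + 2.0 * self.l2 * self.params["W"]
        self.grads["b"] = g.sum(axis=0)
        return g @ self.params["W"].T


class SEBlock(Layer):
    """Squeeze-and-excitation channel gating (reduction r, sigmoid output).

    Squeeze: global average over time; excite: dense(C//r, ReLU) ->
    dense(C, sigmoid); the gate rescales each feature map multiplicatively.
    C//r uses integer floor when C is not divisible by r.
    """

    def __init__(self, channels: int, r: int = 8, rng: np.random.Generator | None = None,
                 name: str = "se"):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        hidden = max(1, channels // r)
        self.name = name
        self.params["W1"] = _he_normal(rng, channels, (channels, hidden))
        self.params["b1"] = np.zeros(hidden, dtype=DTYPE)
        self.params["W2"] = _he_normal(rng, hidden, (hidden, channels))
        self.params["b2"] = np.zeros(channels, dtype=DTYPE)

    def forward(self, x, training=False, rng=None):
        x = x.astype(DTYPE, copy=False)
        self._x = x
        self._L = x.shape[1]
        s = x.mean(axis=1)
        h = np.maximum(s @ self.params["W1"] + self.params["b1"], 0.0)
        gate = 1.0 / (1.0 + np.exp(-(h @ self.params["W2"] + self.params["b2"])))
        self._s, self._h, self._gate = s, h, gate
        return x * gate[:, None, :]

    def backward(self, g):
        g = g.astype(DTYPE, copy=False)
        gx = g * self._gate[:, None, :]
        ggate = (g * self._x).sum(axis=1)
        gz2 = ggate * self._gate * (1.0 - self._gate)
        self.grads["W2"] = self._h.T @ gz2
        self.grads["b2"] = gz2.sum(axis=0)
        gh = (gz2 @ self.params["W2"].T) * (self._h > 0)
        self.grads["W1"] = self._s.T @ gh
        self.grads["b1"] = gh.sum(axis=0)
        gs = gh @ self.params["W1"].T
        gx += gs[:, None, :] / self._L
        return gx


class Sequential:
    """A simple forward/backward chain of layers."""

    def __init__(self, layers: Sequence[Layer]):
        self.layers = list(layers)
        if self.layers and isinstance(self.layers[0], Conv1D):
            self.layers[0].is_input_layer = True

    def forward(self, x, training=False, rng=None):
        for layer in self.layers:
            x = layer.forward(x, training=training, rng=rng)
        return x

    def backward(self, g):
        for layer in reversed(self.layers):
            g = layer.backward(g)
        return g

    @property
    def param_count(self) -> int:
        return sum(layer.param_count for layer in self.layers)

    def l2_loss(self) -> float:
        return sum(layer.l2_loss() for layer in self.layers)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def weighted_softmax_xent(
    logits: np.ndarray, y: np.ndarray, class_weights: np.ndarray | None = None
) -> tuple[float, np.ndarray]:
    """Soft-label cross-entropy with per-class weights.

    y may be one-hot or MixUp-soft; a sample's weight is sum_c y_c * w_c,
    which reduces to the plain class weight for hard labels.  Returns
    (mean weighted loss, gradient w.r.t. logits).
    """
    p = softmax(logits.astype(np.float64))
    n = logits.shape[0]
    w = (
        np.ones(n)
        if class_weights is None
        else y @ np.asarray(class_weights, dtype=np.float64)
    )
    eps = 1e-12
    loss = float(np.mean(w * -(y * np.log(p + eps)).sum(axis=1)))
    grad = (p - y) * w[:, None] / n
    return loss, grad.astype(DTYPE)


class Adam:
    """Adam with optional gradient application over arbitrary param dicts."""

    def __init__(self, lr: float = 1e-3, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-7):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self._m: dict[int, np.ndarray] = {}
        self._v: dict[int, np.ndarray] = {}

    def step(self, layers: Sequence[Layer]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for layer in layers:
            for key, p in layer.params.items():
                g = layer.grads.get(key)
                if g is None:
                    continue
                pid = id(p)
                m = self._m.setdefault(pid, np.zeros_like(p))
                v = self._v.setdefault(pid, np.zeros_like(p))
                m *= b1
                m += (1 - b1) * g
                v *= b2
                v += (1 - b2) * g * g
                mhat = m / (1 - b1 ** self.t)
                vhat = v / (1 - b2 ** self.t)
                p -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(p.dtype)
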