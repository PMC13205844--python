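"""A small, self-contained NumPy neural-network engine.

Implements exactly the layer types the coordinate-regression landmark
network needs: valid-padding 3x3 convolution (stride 1), 2x2 max
pooling, flatten, dense, ReLU, inverted dropout and a sigmoid output,
trained with mean-squared-error loss and the Adam optimizer.  All
computation is float32.  Convolutions are computed as a sum of nine
shifted matrix products (one per kernel tap), which keeps memory flat
and routes the work through BLAS.

Weight initialization is Glorot-uniform; every source of randomness
(init, batch shuffling, dropout masks) is driven by explicit
``numpy.random.Generator`` objects so runs are reproducible.
"""

from __future__ import annotations

import numpy as np

F32 = np.float32


def glorot_uniform(rng: np.random.Generator, shape: tuple[int, ...],
                   fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(F32)


class Layer:
    """Base class: parameterless identity layer."""

    params: list[np.ndarray] = []
    grads: list[np.ndarray] = []

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv2D(Layer):
    """3x3 valid-padding convolution, stride 1, NHWC layout."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator,
                 kernel: int = 3):
        k = kernel
        fan_in = k * k * c_in
        fan_out = k * k * c_out
        self.W = glorot_uniform(rng, (k, k, c_in, c_out), fan_in, fan_out)
        self.b = np.zeros(c_out, dtype=F32)
        self.k = k
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x, training=False):
        self._x = x
        n, h, w, _ = x.shape
        ho, wo = h - self.k + 1, w - self.k + 1
        out = np.empty((n, ho, wo, self.W.shape[-1]), dtype=F32)
        out[:] = self.b
        for di in range(self.k):
            for dj in range(self.k):
                out += x[:, di:di + ho, dj:dj + wo, :] @ self.W[di, dj]
        return out

    def backward(self, dout):
        x = self._x
        n, h, w, _ = x.shape
        ho, wo = dout.shape[1], dout.shape[2]
        dW, db = self.grads
        db[:] = dout.sum(axis=(0, 1, 2))
        dx = np.zeros_like(x)
        for di in range(self.k):
            for dj in range(self.k):
                patch = x[:, di:di + ho, dj:dj + wo, :]
                dW[di, dj] = np.tensordot(patch, dout, axes=([0, 1, 2],
                                                             [0, 1, 2]))
                dx[:, di:di + ho, dj:dj + wo, :] += dout @ self.W[di, dj].T
        self._x = None
        return dx


class MaxPool2D(Layer):
    """2x2 max pooling, stride 2; trailing odd rows/columns are dropped."""

    def forward(self, x, training=False):
        n, h, w, c = x.shape
        ho, wo = h // 2, w // 2
        xr = x[:, :2 * ho, :2 * wo, :].reshape(n, ho, 2, wo, 2, c)
        out = xr.max(axis=(2, 4))
        self._cache = (x.shape, xr, out)
        return out

    def backward(self, dout):
        shape, xr, out = self._cache
        n, ho, _, wo, _, c = xr.shape
        mask = (xr == out[:, :, None, :, None, :])
        counts = mask.sum(axis=(2, 4), keepdims=True)  # tie-splitting
        dxr = mask * (dout[:, :, None, :, None, :] / counts)
        dx = np.zeros(shape, dtype=F32)
        dx[:, :2 * ho, :2 * wo, :] = dxr.reshape(n, 2 * ho, 2 * wo, c)
        self._cache = None
        return dx


class ReLU(Layer):
    def forward(self, x, training=False):
        self._mask = x > 0
        return np.where(self._mask, x, F32(0))

    def backward(self, dout):
        out = dout * self._mask
        self._mask = None
        return out


class Flatten(Layer):
    def forward(self, x, training=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.W = glorot_uniform(rng, (n_in, n_out), n_in, n_out)
        self.b = np.zeros(n_out, dtype=F32)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x, training=False):
        self._x = x
        return x @ self.W + self.b

    def backward(self, dout):
        dW, db = self.grads
        dW[:] = self._x.T @ dout
        db[:] = dout.sum(axis=0)
        dx = dout @ self.W.T
        self._x = None
        return dx


class Dropout(Layer):
    """Inverted dropout: active only during training."""

    def __init__(self, rate: float, rng: np.random.Generator):
        if not 0 <= rate < 1:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng

    def forward(self, x, training=False):
        if not training or self.rate == 0:
            self._mask = None
            return x
        keep = F32(1.0 - self.rate)
        self._mask = (self.rng.random(x.shape, dtype=F32) >= self.rate
                      ).astype(F32) / keep
        return x * self._mask

    def backward(self, dout):
        if self._mask is None:
            return dout
        out = dout * self._mask
        self._mask = None
        return out


class Sigmoid(Layer):
    def forward(self, x, training=False):
        # clip to keep exp() in float32 range; gradients unaffected in practice
        out = 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))
        self._out = out.astype(F32)
        return self._out

    def backward(self, dout):
        out = dout * self._out * (1 - self._out)
        self._out = None
        return out


class Network:
    """A plain feed-forward stack of layers with MSE loss."""

    def __init__(self, layers: list[Layer]):
        self.layers = layers

    @property
    def params(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params]

    @property
    def grads(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, training=training)
        return x

    def backward(self, dout: np.ndarray) -> None:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)

    def train_step(self, x: np.ndarray, y: np.ndarray) -> float:
        """One forward/backward pass; returns the batch MSE loss."""
        pred = self.forward(x, training=True)
        diff = pred - y
        loss = float(np.mean(diff.astype(np.float64) ** 2))
        self.backward((2.0 / diff.size) * diff.astype(F32))
        return loss

    def evaluate_loss(self, x: np.ndarray, y: np.ndarray,
                      batch_size: int = 32) -> float:
        """Mean squared error over a dataset, inference mode."""
        total, count = 0.0, 0
        for i in range(0, len(x), batch_size):
            pred = self.forward(x[i:i + batch_size], training=False)
            d = pred.astype(np.float64) - y[i:i + batch_size]
            total += float((d ** 2).sum())
            count += d.size
        return total / count

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for p in self.params]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        for p, w in zip(self.params, weights, strict=True):
            p[...] = w


class Adam:
    """Adam optimizer with bias correction (Keras-style defaults)."""

    def __init__(self, params: list[np.ndarray], lr: float = 1e-4,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-7):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        lr_t = self.lr * np.sqrt(1 - b2 ** self.t) / (1 - b1 ** self.t)
        for p, g, m, v in zip(self.params, grads, self.m, self.v, strict=True):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * np.square(g)
            p -= F32(lr_t) * m / (np.sqrt(v) + self.eps)
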