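"""Minimal convolutional neural network on numpy arrays.

Implements exactly the layer vocabulary the differentiability test needs —
2-D convolution, ReLU, max-pooling, dropout, flatten, dense, softmax output —
with reverse-mode gradients and an Adam optimizer.  Arrays are NHWC float32;
the softmax/cross-entropy pair is fused for numerical stability.

The network is deliberately small and CPU-oriented: convolutions are lowered
to matrix products via im2col, so a full forward/backward pass is a handful
of BLAS calls.  Gradient correctness is covered by finite-difference tests.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Conv2D",
    "ReLU",
    "MaxPool2D",
    "Dropout",
    "Flatten",
    "Dense",
    "Sequential",
    "Adam",
    "softmax",
]


def _glorot_uniform(fan_in: int, fan_out: int, shape: tuple,
                    rng: np.random.Generator) -> np.ndarray:
    """Glorot/Xavier uniform init — keeps initial logits near zero so the
    first optimizer steps are spent learning, not unwinding confident
    random predictions."""
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(np.float32)


def softmax(logits: np.ndarray) -> np.ndarray:
    """Row-wise softmax, shifted by the row max for stability."""
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


class Layer:
    """Base layer: stateless unless it declares ``params``/``grads``."""

    params: dict
    grads: dict

    def __init__(self):
        self.params = {}
        self.grads = {}

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def n_params(self) -> int:
        return int(sum(p.size for p in self.params.values()))


def _im2col(x: np.ndarray, kh: int, kw: int) -> np.ndarray:
    """Gather all kh×kw patches ('valid' positions) into a matrix.

    x: (N, H, W, C) → (N, Ho, Wo, kh*kw*C) with Ho = H-kh+1, Wo = W-kw+1.
    """
    n, h, w, c = x.shape
    ho, wo = h - kh + 1, w - kw + 1
    cols = np.empty((n, ho, wo, kh * kw, c), dtype=x.dtype)
    for i in range(kh):
        for j in range(kw):
            cols[:, :, :, i * kw + j, :] = x[:, i : i + ho, j : j + wo, :]
    return cols.reshape(n, ho, wo, kh * kw * c)


class Conv2D(Layer):
    """3×3-style valid convolution (no padding, stride 1)."""

    def __init__(self, in_channels: int, filters: int, kernel_size: int,
                 rng: np.random.Generator):
        super().__init__()
        self.kh = self.kw = int(kernel_size)
        self.in_channels = in_channels
        self.filters = filters
        fan_in = self.kh * self.kw * in_channels
        fan_out = self.kh * self.kw * filters
        self.params = {"W": _glorot_uniform(fan_in, fan_out, (fan_in, filters), rng),
                       "b": np.zeros(filters, dtype=np.float32)}

    def forward(self, x, training=False):
        n, h, w, _ = x.shape
        if h < self.kh or w < self.kw:
            raise ValueError(
                f"input {h}x{w} smaller than {self.kh}x{self.kw} kernel"
            )
        cols = _im2col(x, self.kh, self.kw)
        self._cache = (x.shape, cols)
        out = cols @ self.params["W"] + self.params["b"]
        return out

    def backward(self, dout):
        x_shape, cols = self._cache
        n, ho, wo, f = dout.shape
        k = self.kh * self.kw * self.in_channels
        cols2 = cols.reshape(-1, k)
        dflat = dout.reshape(-1, f)
        self.grads = {"W": cols2.T @ dflat, "b": dflat.sum(axis=0)}
        dcols = (dflat @ self.params["W"].T).reshape(
            n, ho, wo, self.kh * self.kw, self.in_channels
        )
        dx = np.zeros(x_shape, dtype=dout.dtype)
        for i in range(self.kh):
            for j in range(self.kw):
                dx[:, i : i + ho, j : j + wo, :] += dcols[:, :, :, i * self.kw + j, :]
        return dx


class ReLU(Layer):
    def forward(self, x, training=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class MaxPool2D(Layer):
    """Non-overlapping max pooling; trailing rows/cols that do not fill a
    window are dropped (the common 'valid' convention)."""

    def __init__(self, pool_size: int = 2):
        super().__init__()
        self.p = int(pool_size)

    def forward(self, x, training=False):
        p = self.p
        n, h, w, c = x.shape
        ho, wo = h // p, w // p
        if ho == 0 or wo == 0:
            raise ValueError(f"input {h}x{w} too small for pool size {p}")
        xt = x[:, : ho * p, : wo * p, :]
        patches = (
            xt.reshape(n, ho, p, wo, p, c)
            .transpose(0, 1, 3, 5, 2, 4)
            .reshape(n, ho, wo, c, p * p)
        )
        self._argmax = patches.argmax(axis=-1)
        self._x_shape = x.shape
        return patches.max(axis=-1)

    def backward(self, dout):
        p = self.p
        n, ho, wo, c = dout.shape
        dpatch = np.zeros((n, ho, wo, c, p * p), dtype=dout.dtype)
        np.put_along_axis(dpatch, self._argmax[..., None], dout[..., None], axis=-1)
        dx = np.zeros(self._x_shape, dtype=dout.dtype)
        dx[:, : ho * p, : wo * p, :] = (
            dpatch.reshape(n, ho, wo, c, p, p)
            .transpose(0, 1, 4, 2, 5, 3)
            .reshape(n, ho * p, wo * p, c)
        )
        return dx


class Dropout(Layer):
    """Inverted dropout: active only during training; identity at inference."""

    def __init__(self, rate: float, rng: np.random.Generator):
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"dropout rate must be in [0, 1), got {rate}")
        self.rate = float(rate)
        self.rng = rng

    def forward(self, x, training=False):
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, dout):
        return dout if self._mask is None else dout * self._mask


class Flatten(Layer):
    def forward(self, x, training=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


class Dense(Layer):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        super().__init__()
        self.params = {
            "W": _glorot_uniform(in_features, out_features,
                                 (in_features, out_features), rng),
            "b": np.zeros(out_features, dtype=np.float32),
        }

    def forward(self, x, training=False):
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dout):
        self.grads = {"W": self._x.T @ dout, "b": dout.sum(axis=0)}
        return dout @ self.params["W"].T


class Adam:
    """Adam with the usual bias-corrected first/second moments."""

    def __init__(self, layers, learning_rate=1e-3, beta1=0.9, beta2=0.999,
                 epsilon=1e-7):
        self.layers = [l for l in layers if l.params]
        self.lr = learning_rate
        self.b1, self.b2, self.eps = beta1, beta2, epsilon
        self.t = 0
        self.m = [{k: np.zeros_like(v) for k, v in l.params.items()}
                  for l in self.layers]
        self.v = [{k: np.zeros_like(v) for k, v in l.params.items()}
                  for l in self.layers]

    def step(self):
        self.t += 1
        lr_t = self.lr * np.sqrt(1 - self.b2 ** self.t) / (1 - self.b1 ** self.t)
        for layer, m, v in zip(self.layers, self.m, self.v):
            for k, p in layer.params.items():
                g = layer.grads[k]
                m[k] = self.b1 * m[k] + (1 - self.b1) * g
                v[k] = self.b2 * v[k] + (1 - self.b2) * g * g
                p -= lr_t * m[k] / (np.sqrt(v[k]) + self.eps)


class Sequential:
    """A feed-forward stack ending in a linear (logit) layer.

    The final softmax is folded into :meth:`loss_and_grad`; ``predict_proba``
    applies it explicitly.
    """

    def __init__(self, layers):
        self.layers = list(layers)

    # -- inference ---------------------------------------------------------
    def forward(self, x, training=False):
        for layer in self.layers:
            x = layer.forward(x, training=training)
        return x

    def predict_proba(self, x):
        return softmax(self.forward(x, training=False))

    def forward_from(self, layer_index: int, activation: np.ndarray) -> np.ndarray:
        """Run the tail of the network starting *after* ``layer_index``.

        Used by finite-difference checks of intermediate-layer gradients.
        """
        x = activation
        for layer in self.layers[layer_index + 1 :]:
            x = layer.forward(x, training=False)
        return x

    # -- training ----------------------------------------------------------
    def loss_and_grad(self, x, y):
        """Mean cross-entropy of softmax(logits) against integer labels y;
        backpropagates and leaves gradients on the layers."""
        logits = self.forward(x, training=True)
        n = logits.shape[0]
        p = softmax(logits)
        eps = 1e-12
        loss = -np.log(p[np.arange(n), y] + eps).mean()
        dlogits = p.copy()
        dlogits[np.arange(n), y] -= 1.0
        dlogits /= n
        dout = dlogits.astype(np.float32)
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return float(loss)

    # -- introspection -----------------------------------------------------
    def n_params(self) -> int:
        return sum(l.n_params() for l in self.layers)

    def activation_and_gradient(self, x, target_class: int, layer_index: int):
        """Activation A of layers[layer_index] and d(logit[target])/dA.

        The class score is the pre-softmax logit, the convention of
        gradient-weighted class-activation mapping.  Dropout is inactive
        (inference mode), so the map is deterministic.
        """
        a = x
        acts = []
        for layer in self.layers:
            a = layer.forward(a, training=False)
            acts.append(a)
        logits = acts[-1]
        dout = np.zeros_like(logits)
        dout[:, target_class] = 1.0
        for layer in reversed(self.layers[layer_index + 1 :]):
            dout = layer.backward(dout)
        return acts[layer_index], dout
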