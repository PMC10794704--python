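"""Minimal NHWC convolutional-network engine with reverse-mode gradients.

All layers operate on ``float32`` arrays of shape ``(N, H, W, C)`` (dense
layers on ``(N, C)``).  Convolutions are stride-1 with odd kernels and
"same" zero padding; pooling is non-overlapping with window == stride,
which is exactly the geometry the classifier needs (VGG-style stacks and
pyramid-pooling levels).  Everything is seeded through
``numpy.random.Generator`` so identical seeds give identical parameters
and identical training trajectories.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Parameter",
    "Layer",
    "Conv2D",
    "ReLU",
    "MaxPool2D",
    "UpsampleNearest",
    "GlobalAvgPool",
    "Dense",
    "Sequential",
    "Concat",
    "Network",
    "Adam",
    "softmax",
    "softmax_cross_entropy",
    "upsample_nearest",
    "max_pool",
    "relu",
]


class Parameter:
    """A trainable array plus its accumulated gradient."""

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)


def relu(z: np.ndarray) -> np.ndarray:
    """Element-wise max(0, z)."""
    return np.maximum(z, 0)


def softmax(z: np.ndarray, axis: int = -1) -> np.ndarray:
    """Numerically stable softmax along ``axis``."""
    z = np.asarray(z, dtype=np.float64)
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray):
    """Mean cross-entropy over integer labels.

    Returns ``(loss, probs, dlogits)`` where ``dlogits`` is the gradient of
    the mean loss with respect to ``logits``.
    """
    labels = np.asarray(labels)
    n = logits.shape[0]
    probs = softmax(logits, axis=1)
    picked = np.clip(probs[np.arange(n), labels], 1e-12, None)
    loss = float(-np.log(picked).mean())
    dlogits = probs.copy()
    dlogits[np.arange(n), labels] -= 1.0
    dlogits /= n
    return loss, probs, dlogits.astype(np.float32)


def upsample_nearest(x: np.ndarray, s: int) -> np.ndarray:
    """Nearest-neighbour upsampling: U(i, j) = I(floor(i/s), floor(j/s)).

    Works on (H, W), (H, W, C) or (N, H, W, C) arrays; the two spatial axes
    are the first two (or, with a batch axis, axes 1 and 2).
    """
    x = np.asarray(x)
    if x.ndim == 2:
        return x.repeat(s, axis=0).repeat(s, axis=1)
    if x.ndim == 3:
        return x.repeat(s, axis=0).repeat(s, axis=1)
    return x.repeat(s, axis=1).repeat(s, axis=2)


def max_pool(x: np.ndarray, s: int) -> np.ndarray:
    """Non-overlapping max pooling with window ``s`` and stride ``s``."""
    x = np.asarray(x)
    if x.ndim == 2:
        return max_pool(x[..., None], s)[..., 0]
    if x.ndim == 3:
        h, w, c = x.shape
        if h % s or w % s:
            raise ValueError(f"spatial dims {(h, w)} not divisible by pool size {s}")
        return x.reshape(h // s, s, w // s, s, c).max(axis=(1, 3))
    n, h, w, c = x.shape
    if h % s or w % s:
        raise ValueError(f"spatial dims {(h, w)} not divisible by pool size {s}")
    return x.reshape(n, h // s, s, w // s, s, c).max(axis=(2, 4))


class Layer:
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, gy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def parameters(self) -> list[Parameter]:
        return []


class Conv2D(Layer):
    """Stride-1 convolution with odd kernel and same zero padding.

    Weights use He-normal initialisation drawn from the supplied generator.
    """

    def __init__(self, in_channels: int, out_channels: int, kernel: int,
                 rng: np.random.Generator):
        if kernel < 1 or kernel % 2 == 0:
            raise ValueError("kernel must be odd and >= 1")
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel = kernel
        fan_in = in_channels * kernel * kernel
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                       size=(fan_in, out_channels))
        self.w = Parameter(w)
        self.b = Parameter(np.zeros(out_channels))
        self._cols = None
        self._xshape = None

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        k = self.kernel
        p = k // 2
        if p:
            x = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
        win = sliding_window_view(x, (k, k), axis=(1, 2))  # N,H,W,C,k,k
        n, h, w = win.shape[:3]
        return np.ascontiguousarray(win).reshape(n, h, w, -1)

    def forward(self, x, train=False):
        x = np.asarray(x, dtype=np.float32)
        cols = self._im2col(x)
        if train:
            self._cols = cols
            self._xshape = x.shape
        n, h, w, _ = cols.shape
        y = cols.reshape(-1, cols.shape[-1]) @ self.w.value + self.b.value
        return y.reshape(n, h, w, self.out_channels)

    def backward(self, gy):
        cols, (n, h, w, c) = self._cols, self._xshape
        k = self.kernel
        p = k // 2
        gy2 = gy.reshape(-1, self.out_channels).astype(np.float32)
        self.w.grad += cols.reshape(-1, cols.shape[-1]).T @ gy2
        self.b.grad += gy2.sum(axis=0)
        gcols = (gy2 @ self.w.value.T).reshape(n, h, w, c, k, k)
        gxp = np.zeros((n, h + 2 * p, w + 2 * p, c), dtype=np.float32)
        for di in range(k):
            for dj in range(k):
                gxp[:, di:di + h, dj:dj + w, :] += gcols[:, :, :, :, di, dj]
        self._cols = None
        return gxp[:, p:p + h, p:p + w, :] if p else gxp

    def parameters(self):
        return [self.w, self.b]


class ReLU(Layer):
    def forward(self, x, train=False):
        y = np.maximum(x, 0)
        if train:
            self._mask = x > 0
        return y

    def backward(self, gy):
        return gy * self._mask


class MaxPool2D(Layer):
    """Window-``s``, stride-``s`` max pooling (no overlap)."""

    def __init__(self, s: int):
        if s < 2:
            raise ValueError("pool size must be >= 2")
        self.s = s

    def forward(self, x, train=False):
        s = self.s
        n, h, w, c = x.shape
        if h % s or w % s:
            raise ValueError(f"spatial dims {(h, w)} not divisible by pool size {s}")
        r = x.reshape(n, h // s, s, w // s, s, c)
        r = r.transpose(0, 1, 3, 5, 2, 4).reshape(n, h // s, w // s, c, s * s)
        idx = r.argmax(axis=-1)
        y = np.take_along_axis(r, idx[..., None], axis=-1)[..., 0]
        if train:
            self._idx = idx
            self._xshape = (n, h, w, c)
        return y

    def backward(self, gy):
        s = self.s
        n, h, w, c = self._xshape
        gr = np.zeros((n, h // s, w // s, c, s * s), dtype=np.float32)
        np.put_along_axis(gr, self._idx[..., None], gy[..., None], axis=-1)
        gr = gr.reshape(n, h // s, w // s, c, s, s).transpose(0, 1, 4, 2, 5, 3)
        return gr.reshape(n, h, w, c)


class UpsampleNearest(Layer):
    def __init__(self, s: int):
        if s < 2:
            raise ValueError("upsample factor must be >= 2")
        self.s = s

    def forward(self, x, train=False):
        return x.repeat(self.s, axis=1).repeat(self.s, axis=2)

    def backward(self, gy):
        s = self.s
        n, h, w, c = gy.shape
        return gy.reshape(n, h // s, s, w // s, s, c).sum(axis=(2, 4))


class GlobalAvgPool(Layer):
    """Mean of each feature map over both spatial axes: (N,H,W,C) -> (N,C)."""

    def forward(self, x, train=False):
        self._xshape = x.shape
        return x.mean(axis=(1, 2))

    def backward(self, gy):
        n, h, w, c = self._xshape
        return np.broadcast_to(gy[:, None, None, :] / (h * w), (n, h, w, c)).astype(np.float32)


class Dense(Layer):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        w = rng.normal(0.0, np.sqrt(2.0 / in_features), size=(in_features, out_features))
        self.w = Parameter(w)
        self.b = Parameter(np.zeros(out_features))

    def forward(self, x, train=False):
        if train:
            self._x = x
        return x @ self.w.value + self.b.value

    def backward(self, gy):
        self.w.grad += self._x.T @ gy
        self.b.grad += gy.sum(axis=0)
        return gy @ self.w.value.T

    def parameters(self):
        return [self.w, self.b]


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = list(layers)

    def forward(self, x, train=False):
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, gy):
        for layer in reversed(self.layers):
            gy = layer.backward(gy)
        return gy

    def parameters(self):
        return [p for layer in self.layers for p in layer.parameters()]


class Concat(Layer):
    """Run branches on the same input and concatenate outputs channel-wise."""

    def __init__(self, branches: list[Layer]):
        if not branches:
            raise ValueError("Concat needs at least one branch")
        self.branches = list(branches)

    def forward(self, x, train=False):
        outs = [b.forward(x, train=train) for b in self.branches]
        self._widths = [o.shape[-1] for o in outs]
        return np.concatenate(outs, axis=-1)

    def backward(self, gy):
        gx = None
        start = 0
        for b, w in zip(self.branches, self._widths):
            g = b.backward(gy[..., start:start + w])
            gx = g if gx is None else gx + g
            start += w
        return gx

    def parameters(self):
        return [p for b in self.branches for p in b.parameters()]


class Network:
    """Feature extractor + linear classification head.

    ``features`` must map image batches to ``(N, D)`` vectors (its last stage
    is global average pooling); ``head`` is the final dense layer producing
    logits.  ``predict_proba`` applies the softmax of the output layer.
    """

    def __init__(self, features: Layer, head: Dense):
        self.features = features
        self.head = head

    def logits(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        return self.head.forward(self.features.forward(x, train=train), train=train)

    def predict_proba(self, x: np.ndarray, batch_size: int = 64) -> np.ndarray:
        x = np.asarray(x, dtype=np.float32)
        out = []
        for i in range(0, x.shape[0], batch_size):
            out.append(softmax(self.logits(x[i:i + batch_size]), axis=1))
        return np.concatenate(out, axis=0)

    def embeddings(self, x: np.ndarray, batch_size: int = 64) -> np.ndarray:
        x = np.asarray(x, dtype=np.float32)
        out = []
        for i in range(0, x.shape[0], batch_size):
            out.append(self.features.forward(x[i:i + batch_size]))
        return np.concatenate(out, axis=0)

    def backward(self, dlogits: np.ndarray) -> None:
        self.features.backward(self.head.backward(dlogits))

    def parameters(self) -> list[Parameter]:
        return self.features.parameters() + self.head.parameters()

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad[...] = 0.0

    def state_dict(self) -> list[np.ndarray]:
        return [p.value.copy() for p in self.parameters()]

    def load_state_dict(self, state: list[np.ndarray]) -> None:
        params = self.parameters()
        if len(state) != len(params):
            raise ValueError("state does not match network parameters")
        for p, v in zip(params, state):
            if p.value.shape != v.shape:
                raise ValueError("parameter shape mismatch")
            p.value[...] = v


class Adam:
    """Adam optimiser (Kingma & Ba) over a list of :class:`Parameter`."""

    def __init__(self, params: list[Parameter], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr = float(lr)
        self.beta1 = float(beta1)
        self.beta2 = float(beta2)
        self.eps = float(eps)
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * (g * g)
            p.value -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
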