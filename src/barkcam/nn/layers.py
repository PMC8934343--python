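"""Minimal NHWC layer library with explicit forward/backward passes.

Written for desk-scale networks: convolutions use im2col via
numpy.lib.stride_tricks.sliding_window_view, so everything reduces to dense
tensordot calls.  Each layer caches what its backward pass needs on the layer
instance; `backward` must follow the matching `forward`.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Layer", "Conv2D", "ReLU", "MaxPool2", "Flatten", "GlobalAvgPool", "Dropout", "Dense"]


class Layer:
    """Base layer. Parameters live in .params / gradients in .grads (dicts)."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, train: bool = False, rng: np.random.Generator | None = None) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError


def _im2col(x: np.ndarray, kh: int, kw: int) -> np.ndarray:
    # x: (N, H+kh-1, W+kw-1, C) already padded -> (N, H, W, kh, kw, C)
    return np.lib.stride_tricks.sliding_window_view(x, (kh, kw), axis=(1, 2)).transpose(0, 1, 2, 4, 5, 3)


class Conv2D(Layer):
    """3x3-style 'same' convolution, stride 1, He-initialized."""

    def __init__(self, c_in: int, c_out: int, ksize: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.ksize = ksize
        scale = np.sqrt(2.0 / (ksize * ksize * c_in))
        self.params["W"] = rng.normal(0.0, scale, size=(ksize, ksize, c_in, c_out)).astype(np.float64)
        self.params["b"] = np.zeros(c_out)

    def forward(self, x, train=False, rng=None):
        k = self.ksize
        p = k // 2
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
        self._cols = _im2col(xp, k, k)  # (N, H, W, k, k, Cin)
        return np.tensordot(self._cols, self.params["W"], axes=([3, 4, 5], [0, 1, 2])) + self.params["b"]

    def backward(self, dout):
        k = self.ksize
        p = k // 2
        self.grads["W"] = np.tensordot(self._cols, dout, axes=([0, 1, 2], [0, 1, 2]))
        self.grads["b"] = dout.sum(axis=(0, 1, 2))
        # full correlation of dout with the spatially flipped, channel-swapped kernel
        w_flip = self.params["W"][::-1, ::-1].transpose(0, 1, 3, 2)  # (k, k, Cout, Cin)
        dp = np.pad(dout, ((0, 0), (p, p), (p, p), (0, 0)))
        cols = _im2col(dp, k, k)
        return np.tensordot(cols, w_flip, axes=([3, 4, 5], [0, 1, 2]))


class ReLU(Layer):
    def forward(self, x, train=False, rng=None):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dout):
        return np.where(self._mask, dout, 0.0)


class MaxPool2(Layer):
    """2x2 max pooling, stride 2; input spatial dims must be even."""

    def forward(self, x, train=False, rng=None):
        n, h, w, c = x.shape
        if h % 2 or w % 2:
            raise ValueError("MaxPool2 requires even spatial dims")
        xr = x.reshape(n, h // 2, 2, w // 2, 2, c)
        out = xr.max(axis=(2, 4))
        # argmax mask; gradient splits evenly across ties (ties vanish for
        # generic float activations)
        eq = xr == out[:, :, None, :, None, :]
        self._mask = eq / eq.sum(axis=(2, 4), keepdims=True)
        self._in_shape = x.shape
        return out

    def backward(self, dout):
        n, h, w, c = self._in_shape
        d = self._mask * dout[:, :, None, :, None, :]
        return d.reshape(n, h, w, c)


class Flatten(Layer):
    def forward(self, x, train=False, rng=None):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


class GlobalAvgPool(Layer):
    """Spatial mean per feature map: (N, H, W, C) -> (N, C)."""

    def forward(self, x, train=False, rng=None):
        self._shape = x.shape
        return x.mean(axis=(1, 2))

    def backward(self, dout):
        n, h, w, c = self._shape
        return np.broadcast_to(dout[:, None, None, :] / (h * w), self._shape).copy()


class Dropout(Layer):
    """Inverted dropout: identity at inference."""

    def __init__(self, rate: float) -> None:
        super().__init__()
        if not (0.0 <= rate < 1.0):
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate

    def forward(self, x, train=False, rng=None):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        if rng is None:
            raise ValueError("training-mode dropout needs an rng")
        self._mask = (rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, dout):
        return dout if self._mask is None else dout * self._mask


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator) -> None:
        super().__init__()
        scale = np.sqrt(2.0 / n_in)
        self.params["W"] = rng.normal(0.0, scale, size=(n_in, n_out)).astype(np.float64)
        self.params["b"] = np.zeros(n_out)

    def forward(self, x, train=False, rng=None):
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dout):
        self.grads["W"] = self._x.T @ dout
        self.grads["b"] = dout.sum(axis=0)
        return dout @ self.params["W"].T
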