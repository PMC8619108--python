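"""Minimal numpy layers for the keypoint-channel CNN.

Only what the encoder-decoder needs: 3x3 same convolution (zero
padding, stride 1), 2x2 max pooling, 2x nearest-neighbour upsampling,
channel concatenation, ReLU, and Adam.  Tensors are NHWC ``float32``.
All forward passes cache what their backward pass needs.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Conv3x3:
    """3x3 convolution, zero padding, stride 1, optional ReLU."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator,
                 relu: bool = True):
        fan_in = 9 * c_in
        self.W = (rng.standard_normal((3, 3, c_in, c_out))
                  * np.sqrt(2.0 / fan_in)).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.relu = relu
        self.c_in, self.c_out = c_in, c_out
        self._xp = None
        self._mask = None
        self.dW = None
        self.db = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (0, 0)))
        win = sliding_window_view(xp, (3, 3), axis=(1, 2))  # N,H,W,C,3,3
        y = np.einsum("nhwcij,ijco->nhwo", win, self.W, optimize=True)
        y += self.b
        if self.relu:
            mask = y > 0
            y *= mask
        else:
            mask = None
        if train:
            self._xp, self._mask = xp, mask
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        if self.relu:
            dy = dy * self._mask
        win = sliding_window_view(self._xp, (3, 3), axis=(1, 2))
        self.db = dy.sum(axis=(0, 1, 2))
        self.dW = np.einsum("nhwcij,nhwo->ijco", win, dy, optimize=True)
        Wf = self.W[::-1, ::-1]  # spatially flipped kernel
        dyp = np.pad(dy, ((0, 0), (1, 1), (1, 1), (0, 0)))
        dwin = sliding_window_view(dyp, (3, 3), axis=(1, 2))  # N,H,W,O,3,3
        dx = np.einsum("nhwoij,ijco->nhwc", dwin, Wf, optimize=True)
        self._xp = self._mask = None
        return dx

    def params(self):
        return [("W", self), ("b", self)]


class MaxPool2:
    def __init__(self):
        self._idx = None
        self._shape = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, h, w, c = x.shape
        xr = (x.reshape(n, h // 2, 2, w // 2, 2, c)
               .transpose(0, 1, 3, 2, 4, 5)
               .reshape(n, h // 2, w // 2, 4, c))
        idx = xr.argmax(axis=3)
        y = np.take_along_axis(xr, idx[:, :, :, None, :], axis=3)[:, :, :, 0, :]
        if train:
            self._idx, self._shape = idx, x.shape
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, h, w, c = self._shape
        gr = np.zeros((n, h // 2, w // 2, 4, c), dtype=dy.dtype)
        np.put_along_axis(gr, self._idx[:, :, :, None, :],
                          dy[:, :, :, None, :], axis=3)
        dx = (gr.reshape(n, h // 2, w // 2, 2, 2, c)
                .transpose(0, 1, 3, 2, 4, 5)
                .reshape(n, h, w, c))
        self._idx = self._shape = None
        return dx


class Upsample2:
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        return x.repeat(2, axis=1).repeat(2, axis=2)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, h, w, c = dy.shape
        return (dy.reshape(n, h // 2, 2, w // 2, 2, c)
                  .sum(axis=(2, 4)))


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_loss(p: np.ndarray, t: np.ndarray, eps: float = 1e-7) -> float:
    p = np.clip(p, eps, 1.0 - eps)
    return float(-(t * np.log(p) + (1 - t) * np.log(1 - p)).mean())


class Adam:
    def __init__(self, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.state: dict = {}

    def step(self, layers) -> None:
        self.t += 1
        for li, layer in enumerate(layers):
            if not isinstance(layer, Conv3x3):
                continue
            for name, grad in (("W", layer.dW), ("b", layer.db)):
                key = (li, name)
                if key not in self.state:
                    self.state[key] = (np.zeros_like(grad),
                                       np.zeros_like(grad))
                m, v = self.state[key]
                m = self.b1 * m + (1 - self.b1) * grad
                v = self.b2 * v + (1 - self.b2) * grad ** 2
                self.state[key] = (m, v)
                mhat = m / (1 - self.b1 ** self.t)
                vhat = v / (1 - self.b2 ** self.t)
                p = getattr(layer, name)
                p -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(p.dtype)
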