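"""Minimal NumPy convolutional-network engine.

Implements exactly the layers an encoder–decoder segmentation network
needs — same-padding 3x3 and 1x1 convolutions, ReLU, 2x2 max pooling, 2x2
stride-2 transposed convolution, channel concatenation — each with a
hand-coded backward pass, plus the Adam optimizer.  Arrays are NCHW
``float32``.  Convolutions run as im2col matrix products; the gradient with
respect to the input of a same-padded stride-1 convolution is computed as a
full convolution with the spatially flipped kernel, so no scatter (col2im)
step is needed.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Conv2d", "ReLU", "MaxPool2", "UpConv2", "Adam", "he_init"]

DTYPE = np.float32


def he_init(rng: np.random.Generator, shape: tuple, fan_in: int) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(DTYPE)


class Layer:
    """Base: parameterized layers expose aligned params()/grads() lists."""

    def params(self) -> list:
        return []

    def grads(self) -> list:
        return []


class Conv2d(Layer):
    """Same-padding stride-1 convolution with kernel size 3 or 1."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator, kernel: int = 3):
        if kernel not in (1, 3):
            raise ValueError("only 1x1 and 3x3 kernels are supported")
        self.c_in = c_in
        self.c_out = c_out
        self.kernel = kernel
        self.W = he_init(rng, (c_out, c_in, kernel, kernel), c_in * kernel * kernel)
        self.b = np.zeros(c_out, dtype=DTYPE)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._cols = None
        self._in_shape = None

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, c, h, w = x.shape
        if self.kernel == 1:
            cols = x.transpose(0, 2, 3, 1).reshape(-1, c)
        else:
            xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
            win = sliding_window_view(xp, (3, 3), axis=(2, 3))  # n,c,h,w,3,3
            cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * h * w, c * 9)
        y = cols @ self.W.reshape(self.c_out, -1).T + self.b
        if train:
            self._cols = cols
            self._in_shape = x.shape
        return np.ascontiguousarray(y.reshape(n, h, w, self.c_out).transpose(0, 3, 1, 2))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, h, w = self._in_shape
        dyf = dy.transpose(0, 2, 3, 1).reshape(-1, self.c_out)
        self.dW[...] = (dyf.T @ self._cols).reshape(self.W.shape)
        self.db[...] = dyf.sum(axis=0)
        if self.kernel == 1:
            dx = (dyf @ self.W.reshape(self.c_out, -1)).reshape(n, h, w, c)
            return np.ascontiguousarray(dx.transpose(0, 3, 1, 2))
        # dx = full conv of dy with the flipped kernel
        dyp = np.pad(dy, ((0, 0), (0, 0), (1, 1), (1, 1)))
        win = sliding_window_view(dyp, (3, 3), axis=(2, 3))
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * h * w, self.c_out * 9)
        w_flip = self.W[:, :, ::-1, ::-1].transpose(1, 0, 2, 3).reshape(c, -1)
        dx = (cols @ w_flip.T).reshape(n, h, w, c)
        self._cols = None
        return np.ascontiguousarray(dx.transpose(0, 3, 1, 2))


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        y = np.maximum(x, 0)
        if train:
            self._mask = x > 0
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class MaxPool2(Layer):
    """2x2 max pooling with stride 2 (input sides must be even)."""

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, c, h, w = x.shape
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        xr = xr.reshape(n, c, h // 2, w // 2, 4)
        idx = xr.argmax(axis=-1)
        y = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]
        if train:
            self._idx = idx
            self._in_shape = x.shape
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, h, w = self._in_shape
        dxr = np.zeros((n, c, h // 2, w // 2, 4), dtype=dy.dtype)
        np.put_along_axis(dxr, self._idx[..., None], dy[..., None], axis=-1)
        dx = dxr.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return np.ascontiguousarray(dx.reshape(n, c, h, w))


class UpConv2(Layer):
    """2x2 stride-2 transposed convolution (doubles the spatial size).

    Each input pixel maps to a disjoint 2x2 output block, so both passes are
    plain einsums without overlap handling.
    """

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        self.c_in = c_in
        self.c_out = c_out
        self.W = he_init(rng, (c_in, c_out, 2, 2), c_in)
        self.b = np.zeros(c_out, dtype=DTYPE)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, c, h, w = x.shape
        if train:
            self._x = x
        y = np.einsum("nchw,cduv->ndhuwv", x, self.W, optimize=True)
        y = y.reshape(n, self.c_out, 2 * h, 2 * w) + self.b[None, :, None, None]
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, d, h2, w2 = dy.shape
        dyr = dy.reshape(n, d, h2 // 2, 2, w2 // 2, 2)
        self.dW[...] = np.einsum("nchw,ndhuwv->cduv", self._x, dyr, optimize=True)
        self.db[...] = dy.sum(axis=(0, 2, 3))
        dx = np.einsum("ndhuwv,cduv->nchw", dyr, self.W, optimize=True)
        self._x = None
        return dx


class Adam:
    """Adam with bias correction; ``lr`` may be changed between steps."""

    def __init__(self, params: list, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]

    def step(self, grads: list) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * (g * g)
            p -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
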