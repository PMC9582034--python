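"""Minimal NumPy convolutional-network engine.

Implements exactly the primitives the restoration network needs — 3x3
convolutions (stride 1 and 2), 3x3 stride-2 transposed convolutions,
ReLU, skip concatenation, mean-squared-error loss and the Adam optimizer
— with explicit forward/backward passes over float32 tensors.

Activations are channels-last ``(N, H, W, C)``: im2col gathers
``(k, k, C)`` patches from nearly contiguous memory and the GEMM output
is already in activation layout.  Every layer owns persistent scratch
buffers keyed by input shape, so repeated training steps run without
large allocations (first-touch page faults dominate the cost of big
fresh arrays on many systems).
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32


def _out_size(h: int, w: int, k: int, stride: int, pad: int) -> tuple[int, int]:
    return (h + 2 * pad - k) // stride + 1, (w + 2 * pad - k) // stride + 1


class _BufferPool:
    """Named, shape-keyed persistent scratch arrays.

    Buffers are working memory only: they are dropped on pickling and
    can be released explicitly.
    """

    def __init__(self):
        self._bufs: dict = {}

    def clear(self) -> None:
        self._bufs.clear()

    def __getstate__(self):
        return {"_bufs": {}}

    def get(self, name: str, shape: tuple, dtype=DTYPE, zero: bool = False) -> np.ndarray:
        key = (name, shape, np.dtype(dtype))
        buf = self._bufs.get(key)
        if buf is None:
            buf = np.zeros(shape, dtype=dtype)
            self._bufs[key] = buf
        elif zero:
            buf.fill(0)
        return buf


def _im2col_view(xp: np.ndarray, k: int, stride: int, ho: int, wo: int) -> np.ndarray:
    n, _, _, c = xp.shape
    s = xp.strides
    return np.lib.stride_tricks.as_strided(
        xp,
        shape=(n, ho, wo, k, k, c),
        strides=(s[0], s[1] * stride, s[2] * stride, s[1], s[2], s[3]),
    )


class Conv2d:
    """3x3 convolution with 'same'-style padding; optional stride 2."""

    def __init__(
        self,
        c_in: int,
        c_out: int,
        rng: np.random.Generator,
        k: int = 3,
        stride: int = 1,
        relu: bool = True,
    ):
        self.k, self.stride, self.pad = k, stride, k // 2
        self.c_in, self.c_out = c_in, c_out
        self.relu = relu
        fan_in = c_in * k * k
        # weight rows follow the im2col patch layout (k, k, C_in)
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in), (k * k * c_in, c_out)).astype(
            DTYPE
        )
        self.b = np.zeros(c_out, dtype=DTYPE)
        self._pool = _BufferPool()
        self._cache: tuple | None = None

    def __getstate__(self):
        state = self.__dict__.copy()
        state["_cache"] = None
        state.pop("_mask", None)
        state.pop("dW", None)
        state.pop("db", None)
        return state

    # -- core ops reused by the transposed convolution ------------------
    def _forward_linear(self, x: np.ndarray) -> np.ndarray:
        n, h, w, c = x.shape
        k, stride, pad = self.k, self.stride, self.pad
        ho, wo = _out_size(h, w, k, stride, pad)
        xp = self._pool.get("xp", (n, h + 2 * pad, w + 2 * pad, c))
        xp[:, pad : pad + h, pad : pad + w] = x
        cols = self._pool.get("cols", (n, ho, wo, k, k, c))
        np.copyto(cols, _im2col_view(xp, k, stride, ho, wo))
        cols2 = cols.reshape(n * ho * wo, k * k * c)
        y = self._pool.get("y", (n, ho, wo, self.c_out))
        y2 = y.reshape(n * ho * wo, self.c_out)
        np.matmul(cols2, self.W, out=y2)
        y2 += self.b
        self._cache = ((n, h, w, c), cols2)
        return y

    def _backward_linear(self, dy: np.ndarray) -> np.ndarray:
        x_shape, cols2 = self._cache
        n, h, w, c = x_shape
        k, stride, pad = self.k, self.stride, self.pad
        ho, wo = _out_size(h, w, k, stride, pad)
        dyf = dy.reshape(-1, self.c_out)
        self.dW = cols2.T @ dyf
        self.db = dyf.sum(axis=0)
        dcols = self._pool.get("dcols", (n * ho * wo, k * k * c))
        np.matmul(dyf, self.W.T, out=dcols)
        # fold patch rows back onto the (padded) input grid
        dxp = self._pool.get("dxp", (n, h + 2 * pad, w + 2 * pad, c), zero=True)
        dcols6 = dcols.reshape(n, ho, wo, k, k, c)
        for i in range(k):
            for j in range(k):
                dxp[:, i : i + stride * ho : stride, j : j + stride * wo : stride] += (
                    dcols6[:, :, :, i, j]
                )
        self._cache = None
        if pad == 0:
            return dxp
        return dxp[:, pad : pad + h, pad : pad + w]

    def forward(self, x: np.ndarray) -> np.ndarray:
        y = self._forward_linear(x)
        if self.relu:
            mask = self._pool.get("mask", y.shape, dtype=bool)
            np.greater(y, 0, out=mask)
            y *= mask
            self._mask = mask
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        if self.relu:
            dy = np.multiply(dy, self._mask, out=self._pool.get("dy", dy.shape))
        return self._backward_linear(dy)

    @property
    def n_params(self) -> int:
        return self.W.size + self.b.size


class ConvTranspose2d:
    """3x3 stride-2 transposed convolution: doubles the spatial size.

    Implemented as zero-insertion upsampling followed by a stride-1
    convolution; the kernel is learned, so no explicit flip is needed.
    """

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator, relu: bool = True):
        self.conv = Conv2d(c_in, c_out, rng, k=3, stride=1, relu=False)
        self.relu = relu
        self._pool = _BufferPool()

    def __getstate__(self):
        state = self.__dict__.copy()
        state.pop("_mask", None)
        return state

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, h, w, c = x.shape
        # odd positions stay zero across calls; only even ones are written
        z = self._pool.get("z", (n, 2 * h, 2 * w, c))
        z[:, ::2, ::2] = x
        y = self.conv._forward_linear(z)
        if self.relu:
            mask = self._pool.get("mask", y.shape, dtype=bool)
            np.greater(y, 0, out=mask)
            y *= mask
            self._mask = mask
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        if self.relu:
            dy = np.multiply(dy, self._mask, out=self._pool.get("dy", dy.shape))
        dz = self.conv._backward_linear(dy)
        return dz[:, ::2, ::2]

    @property
    def W(self):
        return self.conv.W

    @property
    def b(self):
        return self.conv.b

    @property
    def dW(self):
        return self.conv.dW

    @property
    def db(self):
        return self.conv.db

    @property
    def n_params(self) -> int:
        return self.conv.n_params


class Adam:
    """Adam optimizer over a flat list of layers exposing W/b and dW/db."""

    def __init__(self, layers, lr: float = 1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.layers = layers
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.state = {}

    def step(self) -> None:
        self.t += 1
        for li, layer in enumerate(self.layers):
            for name, grad_name in (("W", "dW"), ("b", "db")):
                p = getattr(layer, name)
                g = getattr(layer, grad_name)
                key = (li, name)
                if key not in self.state:
                    self.state[key] = (np.zeros_like(p), np.zeros_like(p))
                m, v = self.state[key]
                m *= self.b1
                m += (1 - self.b1) * g
                v *= self.b2
                v += (1 - self.b2) * g * g
                mhat = m / (1 - self.b1**self.t)
                vhat = v / (1 - self.b2**self.t)
                p -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(p.dtype)


def mse_loss(pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean squared error and its gradient with respect to ``pred``."""
    diff = (pred - target).astype(DTYPE)
    loss = float(np.mean(diff * diff))
    return loss, (2.0 / diff.size) * diff
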