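"""Layers for 1-D signal-to-signal networks, with explicit backward passes.

Tensors are ``(batch, channels, length)`` float32 arrays. Convolutions use
"same" padding so every layer preserves temporal length; even kernels pad one
extra sample on the right.
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32


class Conv1d:
    """Length-preserving 1-D convolution (cross-correlation) via im2col.

    Weights are stored flat as ``(c_out, k * c_in)`` so the forward pass is a
    single GEMM against the unfolded input. He-style initialization scaled for
    a leaky-ReLU follower.
    """

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator,
                 leaky_slope: float = 0.0):
        self.c_in, self.c_out, self.k = int(c_in), int(c_out), int(k)
        fan_in = self.c_in * self.k
        std = np.sqrt(2.0 / ((1.0 + leaky_slope ** 2) * fan_in))
        self.W = rng.normal(0.0, std, size=(self.c_out, fan_in)).astype(DTYPE)
        self.b = np.zeros(self.c_out, dtype=DTYPE)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._pad_l = (self.k - 1) // 2
        self._pad_r = self.k // 2
        self._cols: np.ndarray | None = None

    @property
    def n_params(self) -> int:
        return self.W.size + self.b.size

    def parameters(self):
        return [(self.W, self.dW), (self.b, self.db)]

    def _unfold(self, x: np.ndarray) -> np.ndarray:
        """im2col with the batch flattened into columns: (c_in*k, n*L)."""
        n, c, length = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (self._pad_l, self._pad_r)))
        cols = np.empty((c * self.k, n, length), dtype=DTYPE)
        for i in range(self.k):
            cols[i * c:(i + 1) * c] = xp[:, :, i:i + length].transpose(1, 0, 2)
        return cols.reshape(c * self.k, n * length)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, _, length = x.shape
        cols = self._unfold(x)
        if train:
            self._cols = cols
        y = self.W @ cols + self.b[:, None]
        return np.ascontiguousarray(
            y.reshape(self.c_out, n, length).transpose(1, 0, 2))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        cols = self._cols
        if cols is None:
            raise RuntimeError("backward() before forward(train=True)")
        n, _, length = dy.shape
        # all three products are single GEMMs over the (batch*length) axis
        dyf = np.ascontiguousarray(dy.transpose(1, 0, 2)).reshape(
            self.c_out, -1)
        self.dW += dyf @ cols.T
        self.db += dyf.sum(axis=1)
        c = self.c_in
        dcols = (self.W.T @ dyf).reshape(c * self.k, n, length)
        dxp = np.zeros((n, c, length + self._pad_l + self._pad_r), dtype=DTYPE)
        for i in range(self.k):
            dxp[:, :, i:i + length] += dcols[i * c:(i + 1) * c].transpose(1, 0, 2)
        self._cols = None
        return dxp[:, :, self._pad_l:self._pad_l + length]


class LeakyReLU:
    def __init__(self, slope: float = 0.3):
        self.slope = float(slope)
        self._neg: np.ndarray | None = None

    def parameters(self):
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        neg = x < 0
        if train:
            self._neg = neg
        return np.where(neg, DTYPE(self.slope) * x, x)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dx = np.where(self._neg, DTYPE(self.slope) * dy, dy)
        self._neg = None
        return dx


class MaxPool1d:
    """Non-overlapping max pooling; input length must divide the pool size."""

    def __init__(self, p: int = 2):
        self.p = int(p)
        self._idx: np.ndarray | None = None
        self._shape: tuple | None = None

    def parameters(self):
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, c, length = x.shape
        if length % self.p:
            raise ValueError(f"length {length} not divisible by pool {self.p}")
        xr = x.reshape(n, c, length // self.p, self.p)
        idx = xr.argmax(axis=3)
        if train:
            self._idx = idx
            self._shape = x.shape
        return np.take_along_axis(xr, idx[..., None], axis=3)[..., 0]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, length = self._shape
        dxr = np.zeros((n, c, length // self.p, self.p), dtype=DTYPE)
        np.put_along_axis(dxr, self._idx[..., None], dy[..., None], axis=3)
        self._idx = None
        self._shape = None
        return dxr.reshape(n, c, length)


class Upsample1d:
    """Temporal upsampling by an integer factor.

    ``mode='nearest'`` repeats samples; ``mode='zeros'`` inserts zeros, which
    together with the following length-2 convolution is equivalent to a
    stride-2 transposed convolution.
    """

    def __init__(self, p: int = 2, mode: str = "nearest"):
        if mode not in ("nearest", "zeros"):
            raise ValueError(f"unknown upsample mode {mode!r}")
        self.p = int(p)
        self.mode = mode

    def parameters(self):
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if self.mode == "nearest":
            return np.repeat(x, self.p, axis=2)
        n, c, length = x.shape
        out = np.zeros((n, c, length * self.p), dtype=DTYPE)
        out[:, :, ::self.p] = x
        return out

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, length = dy.shape
        if self.mode == "nearest":
            return dy.reshape(n, c, length // self.p, self.p).sum(axis=3)
        return dy[:, :, ::self.p].copy()


class Dropout:
    """Inverted dropout; identity outside training."""

    def __init__(self, rate: float, rng: np.random.Generator):
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = float(rate)
        self.rng = rng
        self._mask: np.ndarray | None = None

    def parameters(self):
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if not train or self.rate == 0.0:
            return x
        keep = 1.0 - self.rate
        mask = (self.rng.random(x.shape) < keep).astype(DTYPE) / DTYPE(keep)
        self._mask = mask
        return x * mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return dy
        dx = dy * self._mask
        self._mask = None
        return dx
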