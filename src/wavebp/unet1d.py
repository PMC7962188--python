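"""Modified 1-D U-Net mapping a normalized PPG window to a normalized ABP window.

The network is the classic encoder/bottleneck/decoder "U" adapted to one
dimension and to same-length output: every convolution uses "same" padding, so
a 256-sample input window yields a 256-sample output window with no cropping.

Structure for ``depth`` contraction levels and ``base_channels`` = C:

* contraction block *i*: two length-3 convolutions (each followed by leaky
  ReLU) at ``C * 2**i`` channels, then 2x max-pooling; channel count doubles
  per level. Dropout is applied after the deepest block's convolutions.
* bottleneck: two length-3 convolutions at ``C * 2**depth`` channels, then
  dropout.
* expansion block (mirrored): 2x upsampling, one length-2 convolution halving
  the channels, concatenation with the same-resolution contraction features,
  then two length-3 convolutions.
* head: one length-3 convolution at C channels (leaky ReLU) and a final
  length-3 convolution projecting to the single output channel, linear — the
  targets are min-max normalized, so no output squashing is wanted.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .errors import ConfigError
from .nn import Conv1d, Dropout, LeakyReLU, MaxPool1d, Upsample1d
from .nn.layers import DTYPE

__all__ = ["UNetConfig", "UNet1D", "build_unet", "count_parameters",
           "save_checkpoint", "load_checkpoint"]


@dataclass(frozen=True)
class UNetConfig:
    """Architecture hyper-parameters.

    ``input_len`` must be divisible by ``pool_len ** depth`` so that pooling
    and upsampling round-trip exactly and the skip concatenations line up
    without cropping.
    """

    input_len: int = 256
    depth: int = 4
    base_channels: int = 64
    kernel_len: int = 3
    pool_len: int = 2
    leaky_slope: float = 0.3
    dropout_rate: float = 0.5
    out_channels: int = 1
    in_channels: int = 1
    upsample_mode: str = "nearest"  # or "zeros" (transposed-conv equivalent)

    def validate(self) -> None:
        if self.input_len <= 0 or self.base_channels <= 0:
            raise ConfigError("input_len and base_channels must be positive")
        if self.depth < 0:
            raise ConfigError("depth must be >= 0")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ConfigError("dropout_rate must be in [0, 1)")
        if self.input_len % (self.pool_len ** self.depth):
            raise ConfigError(
                f"input_len={self.input_len} not divisible by "
                f"pool_len**depth={self.pool_len ** self.depth}")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "UNetConfig":
        return cls(**d)


@dataclass
class _EncBlock:
    convs: list
    acts: list
    drop: Dropout | None
    pool: MaxPool1d


@dataclass
class _DecBlock:
    up: Upsample1d
    upconv: Conv1d
    upact: LeakyReLU
    convs: list = field(default_factory=list)
    acts: list = field(default_factory=list)


class UNet1D:
    """The built network; construct through :func:`build_unet`."""

    def __init__(self, config: UNetConfig, seed: int = 0):
        config.validate()
        self.config = config
        self._init_rng = np.random.default_rng(seed)
        self.dropout_rng = np.random.default_rng(seed + 1)
        c = config
        slope = c.leaky_slope
        k = c.kernel_len

        def conv(ci, co, kk=k):
            return Conv1d(ci, co, kk, self._init_rng, leaky_slope=slope)

        self.enc: list[_EncBlock] = []
        ch = c.in_channels
        for i in range(c.depth):
            co = c.base_channels * (2 ** i)
            drop = (Dropout(c.dropout_rate, self.dropout_rng)
                    if i == c.depth - 1 else None)
            self.enc.append(_EncBlock(
                convs=[conv(ch, co), conv(co, co)],
                acts=[LeakyReLU(slope), LeakyReLU(slope)],
                drop=drop, pool=MaxPool1d(c.pool_len)))
            ch = co

        self.bottleneck: _EncBlock | None = None
        if c.depth > 0:
            co = c.base_channels * (2 ** c.depth)
            self.bottleneck = _EncBlock(
                convs=[conv(ch, co), conv(co, co)],
                acts=[LeakyReLU(slope), LeakyReLU(slope)],
                drop=Dropout(c.dropout_rate, self.dropout_rng), pool=None)
            ch = co

        self.dec: list[_DecBlock] = []
        for i in reversed(range(c.depth)):
            co = c.base_channels * (2 ** i)
            blk = _DecBlock(
                up=Upsample1d(c.pool_len, mode=c.upsample_mode),
                upconv=conv(ch, co, kk=c.pool_len),
                upact=LeakyReLU(slope))
            blk.convs = [conv(2 * co, co), conv(co, co)]
            blk.acts = [LeakyReLU(slope), LeakyReLU(slope)]
            self.dec.append(blk)
            ch = co

        self.head_convs = [conv(ch, c.base_channels),
                           conv(c.base_channels, c.out_channels)]
        self.head_act = LeakyReLU(slope)

    # -- plumbing -----------------------------------------------------------

    def _all_convs(self) -> list[Conv1d]:
        convs: list[Conv1d] = []
        for blk in self.enc:
            convs.extend(blk.convs)
        if self.bottleneck is not None:
            convs.extend(self.bottleneck.convs)
        for blk in self.dec:
            convs.append(blk.upconv)
            convs.extend(blk.convs)
        convs.extend(self.head_convs)
        return convs

    def parameters(self):
        params = []
        for cv in self._all_convs():
            params.extend(cv.parameters())
        return params

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for p, _ in self.parameters()]

    def set_weights(self, weights) -> None:
        params = self.parameters()
        if len(weights) != len(params):
            raise ConfigError("weight list does not match architecture")
        for (p, _), w in zip(params, weights):
            if p.shape != w.shape:
                raise ConfigError(
                    f"weight shape {w.shape} != expected {p.shape}")
            p[...] = w

    # -- forward / backward -------------------------------------------------

    def _check_input(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=DTYPE)
        if x.ndim == 2:
            x = x[:, None, :]
        if x.ndim != 3 or x.shape[1] != self.config.in_channels:
            raise ConfigError(
                f"expected batch of shape (n, {self.config.input_len}) or "
                f"(n, {self.config.in_channels}, {self.config.input_len})")
        if x.shape[2] != self.config.input_len:
            raise ConfigError(
                f"input length {x.shape[2]} != expected {self.config.input_len}")
        return x

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Map ``(n, 256)`` or ``(n, 1, 256)`` PPG windows to ABP windows.

        Dropout is active only when ``train`` is true; inference is
        deterministic.
        """
        x = self._check_input(x)
        h = x
        skips = []
        for blk in self.enc:
            for cv, act in zip(blk.convs, blk.acts):
                h = act.forward(cv.forward(h, train), train)
            if blk.drop is not None:
                h = blk.drop.forward(h, train)
            skips.append(h)
            h = blk.pool.forward(h, train)
        if self.bottleneck is not None:
            bn = self.bottleneck
            for cv, act in zip(bn.convs, bn.acts):
                h = act.forward(cv.forward(h, train), train)
            h = bn.drop.forward(h, train)
        for blk, skip in zip(self.dec, reversed(skips)):
            h = blk.upact.forward(blk.upconv.forward(
                blk.up.forward(h, train), train), train)
            h = np.concatenate([skip, h], axis=1)
            for cv, act in zip(blk.convs, blk.acts):
                h = act.forward(cv.forward(h, train), train)
        h = self.head_act.forward(self.head_convs[0].forward(h, train), train)
        h = self.head_convs[1].forward(h, train)
        return h

    def __call__(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        return self.forward(x, train=train)

    def backward(self, dy: np.ndarray) -> None:
        """Backpropagate loss gradient ``dy`` (same shape as the output)."""
        dh = self.head_convs[1].backward(dy)
        dh = self.head_convs[0].backward(self.head_act.backward(dh))
        dskips = []
        for blk in reversed(self.dec):
            for cv, act in zip(reversed(blk.convs), reversed(blk.acts)):
                dh = cv.backward(act.backward(dh))
            n_skip = dh.shape[1] // 2
            dskips.append(dh[:, :n_skip, :].copy())
            dh = dh[:, n_skip:, :].copy()
            dh = blk.up.backward(blk.upconv.backward(blk.upact.backward(dh)))
        if self.bottleneck is not None:
            bn = self.bottleneck
            dh = bn.drop.backward(dh)
            for cv, act in zip(reversed(bn.convs), reversed(bn.acts)):
                dh = cv.backward(act.backward(dh))
        for blk, dskip in zip(reversed(self.enc), reversed(dskips)):
            dh = blk.pool.backward(dh)
            dh = dh + dskip
            if blk.drop is not None:
                dh = blk.drop.backward(dh)
            for cv, act in zip(reversed(blk.convs), reversed(blk.acts)):
                dh = cv.backward(act.backward(dh))

    def predict(self, x: np.ndarray, batch_size: int = 64) -> np.ndarray:
        """Batched inference returning ``(n, input_len)`` windows."""
        x = self._check_input(x)
        outs = [self.forward(x[i:i + batch_size])
                for i in range(0, x.shape[0], batch_size)]
        return np.concatenate(outs, axis=0)[:, 0, :]


def build_unet(config: UNetConfig | None = None, seed: int = 0) -> UNet1D:
    """Build a randomly initialized network from ``config`` (validated)."""
    return UNet1D(config or UNetConfig(), seed=seed)


def count_parameters(model: UNet1D) -> int:
    """Total number of trainable scalar parameters."""
    return sum(p.size for p, _ in model.parameters())


def save_checkpoint(path, model: UNet1D, norm_params=None, extra: dict | None = None):
    """Write a self-describing checkpoint: weights + config + normalization."""
    meta = {"config": model.config.to_dict(),
            "norm_params": None if norm_params is None else norm_params.to_dict(),
            "extra": extra or {}}
    arrays = {f"w{i}": w for i, w in enumerate(model.get_weights())}
    np.savez_compressed(Path(path), meta=np.array(json.dumps(meta)), **arrays)


def load_checkpoint(path):
    """Load a checkpoint; returns ``(model, norm_params_dict_or_None, extra)``."""
    with np.load(Path(path), allow_pickle=False) as data:
        meta = json.loads(str(data["meta"]))
        n = sum(1 for k in data.files if k.startswith("w"))
        weights = [data[f"w{i}"] for i in range(n)]
    model = build_unet(UNetConfig.from_dict(meta["config"]))
    model.set_weights(weights)
    return model, meta.get("norm_params"), meta.get("extra", {})
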