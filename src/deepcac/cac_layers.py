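"""Attention-augmented convolution branches and their parallel concatenation.

An attention-augmented convolution (AAConv) produces ``d_out`` channels as
the channel-wise concatenation of a stride-1 same convolution (``d_conv``
filters) and multi-head self-attention (``d_v`` channels), with
``d_conv + d_v = d_out`` enforced at construction and at forward time.

A CAC layer applies ``i`` such branches in parallel to the SAME input,
activates each branch output and concatenates along channels to ``D``
total channels, with ``D`` divided equally among branches.

The functions here are the 2-D (single feature map) reference API; the
trainable batched network is assembled in :mod:`deepcac.model` from
:mod:`deepcac.nn` layers configured by the same dataclasses.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .attention_core import MHAParams, multi_head_attention

__all__ = [
    "AAConvConfig",
    "CACLayerConfig",
    "PoolConfig",
    "ConvParams",
    "default_attention_width",
    "conv1d_same",
    "attention_augmented_conv",
    "cac_layer_forward",
    "max_pool",
]

#: default kernel sizes for the parallel branches of one layer (multi-scale)
DEFAULT_KERNEL_SIZES = (7, 11, 19)


class ChannelAccountingError(ValueError):
    """d_conv + d_v != d_out, or branch widths do not sum to D."""


@dataclasses.dataclass(frozen=True)
class AAConvConfig:
    """Channel accounting for one attention-augmented convolution branch."""

    d_out: int
    d_v: int
    kernel_size: int
    n_heads: int
    input_channels: int

    def __post_init__(self) -> None:
        if not 0 < self.d_v < self.d_out:
            raise ChannelAccountingError(
                f"need 0 < d_v < d_out, got d_v={self.d_v}, d_out={self.d_out}"
            )
        if self.d_v % self.n_heads != 0:
            raise ChannelAccountingError(
                f"d_v={self.d_v} not divisible by n_heads={self.n_heads}"
            )
        if self.d_conv < 1:
            raise ChannelAccountingError(
                f"d_conv = d_out - d_v = {self.d_conv} must be >= 1 "
                f"(d_out={self.d_out}, d_v={self.d_v})"
            )
        if self.kernel_size < 1 or self.kernel_size % 2 == 0:
            raise ValueError(f"kernel_size must be odd positive, got {self.kernel_size}")
        if self.input_channels < 1:
            raise ValueError("input_channels must be >= 1")

    @property
    def d_conv(self) -> int:
        return self.d_out - self.d_v

    @property
    def d_head(self) -> int:
        """Per-head key/value width (d_k = d_h)."""
        return self.d_v // self.n_heads


def default_attention_width(d_out: int, n_heads: int) -> int:
    """Default attention channels: d_out/4 rounded down to a multiple of n_heads."""
    d_v = (d_out // 4) // n_heads * n_heads
    return max(d_v, n_heads)


@dataclasses.dataclass(frozen=True)
class CACLayerConfig:
    """One concatenated layer of ``i`` parallel AAConv branches."""

    D: int
    branches: tuple[AAConvConfig, ...]
    activation: str = "relu"

    def __post_init__(self) -> None:
        object.__setattr__(self, "branches", tuple(self.branches))
        i = self.i
        if i < 1:
            raise ValueError("need at least one branch")
        if self.D % i != 0:
            raise ChannelAccountingError(f"D={self.D} not divisible by i={i}")
        per = self.D // i
        for j, br in enumerate(self.branches):
            if br.d_out != per:
                raise ChannelAccountingError(
                    f"branch {j}: d_out={br.d_out} != D/i = {per} (divided equally)"
                )
        total = sum(br.d_out for br in self.branches)
        if total != self.D:
            raise ChannelAccountingError(f"branch widths sum to {total}, expected D={self.D}")

    @property
    def i(self) -> int:
        return len(self.branches)

    @property
    def input_channels(self) -> int:
        return self.branches[0].input_channels

    @classmethod
    def default(
        cls,
        D: int,
        i: int,
        input_channels: int,
        n_heads: int = 8,
        kernel_sizes: tuple[int, ...] = DEFAULT_KERNEL_SIZES,
        d_v: int | None = None,
        activation: str = "relu",
    ) -> "CACLayerConfig":
        if D % i != 0:
            raise ChannelAccountingError(f"D={D} not divisible by i={i}")
        d_out = D // i
        d_v = default_attention_width(d_out, n_heads) if d_v is None else d_v
        branches = tuple(
            AAConvConfig(
                d_out=d_out,
                d_v=d_v,
                kernel_size=kernel_sizes[j % len(kernel_sizes)],
                n_heads=n_heads,
                input_channels=input_channels,
            )
            for j in range(i)
        )
        return cls(D=D, branches=branches, activation=activation)


@dataclasses.dataclass(frozen=True)
class PoolConfig:
    size: int = 4
    stride: int = 4

    def __post_init__(self) -> None:
        if self.size < 1 or self.stride < 1:
            raise ValueError("size and stride must be >= 1")

    def output_length(self, length: int) -> int:
        if length < self.size:
            raise ValueError(f"length {length} < pool size {self.size}")
        return (length - self.size) // self.stride + 1


@dataclasses.dataclass(frozen=True)
class ConvParams:
    """Weights of one same-convolution: kernels ``(k, D_in, d_conv)`` + bias."""

    kernels: np.ndarray
    bias: np.ndarray

    def __post_init__(self) -> None:
        k = np.asarray(self.kernels, dtype=np.float64)
        b = np.asarray(self.bias, dtype=np.float64)
        object.__setattr__(self, "kernels", k)
        object.__setattr__(self, "bias", b)
        if k.ndim != 3:
            raise ValueError(f"kernels must be (k, D_in, d_conv), got shape {k.shape}")
        if b.shape != (k.shape[2],):
            raise ValueError(f"bias shape {b.shape} != ({k.shape[2]},)")


def conv1d_same(x: np.ndarray, kernels: np.ndarray, bias: np.ndarray) -> np.ndarray:
    """Zero-padded stride-1 'same' convolution of an ``L x D_in`` feature map."""
    x = np.asarray(x, dtype=np.float64)
    kernels = np.asarray(kernels, dtype=np.float64)
    bias = np.asarray(bias, dtype=np.float64)
    if x.ndim != 2:
        raise ValueError(f"expected L x D_in input, got shape {x.shape}")
    k, d_in, d_out = kernels.shape
    if k % 2 == 0:
        raise ValueError(f"kernel size must be odd, got {k}")
    if x.shape[1] != d_in:
        raise ValueError(f"input has {x.shape[1]} channels, kernels expect {d_in}")
    length = x.shape[0]
    pad = k // 2
    xpad = np.pad(x, ((pad, pad), (0, 0)))
    win = np.lib.stride_tricks.sliding_window_view(xpad, k, axis=0)  # (L, d_in, k)
    cols = win.transpose(0, 2, 1).reshape(length, k * d_in)
    return cols @ kernels.reshape(k * d_in, d_out) + bias


def attention_augmented_conv(
    x: np.ndarray,
    cfg: AAConvConfig,
    conv_params: ConvParams,
    mha_params: MHAParams,
) -> np.ndarray:
    """Concatenate the convolution and attention channels of one branch."""
    x = np.asarray(x, dtype=np.float64)
    if conv_params.kernels.shape[2] != cfg.d_conv:
        raise ChannelAccountingError(
            f"conv filter count {conv_params.kernels.shape[2]} != d_conv={cfg.d_conv} "
            f"(d_out={cfg.d_out}, d_v={cfg.d_v})"
        )
    if mha_params.d_v != cfg.d_v:
        raise ChannelAccountingError(
            f"attention output width {mha_params.d_v} != d_v={cfg.d_v} "
            f"(d_out={cfg.d_out}, d_conv={cfg.d_conv})"
        )
    conv_out = conv1d_same(x, conv_params.kernels, conv_params.bias)
    att_out = multi_head_attention(x, mha_params)
    out = np.concatenate([conv_out, att_out], axis=1)
    assert out.shape == (x.shape[0], cfg.d_out)
    return out


def _activate(name: str, x: np.ndarray) -> np.ndarray:
    if name == "relu":
        return np.maximum(x, 0.0)
    if name == "sigmoid":
        return 1.0 / (1.0 + np.exp(-x))
    raise ValueError(f"unknown activation {name!r}")


def cac_layer_forward(
    x: np.ndarray,
    cfg: CACLayerConfig,
    params: list[tuple[ConvParams, MHAParams]],
) -> np.ndarray:
    """Activated branch outputs of the SAME input, concatenated to ``L x D``."""
    if len(params) != cfg.i:
        raise ValueError(f"expected {cfg.i} parameter pairs, got {len(params)}")
    outs = [
        _activate(cfg.activation, attention_augmented_conv(x, br, cp, mp))
        for br, (cp, mp) in zip(cfg.branches, params)
    ]
    out = np.concatenate(outs, axis=1)
    if out.shape[1] != cfg.D:
        raise ChannelAccountingError(f"layer produced {out.shape[1]} channels, expected {cfg.D}")
    return out


def max_pool(x: np.ndarray, cfg: PoolConfig = PoolConfig()) -> np.ndarray:
    """Channel-wise window maxima of an ``L x D`` map."""
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 2:
        raise ValueError(f"expected L x D input, got shape {x.shape}")
    l_out = cfg.output_length(x.shape[0])
    win = np.lib.stride_tricks.sliding_window_view(x, cfg.size, axis=0)
    return win[:: cfg.stride][:l_out].max(axis=-1)
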