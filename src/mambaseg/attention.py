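"""Spatial and channel attention bridges (SAB / CAB).

SAB pools the feature map to per-pixel mean and max channel descriptors,
passes the 2-channel descriptor through a 7x7 convolution and a sigmoid,
and gates the map spatially.  A `literal` mode instead applies the 7x7
convolution to the feature map itself.  CAB squeezes the map by global
average pooling, re-weights channels through a two-layer bottleneck
(reduction r) with ReLU then sigmoid, and gates per channel.  Both gates
lie strictly in (0, 1), so the operators are elementwise contractive.
"""

from __future__ import annotations

import numpy as np

from .nn import Conv2d, Linear, Module, Tensor, concat


class SpatialAttention(Module):
    """7x7 convolutional spatial gate (Conv over pooled descriptors)."""

    def __init__(self, channels: int, rng: np.random.Generator, mode: str = "pooled"):
        super().__init__()
        if mode not in ("pooled", "literal"):
            raise ValueError(f"unknown sab_mode {mode!r}")
        self.mode = mode
        in_ch = 2 if mode == "pooled" else channels
        self.conv = Conv2d(in_ch, 1, 7, rng)

    def attention_map(self, x: Tensor) -> Tensor:
        if self.mode == "pooled":
            desc = concat([x.mean(axis=1, keepdims=True), x.max(axis=1, keepdims=True)], axis=1)
        else:
            desc = x
        return self.conv(desc).sigmoid()

    def forward(self, x: Tensor) -> Tensor:
        return x * self.attention_map(x)


class ChannelAttention(Module):
    """Global-average-pooling channel gate with a bottleneck of reduction r."""

    def __init__(self, channels: int, rng: np.random.Generator, reduction: int = 8):
        super().__init__()
        if channels % reduction:
            raise ValueError(f"channels {channels} not divisible by reduction {reduction}")
        self.w1 = Linear(channels, channels // reduction, rng)
        # small positive bias keeps the narrow ReLU bottleneck alive at init
        self.w1.bias.data[...] = 0.1
        self.w2 = Linear(channels // reduction, channels, rng)

    def attention_vector(self, x: Tensor) -> Tensor:
        gap = x.mean(axis=(2, 3))                  # (B, C)
        return self.w2(self.w1(gap).relu()).sigmoid()

    def forward(self, x: Tensor) -> Tensor:
        b, c = x.shape[0], x.shape[1]
        return x * self.attention_vector(x).reshape(b, c, 1, 1)


class FuseAttention(Module):
    """Combine VSS features with SAB/CAB outputs: elementwise add or concat."""

    def __init__(self, channels: int, rng: np.random.Generator, mode: str = "add"):
        super().__init__()
        if mode not in ("add", "concat"):
            raise ValueError(f"unknown fusion mode {mode!r}")
        self.mode = mode
        self.proj = Conv2d(3 * channels, channels, 1, rng) if mode == "concat" else None

    def forward(self, vss_out: Tensor, sab_out: Tensor, cab_out: Tensor) -> Tensor:
        if not (vss_out.shape == sab_out.shape == cab_out.shape):
            raise ValueError("fuse_attention inputs must share shape")
        if self.mode == "add":
            return vss_out + sab_out + cab_out
        return self.proj(concat([vss_out, sab_out, cab_out], axis=1))


class AttentionBridge(Module):
    """SAB + CAB applied to a feature map and fused with it."""

    def __init__(self, channels: int, rng: np.random.Generator, reduction: int = 8,
                 sab_mode: str = "pooled", fusion: str = "add"):
        super().__init__()
        self.sab = SpatialAttention(channels, rng, mode=sab_mode)
        self.cab = ChannelAttention(channels, rng, reduction=reduction)
        self.fuse = FuseAttention(channels, rng, mode=fusion)

    def forward(self, x: Tensor) -> Tensor:
        return self.fuse(x, self.sab(x), self.cab(x))


def spatial_attention(x: Tensor, module: SpatialAttention) -> Tensor:
    return module(x)


def channel_attention(x: Tensor, module: ChannelAttention) -> Tensor:
    return module(x)


def fuse_attention(vss_out: Tensor, sab_out: Tensor, cab_out: Tensor,
                   module: FuseAttention) -> Tensor:
    return module(vss_out, sab_out, cab_out)
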