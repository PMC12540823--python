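"""Hierarchical MBConv encoder (EfficientNet-style inverted bottlenecks).

Each MBConv block is: pointwise 1x1 expansion -> batch norm -> SiLU ->
depthwise kxk convolution -> batch norm -> SiLU -> optional squeeze-
excitation -> pointwise 1x1 projection -> batch norm, with a residual
connection when the block keeps both stride and channel count.  A stride-2
stem convolution plus four stages and a bridge produce feature maps at
strides 2/4/8/16/32 with the stage widths of the assembled architecture
(default 32/48/80/112 and a 192-channel bridge).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import (
    BatchNorm2d,
    Conv2d,
    DepthwiseConv2d,
    Module,
    ModuleList,
    Sequential,
    SiLU,
    Tensor,
)


@dataclass
class MBConvConfig:
    in_channels: int
    out_channels: int
    expansion: int = 6
    kernel: int = 3
    stride: int = 1
    use_se: bool = False

    def __post_init__(self):
        if self.expansion < 1:
            raise ValueError("expansion must be >= 1")
        if self.kernel % 2 == 0:
            raise ValueError("depthwise kernel must be odd")
        if self.stride not in (1, 2):
            raise ValueError("stride must be 1 or 2")


class SqueezeExcite(Module):
    def __init__(self, channels: int, se_dim: int, rng):
        super().__init__()
        self.reduce = Conv2d(channels, se_dim, 1, rng)
        self.expand = Conv2d(se_dim, channels, 1, rng)

    def forward(self, x: Tensor) -> Tensor:
        s = x.mean(axis=(2, 3), keepdims=True)
        s = self.expand(self.reduce(s).silu()).sigmoid()
        return x * s


class MBConv(Module):
    """Mobile inverted bottleneck convolution block."""

    def __init__(self, cfg: MBConvConfig, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        mid = cfg.in_channels * cfg.expansion
        self.expand = None
        if cfg.expansion > 1:
            self.expand = Sequential([
                Conv2d(cfg.in_channels, mid, 1, rng, bias=False),
                BatchNorm2d(mid), SiLU(),
            ])
        self.depthwise = DepthwiseConv2d(mid, cfg.kernel, rng, stride=cfg.stride, bias=False)
        self.dw_norm = BatchNorm2d(mid)
        self.se = SqueezeExcite(mid, max(1, cfg.in_channels // 4), rng) if cfg.use_se else None
        self.project = Conv2d(mid, cfg.out_channels, 1, rng, bias=False)
        self.proj_norm = BatchNorm2d(cfg.out_channels)
        self.residual = cfg.stride == 1 and cfg.in_channels == cfg.out_channels
        if self.residual:
            # zero-init residual: gamma of the last norm starts at zero so the
            # block is the identity at initialization
            self.proj_norm.gamma.data[...] = 0.0

    def forward(self, x: Tensor) -> Tensor:
        h = self.expand(x) if self.expand is not None else x
        h = self.dw_norm(self.depthwise(h)).silu()
        if self.se is not None:
            h = self.se(h)
        h = self.proj_norm(self.project(h))
        return h + x if self.residual else h


def _stage(in_ch: int, out_ch: int, repeats: int, stride: int, expansion: int,
           use_se: bool, rng) -> Sequential:
    blocks = []
    for i in range(repeats):
        blocks.append(MBConv(MBConvConfig(
            in_channels=in_ch if i == 0 else out_ch,
            out_channels=out_ch,
            expansion=expansion,
            stride=stride if i == 0 else 1,
            use_se=use_se,
        ), rng))
    return Sequential(blocks)


class Encoder(Module):
    """Stem + four stages + bridge; returns all stage maps for skip taps."""

    def __init__(self, input_channels: int, stage_channels: tuple[int, int, int, int],
                 bridge_channels: int, stage_repeats: tuple[int, int, int, int],
                 bridge_repeats: int, expansion: int, use_se: bool,
                 rng: np.random.Generator):
        super().__init__()
        c1, c2, c3, c4 = stage_channels
        self.stem = Sequential([
            Conv2d(input_channels, c1, 3, rng, stride=2, bias=False),
            BatchNorm2d(c1), SiLU(),
        ])
        self.stages = ModuleList([
            _stage(c1, c1, stage_repeats[0], 1, expansion, use_se, rng),
            _stage(c1, c2, stage_repeats[1], 2, expansion, use_se, rng),
            _stage(c2, c3, stage_repeats[2], 2, expansion, use_se, rng),
            _stage(c3, c4, stage_repeats[3], 2, expansion, use_se, rng),
        ])
        self.bridge = _stage(c4, bridge_channels, bridge_repeats, 2, expansion, use_se, rng)

    def forward(self, x: Tensor) -> tuple[list[Tensor], Tensor]:
        h, w = x.shape[2], x.shape[3]
        if h % 32 or w % 32:
            raise ValueError(f"input spatial size {(h, w)} must be divisible by 32")
        feats = []
        h_ = self.stem(x)
        for stage in self.stages:
            h_ = stage(h_)
            feats.append(h_)
        return feats, self.bridge(feats[-1])


def encoder_forward(enc: Encoder, x: Tensor) -> tuple[list[Tensor], Tensor]:
    """Stage-1..4 feature maps plus the bottleneck map."""
    return enc(x)
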