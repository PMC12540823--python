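"""Full segmentation network: MBConv encoder stages with VSS refinement,
attention-bridged bottleneck, patch-expanding decoder with skip
connections, and a softmax segmentation head.

Stage layout for the default 224x224x3 input:

    stem+stage1 112x112x32 -> 56x56x48 -> 28x28x80 -> 14x14x112
    bridge 7x7x192 (VSS x2 + SAB/CAB)
    D4 14x14x112 -> D3 28x28x80 -> D2 56x56x48 -> D1 112x112x32
    final patch expand -> 224x224, 1x1 conv -> softmax over classes

Skip connections carry the VSS-refined encoder maps.  Decoder upsampling
is patch expansion (channel-to-space rearrangement after a linear map):
(H, W, C) -> (2H, 2W, C/2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .attention import AttentionBridge
from .config import NetworkConfig
from .encoder import Encoder
from .nn import (
    BatchNorm2d,
    Conv2d,
    Module,
    ModuleList,
    Sequential,
    SiLU,
    Tensor,
    concat,
    no_grad,
    softmax,
)
from .vss import vss_stack


@dataclass
class SegmentationResult:
    """Per-pixel class probabilities and argmax labels."""

    probabilities: np.ndarray   # (B, H, W, n_classes), rows sum to 1
    labels: np.ndarray          # (B, H, W) int

    def __post_init__(self):
        s = self.probabilities.sum(axis=-1)
        if not np.allclose(s, 1.0, atol=1e-5):
            raise ValueError("probabilities must sum to 1 per pixel")


class PatchExpand(Module):
    """Double the spatial size, halve the channels: (H,W,C) -> (2H,2W,C/2)."""

    def __init__(self, dim: int, rng: np.random.Generator):
        super().__init__()
        if dim % 2:
            raise ValueError(f"patch expansion needs an even channel count, got {dim}")
        self.dim = dim
        self.proj = Conv2d(dim, 2 * dim, 1, rng, bias=False)

    def forward(self, x: Tensor) -> Tensor:
        b, c, h, w = x.shape
        if c != self.dim:
            raise ValueError(f"expected {self.dim} channels, got {c}")
        y = self.proj(x)                                   # (B, 2C, H, W)
        cout = c // 2
        y = y.reshape(b, cout, 2, 2, h, w)
        y = y.transpose(0, 1, 4, 2, 5, 3)                  # (B, C/2, H, 2, W, 2)
        return y.reshape(b, cout, 2 * h, 2 * w)


class DecoderStage(Module):
    """Patch-expand, concat skip, convolutional fusion, VSS x2, SAB/CAB."""

    def __init__(self, up_channels: int, skip_channels: int, out_channels: int,
                 cfg: NetworkConfig, rng: np.random.Generator):
        super().__init__()
        self.expand = PatchExpand(up_channels, rng)
        cat_ch = skip_channels + up_channels // 2
        self.fuse = Sequential([
            Conv2d(cat_ch, out_channels, 3, rng, bias=False),
            BatchNorm2d(out_channels), SiLU(),
            Conv2d(out_channels, out_channels, 3, rng, bias=False),
            BatchNorm2d(out_channels), SiLU(),
        ])
        self.vss = vss_stack(out_channels, cfg.vss_per_stage, rng,
                             state_size=cfg.state_size, expand_ratio=cfg.expand_ratio,
                             selective=cfg.selective)
        self.attn = AttentionBridge(out_channels, rng, reduction=cfg.reduction,
                                    sab_mode=cfg.sab_mode, fusion=cfg.fusion)

    def forward(self, up: Tensor, skip: Tensor) -> Tensor:
        up = self.expand(up)
        if up.shape[2:] != skip.shape[2:]:
            raise ValueError(f"decoder spatial mismatch: up {up.shape} vs skip {skip.shape}")
        h = self.fuse(concat([skip, up], axis=1))   # skip first, upsampled second
        for blk in self.vss:
            h = blk(h)
        return self.attn(h)


class SegmentationNetwork(Module):
    def __init__(self, cfg: NetworkConfig):
        super().__init__()
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        c1, c2, c3, c4 = cfg.stage_channels
        cb = cfg.bridge_channels

        self.encoder = Encoder(cfg.input_channels, cfg.stage_channels, cb,
                               cfg.stage_repeats, cfg.bridge_repeats,
                               cfg.expansion, cfg.use_se, rng)
        vss_kw = dict(state_size=cfg.state_size, expand_ratio=cfg.expand_ratio,
                      selective=cfg.selective)
        self.encoder_vss = ModuleList([
            vss_stack(c, cfg.vss_per_stage, rng, **vss_kw)
            for c in (c1, c2, c3, c4)
        ])
        self.bridge_vss = vss_stack(cb, cfg.vss_per_stage, rng, **vss_kw)
        self.bridge_attn = AttentionBridge(cb, rng, reduction=cfg.reduction,
                                           sab_mode=cfg.sab_mode, fusion=cfg.fusion)
        self.decoder = ModuleList([
            DecoderStage(cb, c4, c4, cfg, rng),   # D4: 7 -> 14
            DecoderStage(c4, c3, c3, cfg, rng),   # D3: 14 -> 28
            DecoderStage(c3, c2, c2, cfg, rng),   # D2: 28 -> 56
            DecoderStage(c2, c1, c1, cfg, rng),   # D1: 56 -> 112
        ])
        self.final_expand = PatchExpand(c1, rng)
        self.head = Conv2d(c1 // 2, cfg.n_classes, 1, rng)
        # prior-probability head-bias init: start the foreground probability
        # near the expected lesion fraction instead of 0.5, which removes the
        # large initial background gradient on class-imbalanced data
        if cfg.n_classes == 2 and cfg.foreground_prior is not None:
            pi = cfg.foreground_prior
            self.head.bias.data[1] = float(np.log(pi / (1.0 - pi)))
        self.stage_shapes: list[tuple[str, int, int, int]] = []

    # -- forward ------------------------------------------------------------

    def forward_logits(self, x: Tensor) -> Tensor:
        if x.shape[1] != self.cfg.input_channels:
            raise ValueError(
                f"input has {x.shape[1]} channels, config expects {self.cfg.input_channels}"
            )
        shapes = [("input", x.shape[2], x.shape[3], x.shape[1])]
        feats, bridge = self.encoder(x)
        skips = []
        for i, (f, stack) in enumerate(zip(feats, self.encoder_vss)):
            for blk in stack:
                f = blk(f)
            skips.append(f)
            shapes.append((f"enc{i + 1}", f.shape[2], f.shape[3], f.shape[1]))
        h = bridge
        for blk in self.bridge_vss:
            h = blk(h)
        h = self.bridge_attn(h)
        shapes.append(("bridge", h.shape[2], h.shape[3], h.shape[1]))
        for i, stage in enumerate(self.decoder):
            h = stage(h, skips[3 - i])
            shapes.append((f"D{4 - i}", h.shape[2], h.shape[3], h.shape[1]))
        h = self.final_expand(h)
        logits = self.head(h)
        shapes.append(("output", logits.shape[2], logits.shape[3], logits.shape[1]))
        self.stage_shapes = shapes
        return logits

    forward = forward_logits

    def foreground_probability(self, x: Tensor) -> Tensor:
        """Softmax probability of the lesion class, (B, H, W)."""
        probs = softmax(self.forward_logits(x), axis=1)
        b, _, h, w = probs.shape
        return probs[:, 1, :, :].reshape(b, h, w) if self.cfg.n_classes == 2 else probs

    def predict_batch(self, images: np.ndarray) -> SegmentationResult:
        """Inference on a (B, C, H, W) array; deterministic in eval mode."""
        was_training = self.training
        self.eval()
        try:
            with no_grad():
                probs = softmax(self.forward_logits(Tensor(images)), axis=1).data
        finally:
            if was_training:
                self.train()
        probs = np.moveaxis(probs, 1, -1)
        return SegmentationResult(probabilities=probs, labels=probs.argmax(axis=-1))


def build_network(cfg: NetworkConfig | None = None) -> SegmentationNetwork:
    return SegmentationNetwork(cfg or NetworkConfig())


def count_parameters(net: Module) -> int:
    """Total size of all trainable weight arrays."""
    return sum(p.size for p in net.parameters() if p.requires_grad)


def summary(net: SegmentationNetwork, input_size: int | None = None) -> list[tuple[str, str, int]]:
    """Instantiated stage table: (stage, HxW, C) rows from a real forward pass."""
    cfg = net.cfg
    s = input_size or cfg.input_size
    net.eval()
    with no_grad():
        net.forward_logits(Tensor(np.zeros((1, cfg.input_channels, s, s), dtype=np.float32)))
    return [(name, f"{h}x{w}", c) for name, h, w, c in net.stage_shapes]
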