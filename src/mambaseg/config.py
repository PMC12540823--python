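"""Configuration dataclasses and presets."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .losses import LossConfig


@dataclass
class NetworkConfig:
    """Architecture configuration.

    The default preset follows the published stage table: input 224x224x3,
    stage widths (32, 48, 80, 112) with a 192-channel bridge, two VSS
    blocks per stage, attention bridges in the bottleneck and decoder, and
    a softmax head with 2 classes.  Since the stage widths are fixed by the
    table, the stage/bridge repeat counts are the depth dial that places
    the total trainable-parameter count at the published ~8.7 million.
    """

    input_size: int = 224
    input_channels: int = 3
    stage_channels: tuple[int, int, int, int] = (32, 48, 80, 112)
    bridge_channels: int = 192
    n_classes: int = 2
    stage_repeats: tuple[int, int, int, int] = (3, 4, 6, 9)
    bridge_repeats: int = 8
    expansion: int = 6
    use_se: bool = False
    vss_per_stage: int = 2
    state_size: int = 16
    expand_ratio: int = 2
    selective: bool = False
    sab_mode: str = "pooled"
    fusion: str = "add"
    reduction: int = 8
    foreground_prior: float | None = 0.05   # head-bias init; None disables
    seed: int = 0

    def __post_init__(self):
        self.stage_channels = tuple(self.stage_channels)
        self.stage_repeats = tuple(self.stage_repeats)
        self.validate()

    def validate(self) -> None:
        if self.input_size % 32:
            raise ValueError(f"input_size {self.input_size} must be divisible by 32")
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if len(self.stage_channels) != 4 or len(self.stage_repeats) != 4:
            raise ValueError("stage_channels and stage_repeats must have 4 entries")
        for c in (*self.stage_channels, self.bridge_channels):
            if c % self.reduction:
                raise ValueError(
                    f"channel width {c} not divisible by attention reduction {self.reduction}"
                )


def tiny_network() -> NetworkConfig:
    """Quarter-width, single-repeat preset for CPU runs (input 64x64)."""
    return NetworkConfig(
        input_size=64,
        stage_channels=(8, 12, 20, 28),
        bridge_channels=48,
        stage_repeats=(1, 1, 1, 1),
        bridge_repeats=1,
        expansion=2,
        state_size=8,
        reduction=4,
    )


@dataclass
class TrainConfig:
    """Optimization recipe; defaults follow the published training setup."""

    lr0: float = 1e-4
    lr_min: float = 1e-6
    weight_decay: float = 1e-5
    epochs: int = 100
    batch_size: int = 8
    patience: int = 10
    augment: bool = True
    lesion_only: bool = True
    max_steps: int | None = None
    warmup_epochs: int = 0
    grad_clip: float = 1.0      # global grad-norm ceiling; 0 disables
    seed: int = 0
    loss: LossConfig = field(default_factory=LossConfig)

    def __post_init__(self):
        if self.lr_min >= self.lr0:
            raise ValueError("lr_min must be < lr0")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")


def tiny_train() -> TrainConfig:
    """Quick-run recipe paired with the tiny network: the reduced-width model
    tolerates (and, over a few hundred steps, needs) a much larger step size,
    with a short warmup and gradient clipping to keep it stable."""
    return TrainConfig(lr0=1e-2, lr_min=1e-4, epochs=60, batch_size=8,
                       warmup_epochs=2, grad_clip=1.0)


_SECTION_TYPES = {"network": NetworkConfig, "train": TrainConfig, "loss": LossConfig}


def _build(cls, payload: dict):
    names = {f.name for f in fields(cls)}
    unknown = set(payload) - names
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    if cls is TrainConfig and isinstance(payload.get("loss"), dict):
        payload = dict(payload, loss=LossConfig(**payload["loss"]))
    return cls(**payload)


def load_config(path) -> dict:
    """Read a YAML config with optional network/train/loss sections.

    Unknown keys are rejected so typos cannot silently change a run.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    known_sections = {"network", "train", "loss", "preset", "data"}
    unknown = set(raw) - known_sections
    if unknown:
        raise ValueError(f"unknown config sections: {sorted(unknown)}")
    out: dict = {"preset": raw.get("preset", "default"), "data": raw.get("data", {})}
    if out["preset"] not in ("default", "tiny"):
        raise ValueError(f"unknown preset {out['preset']!r}")
    net = tiny_network() if out["preset"] == "tiny" else NetworkConfig()
    tr = tiny_train() if out["preset"] == "tiny" else TrainConfig()
    for key, value in (raw.get("network") or {}).items():
        if key not in {f.name for f in fields(NetworkConfig)}:
            raise ValueError(f"unknown network key: {key}")
        setattr(net, key, tuple(value) if isinstance(value, list) else value)
    net.validate()
    for key, value in (raw.get("train") or {}).items():
        if key not in {f.name for f in fields(TrainConfig)}:
            raise ValueError(f"unknown train key: {key}")
        setattr(tr, key, value)
    if raw.get("loss"):
        tr.loss = _build(LossConfig, raw["loss"])
    out["network"], out["train"] = net, tr
    return out


def config_to_dict(cfg) -> dict:
    return asdict(cfg)
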