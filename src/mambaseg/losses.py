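"""Active-contour, focal and hybrid segmentation losses.

The active-contour loss is the discrete energy

    L_AC = lambda_length * mean(|grad phi|) + lambda_region * mean((phi - g)^2)

with |grad phi| the L1 norm of forward differences (replicated border), so
both terms are pixel means and the default weights are resolution
independent.  The focal loss is mean(-alpha * (1 - p_t)^gamma * log p_t)
with p_t the predicted probability of the true class.  The hybrid loss is
L_AC + beta * L_Focal.

All three are differentiable w.r.t. the probability map and are used
directly as training objectives; the float-returning wrappers operate on
plain arrays.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn import Tensor


@dataclass
class LossConfig:
    lambda_length: float = 1.0
    lambda_region: float = 1.0
    alpha: float = 0.75      # focal class-balance factor
    gamma: float = 2.0       # focal focusing exponent
    beta: float = 0.3        # hybrid weight on the focal term
    epsilon: float = 1e-7    # log clamp

    def __post_init__(self):
        if not (0 < self.alpha <= 1):
            raise ValueError("alpha must be in (0, 1]")
        if self.gamma < 0 or self.beta < 0:
            raise ValueError("gamma and beta must be nonnegative")
        if self.lambda_length < 0 or self.lambda_region < 0:
            raise ValueError("lambda weights must be nonnegative")


@dataclass
class PredictionPair:
    """phi: predicted foreground probabilities; g: binary ground truth."""

    phi: np.ndarray
    g: np.ndarray

    def __post_init__(self):
        self.phi = np.asarray(self.phi, dtype=np.float32)
        self.g = np.asarray(self.g)
        if self.phi.shape != self.g.shape:
            raise ValueError(f"phi {self.phi.shape} and g {self.g.shape} disagree")
        if self.phi.min() < 0 or self.phi.max() > 1:
            raise ValueError("phi must lie in [0, 1]")
        if not np.isin(self.g, (0, 1)).all():
            raise ValueError("g must be binary")


def _as_tensors(p) -> tuple[Tensor, Tensor, int]:
    """Accept a PredictionPair or (Tensor phi, array g); returns batched (B,H,W)."""
    if isinstance(p, PredictionPair):
        phi, g = Tensor(p.phi), p.g
    else:
        phi, g = p
        if not isinstance(phi, Tensor):
            phi = Tensor(phi)
    gt = np.asarray(g, dtype=np.float32)
    if phi.ndim == 2:
        phi = phi.reshape(1, *phi.shape)
        gt = gt.reshape(1, *gt.shape)
    return phi, Tensor(gt), phi.shape[0]


def active_contour_term(phi: Tensor, g: Tensor, cfg: LossConfig) -> Tensor:
    """Differentiable L_AC on a (B, H, W) probability map."""
    b, h, w = phi.shape
    npix = float(h * w)
    region = ((phi - g) ** 2).mean()
    dx = (phi[:, :, 1:] - phi[:, :, :-1]).abs().sum()   # replicated border: zero diff
    dy = (phi[:, 1:, :] - phi[:, :-1, :]).abs().sum()
    length = (dx + dy) * (1.0 / (npix * b))
    return region * cfg.lambda_region + length * cfg.lambda_length


def focal_term(phi: Tensor, g: Tensor, cfg: LossConfig) -> Tensor:
    """Differentiable focal loss on a (B, H, W) probability map."""
    pt = phi * g + (1.0 - phi) * (1.0 - g)
    pt = pt.clip(cfg.epsilon, 1.0 - cfg.epsilon)
    if cfg.gamma == 0:
        weight = Tensor(np.full(pt.shape, 1.0, dtype=np.float32))
    else:
        weight = (1.0 - pt) ** cfg.gamma
    return (weight * pt.log() * (-cfg.alpha)).mean()


def active_contour_loss(p, cfg: LossConfig | None = None) -> float:
    cfg = cfg or LossConfig()
    phi, g, _ = _as_tensors(p)
    return float(active_contour_term(phi, g, cfg).data)


def focal_loss(p, cfg: LossConfig | None = None) -> float:
    cfg = cfg or LossConfig()
    phi, g, _ = _as_tensors(p)
    return float(focal_term(phi, g, cfg).data)


def hybrid_loss(p, cfg: LossConfig | None = None) -> tuple[float, float, float]:
    """(total, L_AC, L_Focal) with total = L_AC + beta * L_Focal."""
    cfg = cfg or LossConfig()
    phi, g, _ = _as_tensors(p)
    l_ac = active_contour_term(phi, g, cfg)
    l_fl = focal_term(phi, g, cfg)
    return float(l_ac.data + cfg.beta * l_fl.data), float(l_ac.data), float(l_fl.data)


def hybrid_loss_tensor(phi: Tensor, g: np.ndarray, cfg: LossConfig) -> tuple[Tensor, float, float]:
    """Training objective: differentiable total plus float components."""
    gt = Tensor(np.asarray(g, dtype=np.float32))
    l_ac = active_contour_term(phi, gt, cfg)
    l_fl = focal_term(phi, gt, cfg)
    total = l_ac + l_fl * cfg.beta
    return total, float(l_ac.data), float(l_fl.data)
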