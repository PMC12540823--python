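"""Segmentation evaluation: overlap metrics and surface distances.

Overlap metrics (recall, precision, F1, Dice, mIoU) are computed from exact
per-pixel confusion counts.  Surface metrics (ASSD, Hausdorff) operate on
boundary point sets in physical (mm) coordinates: a boundary pixel is a
foreground pixel with at least one background face-neighbor, where the
image border counts as background.

Empty-mask conventions: if both masks are empty the prediction is perfect
(overlap metrics 1, distances 0); if exactly one is empty, overlap metrics
are 0 and the distances are +inf with a warning flag on the report.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int
    per_class: list[tuple[int, int, int]] = field(default_factory=list)

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass
class SurfaceSet:
    points: np.ndarray                       # (M, ndim) coordinates in mm
    spacing: tuple[float, ...]

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class MetricReport:
    dsc: float
    precision: float
    recall: float
    f1: float
    miou: float
    assd_mm: float
    hd_mm: float
    surface_warning: bool = False

    def as_dict(self) -> dict:
        return {
            "dsc": self.dsc, "precision": self.precision, "recall": self.recall,
            "f1": self.f1, "miou": self.miou, "assd_mm": self.assd_mm,
            "hd_mm": self.hd_mm,
        }


def confusion_counts(pred: np.ndarray, gt: np.ndarray) -> ConfusionCounts:
    """Exact binary confusion counts between two equally shaped masks."""
    pred = np.asarray(pred) > 0
    gt = np.asarray(gt) > 0
    if pred.shape != gt.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs gt {gt.shape}")
    tp = int(np.sum(pred & gt))
    fp = int(np.sum(pred & ~gt))
    fn = int(np.sum(~pred & gt))
    tn = int(np.sum(~pred & ~gt))
    per_class = [(tn, fn, fp), (tp, fp, fn)]   # background, foreground
    return ConfusionCounts(tp, fp, fn, tn, per_class)


def overlap_metrics(c: ConfusionCounts) -> tuple[float, float, float, float]:
    """(recall, precision, f1, dsc); f1 and dsc are algebraically identical."""
    if c.tp + c.fp + c.fn == 0:          # both masks empty
        return 1.0, 1.0, 1.0, 1.0
    recall = c.tp / (c.tp + c.fn) if c.tp + c.fn else 0.0
    precision = c.tp / (c.tp + c.fp) if c.tp + c.fp else 0.0
    dsc = 2 * c.tp / (2 * c.tp + c.fp + c.fn)
    if precision + recall > 0:
        f1 = 2 * precision * recall / (precision + recall)
    else:
        f1 = 0.0
    return recall, precision, f1, dsc


def miou(pred: np.ndarray, gt: np.ndarray, k: int = 1) -> float:
    """Mean IoU over classes 0..k; classes absent from both maps are skipped."""
    pred = np.asarray(pred).astype(np.int64)
    gt = np.asarray(gt).astype(np.int64)
    if pred.min() < 0 or gt.min() < 0 or pred.max() > k or gt.max() > k:
        raise ValueError(f"labels out of range [0, {k}]")
    ious = []
    for cls in range(k + 1):
        p = pred == cls
        g = gt == cls
        union = int(np.sum(p | g))
        if union == 0:
            continue
        ious.append(int(np.sum(p & g)) / union)
    return float(np.mean(ious)) if ious else 1.0


def surface_extract(mask: np.ndarray, spacing=None) -> SurfaceSet:
    """Boundary pixels of a binary mask, scaled to mm coordinates."""
    mask = np.asarray(mask) > 0
    nd = mask.ndim
    if spacing is None:
        spacing = (1.0,) * nd
    padded = np.pad(mask, 1)  # border counts as background
    acc = np.ones_like(mask)
    for ax in range(nd):
        for shift in (-1, 1):
            acc &= np.roll(padded, shift, axis=ax)[tuple(slice(1, -1) for _ in range(nd))]
    boundary = mask & ~acc
    pts = np.argwhere(boundary).astype(np.float64) * np.asarray(spacing, dtype=np.float64)
    return SurfaceSet(points=pts, spacing=tuple(float(s) for s in spacing))


def surface_distances(a: SurfaceSet, b: SurfaceSet) -> tuple[float, float, float, float]:
    """(ASD(A,B), ASD(B,A), ASSD, HD) between two boundary point sets."""
    if len(a) == 0 or len(b) == 0:
        inf = float("inf")
        return inf, inf, inf, inf
    d_ab = cKDTree(b.points).query(a.points, k=1)[0]
    d_ba = cKDTree(a.points).query(b.points, k=1)[0]
    asd_ab = float(d_ab.mean())
    asd_ba = float(d_ba.mean())
    assd = 0.5 * (asd_ab + asd_ba)
    hd = float(max(d_ab.max(), d_ba.max()))
    return asd_ab, asd_ba, assd, hd


def evaluate_pair(pred: np.ndarray, gt: np.ndarray, spacing=None) -> MetricReport:
    """Full per-case metric report (works for 2D slices and 3D volumes)."""
    pred = np.asarray(pred) > 0
    gt = np.asarray(gt) > 0
    if pred.shape != gt.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs gt {gt.shape}")
    c = confusion_counts(pred, gt)
    recall, precision, f1, dsc = overlap_metrics(c)
    assert abs(dsc - f1) < 1e-12 or (precision + recall) == 0
    m = miou(pred.astype(np.int64), gt.astype(np.int64), k=1)

    if not pred.any() and not gt.any():
        return MetricReport(dsc, precision, recall, f1, m, 0.0, 0.0)
    sa = surface_extract(pred, spacing)
    sb = surface_extract(gt, spacing)
    _, _, assd, hd = surface_distances(sa, sb)
    warning = not np.isfinite(assd)
    return MetricReport(dsc, precision, recall, f1, m, assd, hd, warning)


def metric_table(reports: dict[str, MetricReport]) -> pd.DataFrame:
    """Per-case table plus mean and sd summary rows."""
    df = pd.DataFrame({cid: r.as_dict() for cid, r in reports.items()}).T
    df.index.name = "case"
    finite = df.replace([np.inf, -np.inf], np.nan)
    summary = pd.DataFrame({"mean": finite.mean(), "sd": finite.std()}).T
    return pd.concat([df, summary])
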