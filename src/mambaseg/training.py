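"""Training loop, slice-wise volume inference, and dataset evaluation.

The optimizer is AdamW with decoupled weight decay and cosine-annealed
learning rate; validation is monitored every epoch and training stops
early after `patience` epochs without improvement of the validation
hybrid loss.  The best-validation weights are retained.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import NetworkConfig, TrainConfig, tiny_network
from .losses import hybrid_loss_tensor
from .metrics import evaluate_pair, metric_table
from .network import SegmentationNetwork, build_network
from .nn import AdamW, Tensor, cosine_lr, no_grad
from .preprocessing import (
    MultiModalSlice,
    augment_slice,
    extract_axial_slices,
    load_multimodal_nifti,
    load_nifti_volume,
    normalize_multimodal,
    resize_slice,
)
from .volume import Volume, write_nifti


# ---------------------------------------------------------------------------
# dataset assembly
# ---------------------------------------------------------------------------

def read_manifest(manifest_path) -> pd.DataFrame:
    manifest_path = Path(manifest_path)
    if not manifest_path.exists():
        raise FileNotFoundError(f"manifest not found: {manifest_path}")
    df = pd.read_csv(manifest_path, sep="\t")
    df["image"] = [str(manifest_path.parent / p) for p in df["image"]]
    df["mask"] = [str(manifest_path.parent / p) for p in df["mask"]]
    return df


def build_slice_dataset(manifest_path, split: str, input_size: int,
                        lesion_only: bool = True) -> tuple[np.ndarray, np.ndarray]:
    """Load, normalize, slice and resize one split into (N,C,H,W) arrays."""
    df = read_manifest(manifest_path)
    rows = df[df["split"] == split]
    if rows.empty:
        raise ValueError(f"split '{split}' is empty in {manifest_path}")
    images, masks = [], []
    for _, row in rows.iterrows():
        mmv = normalize_multimodal(load_multimodal_nifti(row["image"]))
        mask = load_nifti_volume(row["mask"], modality="mask")
        for s in extract_axial_slices(mmv, mask, lesion_only=lesion_only,
                                      volume_id=Path(row["image"]).stem):
            s = resize_slice(s, (input_size, input_size))
            images.append(np.moveaxis(s.image, -1, 0))
            masks.append(s.mask)
    return np.stack(images).astype(np.float32), np.stack(masks).astype(np.uint8)


# ---------------------------------------------------------------------------
# early stopping
# ---------------------------------------------------------------------------

class EarlyStopper:
    """Stop after `patience` consecutive epochs without improvement."""

    def __init__(self, patience: int, min_delta: float = 0.0):
        self.patience = patience
        self.min_delta = min_delta
        self.best = float("inf")
        self.bad_epochs = 0
        self.improved = False

    def update(self, value: float) -> bool:
        """Record an epoch value; returns True when training should stop."""
        self.improved = value < self.best - self.min_delta
        if self.improved:
            self.best = value
            self.bad_epochs = 0
        else:
            self.bad_epochs += 1
        return self.bad_epochs >= self.patience


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def _batch_loss(model: SegmentationNetwork, xb: np.ndarray, yb: np.ndarray, loss_cfg):
    phi = model.foreground_probability(Tensor(xb))
    return hybrid_loss_tensor(phi, yb, loss_cfg)


def _eval_loss(model, images, masks, loss_cfg, batch_size) -> float:
    model.eval()
    tot, n = 0.0, 0
    with no_grad():
        for i in range(0, len(images), batch_size):
            xb, yb = images[i:i + batch_size], masks[i:i + batch_size]
            total, _, _ = _batch_loss(model, xb, yb, loss_cfg)
            tot += float(total.data) * len(xb)
            n += len(xb)
    model.train()
    return tot / n


def train(model: SegmentationNetwork, manifest_path, cfg: TrainConfig,
          out_dir=None, verbose: bool = False) -> dict:
    """Optimize the hybrid loss; returns history, best state and stop epoch."""
    rng = np.random.default_rng(cfg.seed)
    size = model.cfg.input_size
    tr_x, tr_y = build_slice_dataset(manifest_path, "train", size, cfg.lesion_only)
    va_x, va_y = build_slice_dataset(manifest_path, "val", size, cfg.lesion_only)

    opt = AdamW(model.parameters(), lr=cfg.lr0, weight_decay=cfg.weight_decay)
    stopper = EarlyStopper(cfg.patience)
    history = []
    best_state = model.state_dict()
    step = 0
    model.train()
    for epoch in range(cfg.epochs):
        if epoch < cfg.warmup_epochs:
            opt.lr = cfg.lr0 * (epoch + 1) / (cfg.warmup_epochs + 1)
        else:
            opt.lr = cosine_lr(epoch - cfg.warmup_epochs, cfg.lr0, cfg.lr_min,
                               max(1, cfg.epochs - cfg.warmup_epochs))
        order = rng.permutation(len(tr_x))
        ep_loss, ep_ac, ep_fl, nb = 0.0, 0.0, 0.0, 0
        for i in range(0, len(order), cfg.batch_size):
            idx = order[i:i + cfg.batch_size]
            if cfg.augment:
                xb, yb = [], []
                for j in idx:
                    s = MultiModalSlice(np.moveaxis(tr_x[j], 0, -1), tr_y[j])
                    s = augment_slice(s, rng)
                    xb.append(np.moveaxis(s.image, -1, 0))
                    yb.append(s.mask)
                xb, yb = np.stack(xb), np.stack(yb)
            else:
                xb, yb = tr_x[idx], tr_y[idx]
            total, l_ac, l_fl = _batch_loss(model, xb, yb, cfg.loss)
            opt.zero_grad()
            total.backward()
            if cfg.grad_clip:
                opt.clip_grad_norm(cfg.grad_clip)
            opt.step()
            ep_loss += float(total.data)
            ep_ac += l_ac
            ep_fl += l_fl
            nb += 1
            step += 1
            if cfg.max_steps is not None and step >= cfg.max_steps:
                break
        val_loss = _eval_loss(model, va_x, va_y, cfg.loss, cfg.batch_size)
        history.append({
            "epoch": epoch, "lr": opt.lr, "train_loss": ep_loss / nb,
            "train_ac": ep_ac / nb, "train_focal": ep_fl / nb, "val_loss": val_loss,
            "step": step,
        })
        if verbose:
            print(f"epoch {epoch}: train {ep_loss / nb:.4f} val {val_loss:.4f} lr {opt.lr:.2e}")
        stop = stopper.update(val_loss)
        if stopper.improved:
            best_state = model.state_dict()
        if stop or (cfg.max_steps is not None and step >= cfg.max_steps):
            break
    model.load_state_dict(best_state)
    result = {
        "history": pd.DataFrame(history),
        "best_val_loss": stopper.best,
        "stopped_epoch": history[-1]["epoch"],
        "steps": step,
    }
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        result["history"].to_csv(out_dir / "history.csv", index=False)
        save_checkpoint(model, cfg, out_dir / "checkpoint.npz")
    return result


def sweep_loss_grid(manifest_path, net_cfg: NetworkConfig, base_cfg: TrainConfig,
                    alphas=(0.25, 0.5, 0.75, 0.9),
                    betas=(0.1, 0.3, 0.5, 0.7, 1.0),
                    split: str = "val") -> pd.DataFrame:
    """Ablation grids over the focal class-balance factor alpha and the
    hybrid weight beta: trains one model per setting and tabulates mIoU and
    foreground F1 on a held-out split.  Grid and budget are configurable;
    each row is an independent seeded run from the same initialization."""
    import dataclasses

    from .metrics import confusion_counts, miou as miou_fn, overlap_metrics

    rows = []
    grid = [("alpha", a) for a in alphas] + [("beta", b) for b in betas]
    for name, value in grid:
        cfg = dataclasses.replace(base_cfg, loss=dataclasses.replace(base_cfg.loss, **{name: value}))
        model = build_network(net_cfg)
        train(model, manifest_path, cfg)
        x, y = build_slice_dataset(manifest_path, split, net_cfg.input_size)
        preds = []
        for i in range(0, len(x), cfg.batch_size):
            preds.append(model.predict_batch(x[i:i + cfg.batch_size]).labels)
        pred = np.concatenate(preds)
        _, _, f1, _ = overlap_metrics(confusion_counts(pred, y))
        rows.append({"parameter": name, "value": value,
                     "miou": miou_fn(pred, y), "foreground_f1": f1})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(model: SegmentationNetwork, train_cfg: TrainConfig | None, path) -> Path:
    """Weights plus embedded config/seed/version for provenance."""
    path = Path(path)
    meta = {
        "network": asdict(model.cfg),
        "train": asdict(train_cfg) if train_cfg else None,
        "version": __version__,
        "numpy": np.__version__,
    }
    np.savez(path, __meta__=json.dumps(meta), **model.state_dict())
    return path


def load_checkpoint(path) -> SegmentationNetwork:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"checkpoint not found: {path}")
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["__meta__"]))
        state = {k: data[k] for k in data.files if k != "__meta__"}
    net_cfg = meta["network"]
    net_cfg["stage_channels"] = tuple(net_cfg["stage_channels"])
    net_cfg["stage_repeats"] = tuple(net_cfg["stage_repeats"])
    model = build_network(NetworkConfig(**net_cfg))
    model.load_state_dict(state)
    model.eval()
    return model


# ---------------------------------------------------------------------------
# inference and evaluation
# ---------------------------------------------------------------------------

def predict_volume(model: SegmentationNetwork, image_path, batch_size: int = 8) -> Volume:
    """Slice-wise inference reassembled into a 3D label volume."""
    mmv = load_multimodal_nifti(image_path)
    if mmv.n_modalities != model.cfg.input_channels:
        raise ValueError(
            f"volume has {mmv.n_modalities} modalities, model expects "
            f"{model.cfg.input_channels}"
        )
    mmv = normalize_multimodal(mmv)
    size = model.cfg.input_size
    h, w, d, _ = mmv.data.shape
    dummy_mask = Volume(np.zeros((h, w, d), dtype=np.uint8), mmv.spacing)
    slices = extract_axial_slices(mmv, dummy_mask, lesion_only=False)
    imgs = np.stack([
        np.moveaxis(resize_slice(s, (size, size)).image, -1, 0) for s in slices
    ])
    labels = []
    for i in range(0, len(imgs), batch_size):
        labels.append(model.predict_batch(imgs[i:i + batch_size]).labels)
    pred = np.concatenate(labels).astype(np.uint8)          # (D, size, size)
    if (size, size) != (h, w):
        from skimage.transform import resize as sk_resize
        pred = np.stack([
            sk_resize(p, (h, w), order=0, preserve_range=True).astype(np.uint8)
            for p in pred
        ])
    return Volume(np.moveaxis(pred, 0, -1), mmv.spacing, modality="prediction")


def predict(model: SegmentationNetwork, image_paths, out_dir) -> list[Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for p in image_paths:
        vol = predict_volume(model, p)
        dest = out_dir / (Path(p).name.replace("_image", "_pred"))
        written.append(write_nifti(vol, dest))
    return written


def evaluate_dataset(model: SegmentationNetwork, manifest_path, split: str) -> dict:
    """Volume-level metric table plus slice-level mean Dice for one split."""
    df = read_manifest(manifest_path)
    rows = df[df["split"] == split]
    if rows.empty:
        raise ValueError(f"split '{split}' has no cases")
    reports, slice_dscs = {}, []
    for _, row in rows.iterrows():
        gt = load_nifti_volume(row["mask"], modality="mask")
        pred = predict_volume(model, row["image"])
        cid = Path(row["image"]).stem.replace("_image.nii", "")
        reports[cid] = evaluate_pair(pred.data, gt.data, spacing=gt.spacing)
        for d in range(gt.data.shape[2]):
            if gt.data[:, :, d].any() or pred.data[:, :, d].any():
                slice_dscs.append(evaluate_pair(pred.data[:, :, d], gt.data[:, :, d]).dsc)
    table = metric_table(reports)
    return {
        "table": table,
        "mean_dsc": float(table.loc["mean", "dsc"]),
        "slice_mean_dsc": float(np.mean(slice_dscs)) if slice_dscs else 1.0,
    }
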