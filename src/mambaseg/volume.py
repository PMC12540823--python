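"""3D volume container and NIfTI round-trip helpers."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np


@dataclass
class Volume:
    """A single-modality 3D scalar grid with voxel spacing in mm."""

    data: np.ndarray                      # (H, W, D)
    spacing: tuple[float, float, float]   # mm per axis
    modality: str = "unknown"

    def __post_init__(self):
        self.data = np.asarray(self.data)
        self.spacing = tuple(float(s) for s in self.spacing)
        if self.data.ndim != 3:
            raise ValueError(f"Volume data must be 3D, got shape {self.data.shape}")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class MultiModalVolume:
    """Channel-stacked modalities on a common grid: data is (H, W, D, C)."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    modalities: tuple[str, ...] = field(default_factory=tuple)

    @property
    def n_modalities(self) -> int:
        return self.data.shape[3]


def _affine(spacing) -> np.ndarray:
    return np.diag([spacing[0], spacing[1], spacing[2], 1.0])


def write_nifti(volume: Volume, path) -> Path:
    """Write a Volume (3D) or a MultiModalVolume (4D) as NIfTI-1."""
    path = Path(path)
    data = volume.data
    if data.dtype.kind in "ui":
        data = data.astype(np.uint8)
    else:
        data = data.astype(np.float32)
    img = nib.Nifti1Image(data, _affine(volume.spacing))
    zooms = volume.spacing + ((1.0,) if data.ndim == 4 else ())
    img.header.set_zooms(zooms)
    try:
        img.to_filename(str(path))
    except OSError as exc:
        raise OSError(f"cannot write NIfTI to {path}: {exc}") from exc
    return path


def _load(path) -> nib.Nifti1Image:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"NIfTI file not found: {path}")
    try:
        return nib.load(str(path))
    except Exception as exc:  # malformed file
        raise ValueError(f"not a readable NIfTI file: {path}: {exc}") from exc


def load_nifti_volume(path, modality: str = "unknown") -> Volume:
    """Load a 3D single-modality NIfTI volume; 4D files are rejected."""
    img = _load(path)
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(
            f"expected a 3D single-modality volume, got {data.ndim}D data in {path}; "
            "use load_multimodal_nifti for channel-stacked files"
        )
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return Volume(data=data, spacing=spacing, modality=modality)


def load_multimodal_nifti(path, modalities: tuple[str, ...] | None = None) -> MultiModalVolume:
    """Load a 4D NIfTI written by the synthetic generator (H, W, D, C)."""
    img = _load(path)
    data = np.asanyarray(img.dataobj)
    if data.ndim != 4:
        raise ValueError(f"expected a 4D multi-modal volume in {path}, got {data.ndim}D")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    mods = modalities or tuple(f"mod{i}" for i in range(data.shape[3]))
    return MultiModalVolume(data=data, spacing=spacing, modalities=mods)
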