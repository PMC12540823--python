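"""Seeded generator of multi-modal brain-like volumes with ellipsoidal lesions.

The generator emulates the statistical features of stroke/tumor MR data the
pipeline has to cope with, without any anatomy: per-volume raw intensity
ranges far outside [0, 1] (so normalization is non-trivial), a smooth
low-frequency background field shared across modalities (same "anatomy"
seen with different contrasts), modality-dependent lesion contrast
(hypointense on T1-like channels, strongly hyperintense on DWI/FLAIR-like
ones), small lesion volume fraction, and a mix of lesion-bearing and
lesion-free axial slices.

Lesions are axis-aligned ellipsoids with a smooth radial intensity falloff;
the ground-truth mask is the exact union of the ellipsoid interiors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .volume import MultiModalVolume, Volume, write_nifti

MODALITY_SETS = {3: ("T1", "T2", "DWI"), 4: ("T1", "T1c", "T2", "FLAIR")}
# lesion intensity offset per modality, as a fraction of the intensity range
CONTRAST_SETS = {3: (-0.12, 0.25, 0.40), 4: (-0.12, 0.20, 0.25, 0.35)}
INTENSITY_SETS = {
    3: ((0.0, 900.0), (0.0, 1200.0), (0.0, 600.0)),
    4: ((0.0, 900.0), (0.0, 850.0), (0.0, 1200.0), (0.0, 1000.0)),
}


@dataclass
class SyntheticSpec:
    """Study conditions for the synthetic data generator."""

    volume_shape: tuple[int, int, int] = (64, 64, 24)
    n_modalities: int = 3
    voxel_spacing: tuple[float, float, float] = (1.0, 1.0, 2.5)
    lesion_count_range: tuple[int, int] = (1, 3)
    lesion_radius_range: tuple[float, float] = (3.0, 7.0)   # in-plane, voxels
    lesion_contrast: tuple[float, ...] | None = None
    background_level: float = 0.45
    smooth_field_scale: float = 8.0       # voxels; scale of the background field
    field_amplitude: float = 0.12
    noise_sigma: float = 0.03             # iid noise, fraction of intensity range
    intensity_range: tuple[tuple[float, float], ...] | None = None
    seed: int = 0

    def __post_init__(self):
        self.validate()

    @property
    def modalities(self) -> tuple[str, ...]:
        return MODALITY_SETS[self.n_modalities]

    @property
    def contrasts(self) -> tuple[float, ...]:
        return self.lesion_contrast or CONTRAST_SETS[self.n_modalities]

    @property
    def ranges(self) -> tuple[tuple[float, float], ...]:
        return self.intensity_range or INTENSITY_SETS[self.n_modalities]

    def validate(self) -> None:
        if self.n_modalities not in (3, 4):
            raise ValueError(f"n_modalities must be 3 or 4, got {self.n_modalities}")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        h, w, d = self.volume_shape
        rmax = self.lesion_radius_range[1]
        if 2 * rmax >= min(h, w) or self.lesion_radius_range[0] <= 0:
            raise ValueError(
                f"lesion radius range {self.lesion_radius_range} does not fit "
                f"inside volume of shape {self.volume_shape}"
            )
        if self.lesion_contrast is not None and len(self.lesion_contrast) != self.n_modalities:
            raise ValueError("lesion_contrast length must match n_modalities")


def _ellipsoid_fields(shape, center, radii):
    """Normalized squared radius r2 over the voxel grid for one ellipsoid."""
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    r2 = sum(((g - c) / r) ** 2 for g, c, r in zip(grids, center, radii))
    return r2


def sample_lesions(spec: SyntheticSpec, rng: np.random.Generator) -> list[dict]:
    """Draw lesion centers/radii; z-extent is kept off the outermost slices."""
    h, w, d = spec.volume_shape
    lo, hi = spec.lesion_count_range
    n = int(rng.integers(lo, hi + 1))
    sx, _, sz = spec.voxel_spacing
    lesions = []
    for _ in range(n):
        rx = rng.uniform(*spec.lesion_radius_range)
        ry = rng.uniform(*spec.lesion_radius_range)
        # physical isotropy: scale the axial radius by the spacing ratio
        rz = float(np.clip(rng.uniform(*spec.lesion_radius_range) * sx / sz, 1.2, d / 6))
        cx = rng.uniform(rx + 1, h - rx - 2)
        cy = rng.uniform(ry + 1, w - ry - 2)
        cz = rng.uniform(rz + 2, d - rz - 3)  # slices 0..1 stay lesion-free
        lesions.append({"center": (cx, cy, cz), "radii": (rx, ry, rz)})
    return lesions


def generate_volume(spec: SyntheticSpec, seed: int) -> tuple[MultiModalVolume, Volume]:
    """Generate one multi-modal raw-intensity volume and its binary lesion mask.

    Deterministic: identical spec and seed give bit-identical arrays.
    """
    spec.validate()
    rng = np.random.default_rng(seed)
    shape = tuple(spec.volume_shape)
    lesions = sample_lesions(spec, rng)  # first draw, so tests can replay it

    # shared smooth "anatomy" field, unit-std
    field = gaussian_filter(rng.standard_normal(shape), sigma=spec.smooth_field_scale,
                            mode="nearest")
    sd = field.std()
    if sd > 0:
        field = field / sd
    mask = np.zeros(shape, dtype=np.uint8)
    profile = np.zeros(shape, dtype=np.float64)  # smooth radial falloff in [0,1]
    for les in lesions:
        r2 = _ellipsoid_fields(shape, les["center"], les["radii"])
        inside = r2 <= 1.0
        mask[inside] = 1
        profile = np.maximum(profile, np.sqrt(np.clip(1.0 - r2, 0.0, 1.0)))

    channels = []
    for m in range(spec.n_modalities):
        lo, hi = spec.ranges[m]
        span = hi - lo
        base = spec.background_level + spec.field_amplitude * field
        noise = spec.noise_sigma * rng.standard_normal(shape)
        raw = lo + span * (base + noise + spec.contrasts[m] * profile)
        channels.append(raw.astype(np.float32))

    mmv = MultiModalVolume(
        data=np.stack(channels, axis=-1),
        spacing=spec.voxel_spacing,
        modalities=spec.modalities,
    )
    mask_vol = Volume(data=mask, spacing=spec.voxel_spacing, modality="mask")
    return mmv, mask_vol


def _split_assignment(n: int, fractions: tuple[float, float, float]) -> list[str]:
    n_train = int(round(n * fractions[0]))
    n_val = int(round(n * fractions[1]))
    n_test = n - n_train - n_val
    return ["train"] * n_train + ["val"] * n_val + ["test"] * n_test


def generate_dataset(spec: SyntheticSpec, n_volumes: int, out_dir, seed: int,
                     split: tuple[float, float, float] = (0.6, 0.2, 0.2)) -> Path:
    """Write `n_volumes` image/mask NIfTI pairs plus a tabular manifest.

    Per-volume seeds are derived deterministically from the master seed, so
    regeneration with the same seed is byte-identical.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    child_seeds = [int(s) % (2 ** 31) for s in np.random.SeedSequence(seed).generate_state(n_volumes)]
    splits = _split_assignment(n_volumes, split)

    rows = []
    for i, (s, part) in enumerate(zip(child_seeds, splits)):
        mmv, mask = generate_volume(spec, s)
        img_path = out_dir / f"case{i:03d}_image.nii.gz"
        msk_path = out_dir / f"case{i:03d}_mask.nii.gz"
        write_nifti(mmv, img_path)
        write_nifti(mask, msk_path)
        rows.append({"image": img_path.name, "mask": msk_path.name, "split": part, "seed": s})

    manifest = out_dir / "manifest.tsv"
    pd.DataFrame(rows).to_csv(manifest, sep="\t", index=False)
    return manifest
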