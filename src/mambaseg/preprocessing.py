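"""Preprocessing: normalization, modality stacking, axial slicing, resizing
and training-time augmentation.

Conventions: arrays are (row, column) = (y from top, x from left), 0-based;
the axial slice index is the third volume axis.  Images are normalized to
[0, 1] per volume before slicing; masks stay binary throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import rotate as nd_rotate
from skimage.transform import resize as sk_resize

from .volume import (  # noqa: F401  (re-exported module surface)
    MultiModalVolume,
    Volume,
    load_multimodal_nifti,
    load_nifti_volume,
)

_EPS_RANGE = 1e-8  # guard for degenerate constant volumes


@dataclass
class MultiModalSlice:
    """A preprocessed 2D training sample: C-channel image in [0,1] + mask."""

    image: np.ndarray            # (H, W, C) float32 in [0, 1]
    mask: np.ndarray             # (H, W) uint8 in {0, 1}
    source: tuple[str, int] = ("", -1)   # (volume id, slice index)

    def __post_init__(self):
        if self.image.shape[:2] != self.mask.shape:
            raise ValueError(
                f"image {self.image.shape[:2]} and mask {self.mask.shape} disagree"
            )


def normalize_volume(v: Volume) -> Volume:
    """Min-max normalize the whole volume to [0, 1].

    A constant volume maps to all zeros (range guarded by a small epsilon).
    """
    data = v.data.astype(np.float32)
    lo, hi = float(data.min()), float(data.max())
    out = (data - lo) / max(hi - lo, _EPS_RANGE)
    return Volume(data=out, spacing=v.spacing, modality=v.modality)


def normalize_multimodal(mmv: MultiModalVolume) -> MultiModalVolume:
    """Per-volume, per-modality min-max normalization to [0, 1]."""
    chans = []
    for c in range(mmv.data.shape[3]):
        d = mmv.data[..., c].astype(np.float32)
        lo, hi = float(d.min()), float(d.max())
        chans.append((d - lo) / max(hi - lo, _EPS_RANGE))
    return MultiModalVolume(np.stack(chans, axis=-1), mmv.spacing, mmv.modalities)


def stack_modalities(volumes: list[Volume]) -> MultiModalVolume:
    """Concatenate modalities along a trailing channel axis (input order kept)."""
    if not volumes:
        raise ValueError("no volumes to stack")
    ref = volumes[0]
    for v in volumes[1:]:
        if v.data.shape != ref.data.shape:
            raise ValueError(
                f"modality '{v.modality}' shape {v.data.shape} does not match "
                f"'{ref.modality}' shape {ref.data.shape}"
            )
        if not np.allclose(v.spacing, ref.spacing):
            raise ValueError(f"modality '{v.modality}' spacing {v.spacing} differs")
    data = np.stack([v.data for v in volumes], axis=-1)
    return MultiModalVolume(data, ref.spacing, tuple(v.modality for v in volumes))


def extract_axial_slices(mmv: MultiModalVolume, mask: Volume,
                         lesion_only: bool = True,
                         volume_id: str = "") -> list[MultiModalSlice]:
    """Decompose a volume into axial 2D slices.

    With `lesion_only`, exactly the slices whose mask contains at least one
    foreground pixel are returned, in ascending slice order.
    """
    if mask.data.shape != mmv.data.shape[:3]:
        raise ValueError(f"mask shape {mask.data.shape} does not match volume {mmv.data.shape[:3]}")
    out = []
    for d in range(mmv.data.shape[2]):
        msk = (mask.data[:, :, d] > 0).astype(np.uint8)
        if lesion_only and msk.sum() == 0:
            continue
        img = np.ascontiguousarray(mmv.data[:, :, d, :], dtype=np.float32)
        out.append(MultiModalSlice(image=img, mask=msk, source=(volume_id, d)))
    return out


def resize_slice(s: MultiModalSlice, size: tuple[int, int]) -> MultiModalSlice:
    """Resize: bilinear for the image, nearest-neighbor for the mask."""
    h, w = size
    if h < 8 or w < 8:
        raise ValueError(f"target size {size} too small (min 8)")
    if s.image.shape[:2] == (h, w):
        return MultiModalSlice(s.image.copy(), s.mask.copy(), s.source)
    img = sk_resize(s.image, (h, w, s.image.shape[2]), order=1, mode="edge",
                    anti_aliasing=False, preserve_range=True).astype(np.float32)
    msk = sk_resize(s.mask, (h, w), order=0, mode="edge", anti_aliasing=False,
                    preserve_range=True).astype(np.uint8)
    return MultiModalSlice(image=img, mask=msk, source=s.source)


def augment_slice(s: MultiModalSlice, rng: np.random.Generator, *,
                  angle: float | None = None, hflip: bool | None = None,
                  vflip: bool | None = None, gain: float | None = None,
                  max_angle: float = 15.0) -> MultiModalSlice:
    """Random rotation, flips and contrast gain.

    Geometric transforms are applied identically to image and mask; the
    contrast gain touches the image only and the result is clipped to [0,1].
    Explicit keyword values override the random draws (used by tests).
    """
    if angle is None:
        angle = float(rng.uniform(-max_angle, max_angle))
    if hflip is None:
        hflip = bool(rng.random() < 0.5)
    if vflip is None:
        vflip = bool(rng.random() < 0.5)
    if gain is None:
        gain = float(rng.uniform(0.9, 1.1))

    img, msk = s.image, s.mask
    if angle != 0.0:
        img = nd_rotate(img, angle, axes=(1, 0), reshape=False, order=1, mode="nearest")
        msk = nd_rotate(msk, angle, axes=(1, 0), reshape=False, order=0, mode="nearest")
    if hflip:
        img, msk = img[:, ::-1], msk[:, ::-1]
    if vflip:
        img, msk = img[::-1], msk[::-1]
    img = np.clip(img.astype(np.float32) * gain, 0.0, 1.0)
    return MultiModalSlice(image=np.ascontiguousarray(img),
                           mask=np.ascontiguousarray(msk.astype(np.uint8)),
                           source=s.source)
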