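"""Patch extraction and intensity normalization.

Pipeline order (both modalities, after PET has been resampled onto the
planning-CT grid): resample to isotropic 1 mm^3 -> crop a 144^3-voxel patch
containing the lesion -> normalize intensities (CT: clip to [-800, 800] HU
and scale to [-1, 1]; PET: per-patch Z-score).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .image import Mask, Modality, Volume
from .registration import background_fill

__all__ = [
    "PatchSpec",
    "resample_isotropic",
    "crop_patch",
    "normalize_ct",
    "normalize_pet",
    "preprocess_case",
    "mask_centroid_voxel",
]

CT_CLIP_HU = 800.0
DEFAULT_PATCH_SIZE = (144, 144, 144)


@dataclass(frozen=True)
class PatchSpec:
    """A half-open crop window ``[center - size//2, center - size//2 + size)``."""

    size: tuple[int, int, int] = DEFAULT_PATCH_SIZE
    center: tuple[int, int, int] = (0, 0, 0)
    pad_value: float = 0.0

    def __post_init__(self) -> None:
        if len(self.size) != 3 or any(int(s) < 1 for s in self.size):
            raise ValueError(f"patch size components must be positive, got {self.size}")

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        size = np.asarray(self.size, dtype=int)
        lo = np.asarray(self.center, dtype=int) - size // 2
        return lo, lo + size


def resample_isotropic(v: Volume, target_spacing=(1.0, 1.0, 1.0)) -> Volume:
    """Resample to the target spacing (default 1 mm^3) with trilinear interpolation.

    Output shape is ``ceil(extent / target_spacing)`` and the origin is
    preserved; sample points beyond the source extent clamp to the edge.
    Masks are resampled nearest-neighbour.
    """
    target = np.asarray(target_spacing, dtype=float)
    if target.shape != (3,) or np.any(target <= 0) or not np.all(np.isfinite(target)):
        raise ValueError(f"target spacing must be 3 positive numbers, got {target_spacing}")
    src = np.asarray(v.spacing)
    out_shape = tuple(int(np.ceil(e / t)) for e, t in zip(v.physical_extent(), target))
    # output voxel j sits at origin + j*target  ->  source index j*target/src
    matrix = target / src
    order = 0 if isinstance(v, Mask) else 1
    data = ndimage.affine_transform(
        np.asarray(v.data, dtype=float),
        matrix,
        offset=np.zeros(3),
        output_shape=out_shape,
        order=order,
        mode="nearest",
    )
    if isinstance(v, Mask):
        return Mask(data=np.rint(data), spacing=tuple(target), origin=v.origin)
    return Volume(data=data, spacing=tuple(target), origin=v.origin, modality=v.modality,
                  normalized=v.normalized)


def crop_patch(v: Volume, spec: PatchSpec) -> Volume:
    """Extract the patch window; out-of-image parts are padded with ``spec.pad_value``.

    The origin is shifted so patch voxel (0,0,0) keeps the physical
    coordinate of the window corner in the source frame.
    """
    center = np.asarray(spec.center, dtype=int)
    shape = np.asarray(v.shape)
    if np.any(center < 0) or np.any(center >= shape):
        raise ValueError(f"patch center {tuple(center)} outside image of shape {v.shape}")
    lo, hi = spec.bounds()
    size = np.asarray(spec.size, dtype=int)

    out = np.full(tuple(size), float(spec.pad_value), dtype=float)
    src_lo = np.maximum(lo, 0)
    src_hi = np.minimum(hi, shape)
    dst_lo = src_lo - lo
    dst_hi = dst_lo + (src_hi - src_lo)
    out[dst_lo[0]:dst_hi[0], dst_lo[1]:dst_hi[1], dst_lo[2]:dst_hi[2]] = v.data[
        src_lo[0]:src_hi[0], src_lo[1]:src_hi[1], src_lo[2]:src_hi[2]
    ]
    new_origin = tuple(v.index_to_physical(lo))
    if isinstance(v, Mask):
        return Mask(data=np.rint(out), spacing=v.spacing, origin=new_origin)
    return Volume(data=out, spacing=v.spacing, origin=new_origin, modality=v.modality,
                  normalized=v.normalized)


def normalize_ct(v: Volume, clip_hu: float = CT_CLIP_HU) -> Volume:
    """Clip HU to [-clip_hu, clip_hu] and scale linearly to [-1, 1]."""
    if v.modality is not Modality.CT:
        raise ValueError(f"normalize_ct expects a CT volume, got modality {v.modality}")
    if v.normalized:
        raise ValueError("CT volume is already normalized; refusing double application")
    data = np.clip(np.asarray(v.data, dtype=float), -clip_hu, clip_hu) / clip_hu
    return Volume(data=data, spacing=v.spacing, origin=v.origin, modality=v.modality, normalized=True)


def normalize_pet(patch: Volume, degenerate_std: float = 1e-8) -> Volume:
    """Per-patch Z-score: subtract the patch mean, divide by the population SD.

    A (near-)constant patch maps to all zeros rather than propagating NaN.
    """
    if patch.modality is not Modality.PET:
        raise ValueError(f"normalize_pet expects a PET volume, got modality {patch.modality}")
    if patch.normalized:
        raise ValueError("PET patch is already normalized; refusing double application")
    data = np.asarray(patch.data, dtype=float)
    std = float(data.std())  # population (divisor N)
    if std < degenerate_std:
        out = np.zeros_like(data)
    else:
        out = (data - data.mean()) / std
    return Volume(data=out, spacing=patch.spacing, origin=patch.origin, modality=patch.modality,
                  normalized=True)


def mask_centroid_voxel(mask: Mask) -> tuple[int, int, int]:
    """Rounded voxel index of the foreground centroid."""
    if mask.n_foreground == 0:
        raise ValueError("cannot locate the centroid of an empty mask")
    idx = np.argwhere(mask.data > 0)
    return tuple(int(round(c)) for c in idx.mean(axis=0))


def preprocess_case(
    ct: Volume,
    pet: Volume,
    mask: Mask | None = None,
    patch_size=DEFAULT_PATCH_SIZE,
    center_voxel=None,
    target_spacing=(1.0, 1.0, 1.0),
) -> tuple[Volume, Volume, Mask | None]:
    """Full chain: resample both modalities isotropically, crop the lesion
    patch, normalize CT and PET. CT and PET must share a grid on entry
    (i.e. PET already registered to the planning CT).

    The patch is centred on the mask centroid when a mask is given
    (training), on ``center_voxel`` when supplied, else on the image
    centre (inference without a seed point).
    """
    if not ct.same_grid(pet):
        raise ValueError("CT and PET must be on the same grid (register PET to the pCT first)")
    ct_r = resample_isotropic(ct, target_spacing)
    pet_r = resample_isotropic(pet, target_spacing)
    mask_r = resample_isotropic(mask, target_spacing) if mask is not None else None

    if center_voxel is not None:
        center = tuple(int(c) for c in center_voxel)
    elif mask_r is not None and mask_r.n_foreground > 0:
        center = mask_centroid_voxel(mask_r)
    else:
        center = tuple(s // 2 for s in ct_r.shape)

    size = tuple(int(s) for s in patch_size)
    ct_p = crop_patch(ct_r, PatchSpec(size, center, pad_value=background_fill(Modality.CT)))
    pet_p = crop_patch(pet_r, PatchSpec(size, center, pad_value=background_fill(Modality.PET)))
    mask_p = crop_patch(mask_r, PatchSpec(size, center, pad_value=0.0)) if mask_r is not None else None

    return normalize_ct(ct_p), normalize_pet(pet_p), mask_p
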