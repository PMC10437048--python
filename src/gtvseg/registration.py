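"""Rigid landmark registration and transform application.

The diagnostic PET arrives in the diagnostic scanner's frame; the planning
CT (pCT) defines the treatment frame. A clinician picks 8-10 paired
anatomical landmarks in both frames; the rigid (rotation + translation)
transform minimizing the mean squared landmark mismatch is solved in closed
form (SVD-based orthogonal Procrustes, reflection excluded), and the PET is
resampled onto the pCT grid through it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .image import LandmarkSet, Mask, Modality, RigidTransform, Volume

__all__ = [
    "RegistrationResult",
    "solve_rigid_landmarks",
    "apply_transform",
    "check_registration_extent",
    "background_fill",
]

logger = logging.getLogger(__name__)

REGISTRATION_CUBE_MM = 150.0

_FILL = {Modality.CT: -1000.0, Modality.PET: 0.0, Modality.PROB: 0.0, Modality.OTHER: 0.0}


def background_fill(modality: Modality) -> float:
    """Physically neutral out-of-extent fill value: air HU for CT, zero uptake for PET."""
    return _FILL[Modality(modality)]


@dataclass(frozen=True)
class RegistrationResult:
    transform: RigidTransform
    rms_residual: float
    n_landmarks: int


def solve_rigid_landmarks(fixed: LandmarkSet, moving: LandmarkSet) -> RegistrationResult:
    """Least-squares rigid fit mapping moving landmarks onto fixed landmarks.

    Kabsch algorithm: centre both clouds, take the SVD of the covariance,
    and correct the sign of the smallest singular direction so the result
    is a proper rotation (det = +1), never a reflection.

    Returns the transform together with the post-fit RMS residual in mm.
    """
    P = np.asarray(moving.points, dtype=float)
    Q = np.asarray(fixed.points, dtype=float)
    if P.shape[0] != Q.shape[0]:
        raise ValueError(f"landmark count mismatch: fixed has {Q.shape[0]}, moving has {P.shape[0]}")
    n = P.shape[0]
    if n < 3:
        raise ValueError(f"rigid registration needs >= 3 landmark pairs, got {n}")

    p0, q0 = P.mean(axis=0), Q.mean(axis=0)
    Pc, Qc = P - p0, Q - q0
    # collinear clouds leave a rotation axis unconstrained
    if np.linalg.matrix_rank(Pc, tol=1e-9 * max(1.0, np.abs(Pc).max())) < 2:
        raise ValueError("degenerate landmark geometry: points are collinear")

    H = Pc.T @ Qc
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = q0 - R @ p0
    transform = RigidTransform.from_rotation_translation(R, t)
    residuals = transform.apply_points(P) - Q
    rms = float(np.sqrt(np.mean(np.sum(residuals**2, axis=1))))
    return RegistrationResult(transform=transform, rms_residual=rms, n_landmarks=n)


def _resample_affine(moving: Volume, t: RigidTransform, reference: Volume, order: int, cval: float) -> np.ndarray:
    """Pull-back resampling: reference voxel -> fixed mm -> t^-1 -> moving mm -> moving voxel."""
    Rinv = t.rotation.T
    s_m = np.asarray(moving.spacing)
    s_f = np.asarray(reference.spacing)
    o_m = np.asarray(moving.origin)
    o_f = np.asarray(reference.origin)
    M = (Rinv * s_f[np.newaxis, :]) / s_m[:, np.newaxis]
    offset = (Rinv @ (o_f - t.translation) - o_m) / s_m
    return ndimage.affine_transform(
        np.asarray(moving.data, dtype=float),
        M,
        offset=offset,
        output_shape=reference.shape,
        order=order,
        mode="constant",
        cval=cval,
    )


def apply_transform(moving: Volume, t: RigidTransform, reference: Volume) -> Volume:
    """Resample ``moving`` onto the grid of ``reference`` through rigid transform ``t``.

    Trilinear interpolation for scalar volumes, nearest-neighbour for masks
    (so they stay binary); out-of-extent voxels take the modality's
    background value (CT: -1000 HU, PET/masks: 0).
    """
    if isinstance(moving, Mask):
        data = _resample_affine(moving, t, reference, order=0, cval=0.0)
        return Mask(data=np.rint(data), spacing=reference.spacing, origin=reference.origin)
    cval = background_fill(moving.modality)
    data = _resample_affine(moving, t, reference, order=1, cval=cval)
    return Volume(data=data, spacing=reference.spacing, origin=reference.origin, modality=moving.modality)


def check_registration_extent(reference: Volume, tumor_centroid, cube_mm: float = REGISTRATION_CUBE_MM) -> bool:
    """Whether a ``cube_mm``-sided cube centred on the tumor fits inside the image.

    Registration is only trusted within >= 150x150x150 mm^3 around the
    lesion; a smaller available margin is logged as a warning and returns
    False. The boundary itself counts as inside.
    """
    c = np.asarray(tumor_centroid, dtype=float)
    lo = np.asarray(reference.origin)
    hi = lo + reference.physical_extent()
    if np.any(c < lo) or np.any(c > hi):
        raise ValueError(f"tumor centroid {c} lies outside the image extent [{lo}, {hi}]")
    half = cube_mm / 2.0
    ok = bool(np.all(c - half >= lo - 1e-9) and np.all(c + half <= hi + 1e-9))
    if not ok:
        logger.warning(
            "registration cube of %.0f mm around centroid %s exceeds image extent [%s, %s]",
            cube_mm,
            np.round(c, 1),
            np.round(lo, 1),
            np.round(hi, 1),
        )
    return ok
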