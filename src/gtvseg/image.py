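"""Volumetric data model and file I/O.

Carries CT, PET and probability volumes on axis-aligned grids, binary
segmentation masks, rigid (rotation + translation) transforms between
physical frames, and ordered landmark lists in millimetre coordinates.

Conventions
-----------
* Physical coordinates are in mm; voxel indices are 0-based.
* Voxel ``(i, j, k)`` of a volume sits at ``origin + (i*sx, j*sy, k*sz)``
  (identity direction cosines; oblique NIfTI files are rejected).
* Crop windows are half-open ``[lo, hi)``.
* Rigid transforms map *moving*-frame physical points into the *fixed*
  (planning CT) frame.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from enum import Enum
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "Modality",
    "Volume",
    "Mask",
    "RigidTransform",
    "LandmarkSet",
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "read_transform",
    "write_transform",
    "read_landmarks",
    "write_landmarks",
]

_DIRECTION_TOL = 1e-3
_RIGID_TOL = 1e-6


class Modality(str, Enum):
    CT = "CT"
    PET = "PET"
    PROB = "PROB"
    OTHER = "OTHER"


@dataclass
class Volume:
    """A 3D scalar grid with physical spacing and origin.

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz)
        Scalar intensities (HU for CT, uptake for PET).
    spacing : tuple of float
        Voxel size (sx, sy, sz) in mm; strictly positive.
    origin : tuple of float
        Physical coordinate of voxel (0, 0, 0) in mm.
    modality : Modality
        What the scalars mean.
    normalized : bool
        Set by the preprocessing stage; guards double normalization.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    modality: Modality = Modality.OTHER
    normalized: bool = False

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise ValueError(
                f"volume data must be 3D with each axis >= 1, got shape {self.data.shape}"
            )
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or len(self.origin) != 3:
            raise ValueError("spacing and origin must be length-3")
        sp = np.asarray(self.spacing)
        if not (np.all(np.isfinite(sp)) and np.all(sp > 0)):
            raise ValueError(f"spacing must be strictly positive and finite, got {self.spacing}")
        if not np.all(np.isfinite(self.origin)):
            raise ValueError(f"origin must be finite, got {self.origin}")
        self.modality = Modality(self.modality)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def physical_extent(self) -> np.ndarray:
        """Full grid extent (shape * spacing) in mm."""
        return np.asarray(self.shape) * np.asarray(self.spacing)

    def index_to_physical(self, index) -> np.ndarray:
        """Physical mm coordinate of a (possibly fractional) voxel index."""
        return np.asarray(self.origin) + np.asarray(index, dtype=float) * np.asarray(self.spacing)

    def physical_to_index(self, point) -> np.ndarray:
        """Continuous voxel index of a physical mm point."""
        return (np.asarray(point, dtype=float) - np.asarray(self.origin)) / np.asarray(self.spacing)

    def same_grid(self, other: "Volume | Mask", tol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=tol)
            and np.allclose(self.origin, other.origin, atol=tol)
        )

    def with_data(self, data: np.ndarray, **kw) -> "Volume":
        return replace(self, data=data, **kw)


@dataclass
class Mask(Volume):
    """Binary segmentation aligned to a companion Volume (values 0/1)."""

    modality: Modality = Modality.OTHER

    def __post_init__(self) -> None:
        super().__post_init__()
        vals = np.unique(self.data)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError(f"mask values must be exactly 0 or 1, found {vals[:10]}")
        self.data = self.data.astype(np.uint8)

    @property
    def n_foreground(self) -> int:
        return int(self.data.sum())

    def volume_mm3(self) -> float:
        return self.n_foreground * float(np.prod(self.spacing))


def _validate_rigid(matrix: np.ndarray) -> None:
    if matrix.shape != (4, 4):
        raise ValueError(f"transform matrix must be 4x4, got {matrix.shape}")
    if not np.array_equal(matrix[3], [0.0, 0.0, 0.0, 1.0]):
        raise ValueError(f"last row must be (0,0,0,1) exactly, got {matrix[3]}")
    R = matrix[:3, :3]
    ortho_err = np.abs(R.T @ R - np.eye(3)).max()
    if ortho_err > _RIGID_TOL:
        raise ValueError(f"rotation block is not orthonormal (max |R'R - I| = {ortho_err:.3g})")
    det = float(np.linalg.det(R))
    if abs(det - 1.0) > _RIGID_TOL:
        raise ValueError(f"rotation block has det = {det:.6g}, expected +1 (reflections rejected)")


@dataclass(frozen=True)
class RigidTransform:
    """Rotation + translation mapping moving-frame mm points to fixed-frame mm points."""

    matrix: np.ndarray
    direction: str = "moving_to_fixed"

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        _validate_rigid(m)
        object.__setattr__(self, "matrix", m)
        if self.direction != "moving_to_fixed":
            raise ValueError(f"unsupported transform direction {self.direction!r}")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(4))

    @classmethod
    def from_rotation_translation(cls, R, t) -> "RigidTransform":
        m = np.eye(4)
        m[:3, :3] = R
        m[:3, 3] = t
        return cls(m)

    @property
    def rotation(self) -> np.ndarray:
        return self.matrix[:3, :3]

    @property
    def translation(self) -> np.ndarray:
        return self.matrix[:3, 3]

    def inverse(self) -> "RigidTransform":
        R = self.rotation.T
        return RigidTransform.from_rotation_translation(R, -R @ self.translation)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Transform applying ``other`` first, then ``self``."""
        return RigidTransform(self.matrix @ other.matrix)

    def apply_points(self, points) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return pts @ self.rotation.T + self.translation


@dataclass
class LandmarkSet:
    """Ordered fiducial points in physical mm coordinates."""

    points: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        pts = np.atleast_2d(np.asarray(self.points, dtype=float))
        if pts.ndim != 2 or pts.shape[1] != 3:
            raise ValueError(f"landmarks must be an (n, 3) array, got {pts.shape}")
        if not np.all(np.isfinite(pts)):
            raise ValueError("landmark coordinates must be finite")
        self.points = pts

    def __len__(self) -> int:
        return self.points.shape[0]


# ---------------------------------------------------------------------------
# NIfTI volume I/O


def _affine_from_grid(spacing, origin) -> np.ndarray:
    aff = np.eye(4)
    aff[:3, :3] = np.diag(spacing)
    aff[:3, 3] = origin
    return aff


def read_volume(path, modality: Modality = Modality.OTHER) -> Volume:
    """Read a 3D NIfTI file into a Volume.

    Rejects non-3D images and images with non-identity direction cosines
    (beyond 1e-3): the toolkit's coordinate convention is axis-aligned.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such volume file: {path}")
    img = nib.load(str(path))
    shape = img.shape
    if len(shape) != 3:
        raise ValueError(f"expected a 3D NIfTI image, got {len(shape)}D with shape {shape}")
    aff = np.asarray(img.affine, dtype=float)
    spacing = np.linalg.norm(aff[:3, :3], axis=0)
    if np.any(spacing <= 0):
        raise ValueError(f"non-positive voxel spacing in {path}")
    direction = aff[:3, :3] / spacing
    if np.abs(direction - np.eye(3)).max() > _DIRECTION_TOL:
        raise ValueError(
            f"{path}: non-axis-aligned direction cosines are not supported "
            f"(max deviation {np.abs(direction - np.eye(3)).max():.3g})"
        )
    data = np.asarray(img.dataobj).astype(np.float64)
    return Volume(data=data, spacing=tuple(spacing), origin=tuple(aff[:3, 3]), modality=modality)


def write_volume(v: Volume, path) -> Path:
    """Write a Volume to NIfTI; inverse of :func:`read_volume`."""
    path = Path(path)
    if not path.parent.exists():
        raise FileNotFoundError(f"parent directory does not exist: {path.parent}")
    img = nib.Nifti1Image(np.asarray(v.data, dtype=np.float64), _affine_from_grid(v.spacing, v.origin))
    img.header.set_zooms(v.spacing)
    nib.save(img, str(path))
    return path


def read_mask(path) -> Mask:
    v = read_volume(path)
    data = np.rint(v.data)
    if not np.all(np.isin(np.unique(data), (0, 1))):
        raise ValueError(f"{path}: mask file contains values other than 0/1")
    return Mask(data=data, spacing=v.spacing, origin=v.origin)


def write_mask(m: Mask, path) -> Path:
    return write_volume(m, path)


# ---------------------------------------------------------------------------
# Rigid transform I/O (JSON dialect, plain 4-line text also accepted)


def write_transform(t: RigidTransform, path) -> Path:
    path = Path(path)
    payload = {"matrix": [float(x) for x in t.matrix.reshape(-1)], "direction": t.direction}
    path.write_text(json.dumps(payload, indent=2) + "\n")
    return path


def read_transform(path) -> RigidTransform:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such transform file: {path}")
    text = path.read_text().strip()
    if text.startswith("{"):
        payload = json.loads(text)
        flat = np.asarray(payload["matrix"], dtype=float)
        if flat.size != 16:
            raise ValueError(f"{path}: 'matrix' must hold 16 row-major floats, got {flat.size}")
        matrix = flat.reshape(4, 4)
        direction = payload.get("direction", "moving_to_fixed")
    else:
        rows = [line.split() for line in text.splitlines() if line.strip()]
        matrix = np.asarray(rows, dtype=float)
        direction = "moving_to_fixed"
    return RigidTransform(matrix=matrix, direction=direction)


# ---------------------------------------------------------------------------
# Landmark I/O (CSV with header x,y,z in mm)


def write_landmarks(lm: LandmarkSet, path) -> Path:
    path = Path(path)
    pd.DataFrame(lm.points, columns=["x", "y", "z"]).to_csv(path, index=False)
    return path


def read_landmarks(path, label: str = "") -> LandmarkSet:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such landmark file: {path}")
    df = pd.read_csv(path)
    missing = {"x", "y", "z"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: landmark CSV missing columns {sorted(missing)}")
    return LandmarkSet(points=df[["x", "y", "z"]].to_numpy(dtype=float), label=label or path.stem)
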