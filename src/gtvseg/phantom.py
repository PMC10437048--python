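"""Synthetic dual-modality lung phantoms.

Emulates the data regime the pipeline is built for: a planning-CT-like
volume (soft-tissue body shell around lung-density background, an embedded
higher-HU ellipsoidal tumor, bright fiducial markers), a PET volume with
elevated tumor uptake blurred by the scanner point-spread function plus
noise, an exact ground-truth tumor mask, and an optional known rigid
misalignment between the PET (diagnostic) frame and the CT (planning)
frame with paired landmark lists in both frames.

Geometry is analytic (ellipsoids and elliptic cylinders), so the
moving-frame volumes are generated by evaluating the same analytic scene
at rigidly transformed coordinates — no double interpolation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .image import LandmarkSet, Mask, Modality, RigidTransform, Volume

__all__ = ["TumorSpec", "PETSpec", "PhantomSpec", "PhantomCase", "generate_phantom",
           "generate_cohort", "random_rigid", "ellipsoid_volume_cm3", "semi_axes_for_volume"]

_FWHM_TO_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))


@dataclass(frozen=True)
class TumorSpec:
    center_mm: tuple = (80.0, 80.0, 80.0)
    semi_axes_mm: tuple = (10.0, 12.0, 9.0)
    hu_mean: float = 40.0
    hu_sd: float = 15.0
    rotation_deg: float = 0.0      # in-plane orientation of the ellipsoid
    boundary_wobble: float = 0.0   # optional low-frequency radial perturbation


@dataclass(frozen=True)
class PETSpec:
    tumor_uptake: float = 5.0
    background_uptake: float = 1.0
    psf_fwhm_mm: float = 6.0
    noise_level: float = 0.05


@dataclass(frozen=True)
class PhantomSpec:
    grid_shape: tuple = (80, 80, 80)
    spacing: tuple = (2.0, 2.0, 2.0)
    tumor: TumorSpec = field(default_factory=TumorSpec)
    lung_hu_mean: float = -750.0
    lung_hu_sd: float = 40.0
    body_hu_mean: float = 30.0
    body_hu_sd: float = 10.0
    fiducial_hu: float = 800.0
    fiducial_radius_mm: float = 3.0
    pet: PETSpec = field(default_factory=PETSpec)
    misalignment: RigidTransform | None = None
    n_landmarks: int = 10
    seed: int = 0

    @property
    def extent_mm(self) -> np.ndarray:
        return np.asarray(self.grid_shape) * np.asarray(self.spacing)


@dataclass
class PhantomCase:
    case_id: str
    ct: Volume
    pet: Volume            # moving frame when a misalignment is present
    truth: Mask            # fixed (planning CT) frame
    truth_moving: Mask
    landmarks_fixed: LandmarkSet
    landmarks_moving: LandmarkSet
    transform: RigidTransform  # moving -> fixed; identity when aligned
    spec: PhantomSpec


def ellipsoid_volume_cm3(semi_axes_mm) -> float:
    a, b, c = semi_axes_mm
    return 4.0 / 3.0 * math.pi * a * b * c / 1000.0


def semi_axes_for_volume(volume_cm3: float, anisotropy=(1.0, 1.0, 1.0)) -> tuple:
    """Semi-axes (mm) of an ellipsoid of the given volume with shape factors."""
    f = np.asarray(anisotropy, dtype=float)
    r = (3.0 * volume_cm3 * 1000.0 / (4.0 * math.pi)) ** (1.0 / 3.0)
    f = f / f.prod() ** (1.0 / 3.0)
    return tuple(r * f)


def random_rigid(rng: np.random.Generator, max_rotation_deg: float = 5.0,
                 max_translation_mm: float = 8.0, center_mm=(0.0, 0.0, 0.0)) -> RigidTransform:
    """Random small rigid transform rotating about ``center_mm``."""
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    theta = math.radians(rng.uniform(0.0, max_rotation_deg))
    K = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]])
    R = np.eye(3) + math.sin(theta) * K + (1 - math.cos(theta)) * (K @ K)
    shift = rng.uniform(-max_translation_mm, max_translation_mm, size=3)
    c = np.asarray(center_mm)
    t = c - R @ c + shift
    return RigidTransform.from_rotation_translation(R, t)


def _grid_coords(spec: PhantomSpec):
    """Physical mm coordinates of every voxel centre, shape (3, nx, ny, nz)."""
    idx = np.indices(spec.grid_shape, dtype=np.float64)
    sp = np.asarray(spec.spacing).reshape(3, 1, 1, 1)
    return idx * sp


def _rotz(deg: float) -> np.ndarray:
    r = math.radians(deg)
    return np.array([[math.cos(r), -math.sin(r), 0], [math.sin(r), math.cos(r), 0], [0, 0, 1]])


def _tumor_mask(coords, tumor: TumorSpec) -> np.ndarray:
    Q = _rotz(tumor.rotation_deg)
    d = coords - np.asarray(tumor.center_mm).reshape(3, 1, 1, 1)
    u = np.einsum("ji,jxyz->ixyz", Q, d) / np.asarray(tumor.semi_axes_mm).reshape(3, 1, 1, 1)
    rho = np.sqrt((u**2).sum(axis=0))
    if tumor.boundary_wobble:
        phi = np.arctan2(u[1], u[0])
        theta = np.arctan2(np.hypot(u[0], u[1]), u[2])
        rho = rho / (1.0 + tumor.boundary_wobble * np.sin(3 * phi) * np.sin(2 * theta))
    return rho <= 1.0


def _elliptic_cylinder(coords, center_xy, semi_xy) -> np.ndarray:
    dx = (coords[0] - center_xy[0]) / semi_xy[0]
    dy = (coords[1] - center_xy[1]) / semi_xy[1]
    return dx**2 + dy**2 <= 1.0


def _scene_regions(spec: PhantomSpec, coords):
    """Body shell / lung / tumor indicator masks at the given coordinates."""
    ext = spec.extent_mm
    center_xy = (ext[0] / 2.0, ext[1] / 2.0)
    body = _elliptic_cylinder(coords, center_xy, (0.45 * ext[0], 0.40 * ext[1]))
    lung = _elliptic_cylinder(coords, center_xy, (0.35 * ext[0], 0.30 * ext[1]))
    tumor = _tumor_mask(coords, spec.tumor)
    return body, lung, tumor


def _default_landmarks(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """Fiducial points in the body shell: a jittered ring at varied depths."""
    ext = spec.extent_mm
    n = spec.n_landmarks
    if n < 3:
        raise ValueError("need at least 3 landmarks for rigid registration")
    angles = np.linspace(0.0, 2.0 * math.pi, n, endpoint=False) + rng.uniform(-0.15, 0.15, n)
    z = np.linspace(0.3, 0.7, n) * ext[2] + rng.uniform(-2.0, 2.0, n)
    x = ext[0] / 2.0 + 0.40 * ext[0] * np.cos(angles)
    y = ext[1] / 2.0 + 0.35 * ext[1] * np.sin(angles)
    return np.column_stack([x, y, z])


def _paint_fiducials(ct: np.ndarray, coords, points: np.ndarray, radius: float, hu: float) -> None:
    for p in points:
        d2 = ((coords - p.reshape(3, 1, 1, 1)) ** 2).sum(axis=0)
        ct[d2 <= radius**2] = hu


def _pet_from_regions(spec: PhantomSpec, body, tumor, rng: np.random.Generator) -> np.ndarray:
    pet = np.where(body, spec.pet.background_uptake, 0.0)
    pet = np.where(tumor, spec.pet.tumor_uptake, pet)
    sigma_vox = spec.pet.psf_fwhm_mm / _FWHM_TO_SIGMA / np.asarray(spec.spacing)
    pet = ndimage.gaussian_filter(pet, sigma=sigma_vox)
    if spec.pet.noise_level > 0:
        pet = pet + rng.normal(0.0, spec.pet.noise_level, size=pet.shape)
    return pet


def generate_phantom(spec: PhantomSpec, case_id: str = "phantom") -> PhantomCase:
    """Build one phantom case; fully determined by ``spec`` (incl. its seed)."""
    rng = np.random.default_rng(spec.seed)
    coords = _grid_coords(spec)
    body, lung, tumor = _scene_regions(spec, coords)

    if tumor.any() and np.any(tumor & ~lung):
        raise ValueError("tumor extends outside the lung region; adjust the spec")
    if not tumor.any():
        raise ValueError("tumor is empty on this grid; enlarge it or refine the spacing")

    ct = np.full(spec.grid_shape, -1000.0)
    ct[body] = spec.body_hu_mean
    noise = rng.normal(0.0, 1.0, size=spec.grid_shape)
    ct[body] += spec.body_hu_sd * noise[body]
    ct[lung] = spec.lung_hu_mean + spec.lung_hu_sd * noise[lung]
    ct[tumor] = spec.tumor.hu_mean + spec.tumor.hu_sd * noise[tumor]

    lm_fixed = _default_landmarks(spec, rng)
    _paint_fiducials(ct, coords, lm_fixed, spec.fiducial_radius_mm, spec.fiducial_hu)

    spacing = tuple(spec.spacing)
    ct_vol = Volume(data=ct, spacing=spacing, modality=Modality.CT)
    truth = Mask(data=tumor.astype(np.uint8), spacing=spacing)

    transform = spec.misalignment or RigidTransform.identity()
    if spec.misalignment is None:
        pet = _pet_from_regions(spec, body, tumor, rng)
        pet_vol = Volume(data=pet, spacing=spacing, modality=Modality.PET)
        truth_moving = truth
        lm_moving = lm_fixed.copy()
    else:
        # evaluate the analytic scene at fixed-frame coordinates T(x_moving)
        flat = coords.reshape(3, -1)
        fixed_pts = (transform.rotation @ flat).T + transform.translation
        coords_m = fixed_pts.T.reshape(coords.shape)
        body_m, lung_m, tumor_m = _scene_regions(spec, coords_m)
        pet = _pet_from_regions(spec, body_m, tumor_m, rng)
        pet_vol = Volume(data=pet, spacing=spacing, modality=Modality.PET)
        truth_moving = Mask(data=tumor_m.astype(np.uint8), spacing=spacing)
        lm_moving = transform.inverse().apply_points(lm_fixed)

    return PhantomCase(
        case_id=case_id,
        ct=ct_vol,
        pet=pet_vol,
        truth=truth,
        truth_moving=truth_moving,
        landmarks_fixed=LandmarkSet(lm_fixed, label=f"{case_id}/fixed"),
        landmarks_moving=LandmarkSet(lm_moving, label=f"{case_id}/moving"),
        transform=transform,
        spec=spec,
    )


def generate_cohort(n: int, volume_range_cm3=(0.33, 57.9), seed: int = 0,
                    misalign: bool = True, max_rotation_deg: float = 5.0,
                    max_translation_mm: float = 8.0) -> list[PhantomCase]:
    """A cohort of phantoms with tumor volumes log-uniform over the range.

    Grid spacing adapts to tumor size (~6 voxels across the mean radius,
    clipped to [0.8, 2.0] mm) so small lesions stay resolved; each case
    gets its own seed derived from the master seed, so cohorts are
    reproducible and cases independent.
    """
    if n < 1:
        raise ValueError("cohort size must be >= 1")
    lo, hi = volume_range_cm3
    if not (0 < lo <= hi):
        raise ValueError(f"invalid volume range {volume_range_cm3}")
    master = np.random.default_rng(seed)
    volumes = np.exp(master.uniform(math.log(lo), math.log(hi), size=n))
    cases = []
    for i, vol in enumerate(volumes):
        rng = np.random.default_rng(seed * 100_003 + i * 7919 + 17)
        aniso = rng.uniform(0.75, 1.3, size=3)
        axes = semi_axes_for_volume(float(vol), aniso)
        r_mean = (3.0 * vol * 1000.0 / (4.0 * math.pi)) ** (1.0 / 3.0)
        sp = float(np.clip(r_mean / 6.0, 0.8, 2.0))
        extent = np.array([160.0, 160.0, 160.0])
        grid = tuple(int(round(e / sp)) for e in extent)
        spec = PhantomSpec(grid_shape=grid, spacing=(sp, sp, sp))
        # centre the tumor in the lung with jitter bounded by the free room
        ext = spec.extent_mm
        lung_semi = np.array([0.35 * ext[0], 0.30 * ext[1]])
        room_xy = np.maximum(lung_semi - max(axes) - 3.0, 0.0)
        room_z = max(ext[2] / 2.0 - max(axes) - 3.0, 0.0)
        jitter = rng.uniform(-1.0, 1.0, size=3) * np.array([*(0.5 * room_xy), 0.5 * room_z])
        center = ext / 2.0 + jitter
        tumor = TumorSpec(center_mm=tuple(center), semi_axes_mm=axes,
                          rotation_deg=float(rng.uniform(0.0, 180.0)))
        mis = None
        if misalign:
            mis = random_rigid(rng, max_rotation_deg, max_translation_mm,
                               center_mm=tuple(ext / 2.0))
        spec = replace(spec, tumor=tumor, misalignment=mis,
                       seed=int(rng.integers(0, 2**31 - 1)))
        cases.append(generate_phantom(spec, case_id=f"case{i:03d}"))
    return cases
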