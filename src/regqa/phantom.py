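"""Synthetic thorax phantoms and landmark cohorts.

The image phantom is a layered HU model on an anisotropic grid: air
background (-1000 HU), an elliptic-cylinder body (40 HU) with a posterior
spine rod (700 HU), two lateral lung ellipsoids (-850 HU) and a branching
airway tree of capped cylinders rasterised in world mm whose lumen is
-1000 HU.  A companion PET volume carries focal hot spots.  Misregistered
pairs are produced by resampling the reference volume under a known rigid
transform (trilinear interpolation) with optional extra noise and low-dose
emulation (1.5 mm Gaussian smoothing plus doubled noise, mimicking the
resolution gap between low-dose and diagnostic CT).

The landmark cohort generator draws per-patient large-airway distances from
a lognormal whose median is the patient's latent misalignment and in-lumen
indicators from a Bernoulli whose success probability decays with
misalignment, with NA/NULL codes injected at fixed rates.  All outputs are
bit-reproducible from the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import ValidationError
from .landmarks import LANDMARK_ORDER, LANDMARKS, NA, NULL
from .volume import BinaryMask, ScalarVolume

__all__ = ["AirwayTreeSpec", "HotSpot", "PhantomSpec", "Thorax",
           "make_thorax", "make_pet", "make_misregistered_pair",
           "make_landmark_cohort", "LandmarkCohort"]


@dataclass(frozen=True)
class AirwayTreeSpec:
    """Binary branching tree of capped cylinders, sizes in mm."""

    trachea_length_mm: float = 36.0
    radius_mm: float = 4.0
    branching_depth: int = 1          # 0 = trachea only
    branch_angle_deg: float = 40.0
    length_decay: float = 0.65
    radius_decay: float = 0.7

    def __post_init__(self):
        if self.radius_mm <= 0 or self.trachea_length_mm <= 0:
            raise ValidationError("tree radii and lengths must be positive")
        if self.branching_depth < 0:
            raise ValidationError("branching_depth must be >= 0")


@dataclass(frozen=True)
class HotSpot:
    """Spherical PET uptake focus; centre in world mm (x, y, z)."""

    center_mm: tuple[float, float, float]
    radius_mm: float
    activity: float


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of one synthetic thorax study."""

    shape: tuple[int, int, int] = (48, 56, 56)          # (slice, row, col)
    spacing: tuple[float, float, float] = (2.0, 1.5, 1.5)
    body_hu: float = 40.0
    lung_hu: float = -850.0
    lumen_hu: float = -1000.0
    bone_hu: float = 700.0
    airway: AirwayTreeSpec | None = AirwayTreeSpec()
    hot_spots: tuple[HotSpot, ...] = ()
    pet_background: float = 0.0
    noise_sd: float = 0.0
    seed: int = 0


@dataclass(frozen=True)
class Thorax:
    volume: ScalarVolume
    airway: BinaryMask
    lung: BinaryMask


def _grid_mm(spec: PhantomSpec):
    """Voxel-centre coordinates in mm per array axis (slice, row, col)."""
    axes = [np.arange(n) * s for n, s in zip(spec.shape, spec.spacing)]
    return np.meshgrid(*axes, indexing="ij")


def _extent(spec: PhantomSpec) -> np.ndarray:
    return np.asarray(spec.shape, float) * np.asarray(spec.spacing, float)


def _rasterise_tube(mask, grids, p0, p1, radius):
    """Add a capped cylinder (segment p0->p1, radius, all mm) to ``mask``.

    Points are in (slice, row, col) mm.
    """
    p0, p1 = np.asarray(p0, float), np.asarray(p1, float)
    d = p1 - p0
    L2 = float(d @ d)
    v = [g - c for g, c in zip(grids, p0)]
    t = sum(vi * di for vi, di in zip(v, d)) / max(L2, 1e-12)
    t = np.clip(t, 0.0, 1.0)
    dist2 = sum((vi - t * di) ** 2 for vi, di in zip(v, d))
    mask |= dist2 <= radius ** 2


def _airway_segments(spec: PhantomSpec):
    """Segments ((p0, p1, radius)...) of the tree in (slice, row, col) mm."""
    tree = spec.airway
    ext = _extent(spec)
    top = np.array([0.08 * ext[0], 0.5 * ext[1], 0.5 * ext[2]])
    segments = []

    def grow(p0, direction, length, radius, depth, plane):
        p1 = p0 + length * direction
        segments.append((p0, p1, radius))
        if depth == 0:
            return
        ang = np.deg2rad(tree.branch_angle_deg)
        down = np.array([1.0, 0.0, 0.0])
        # branch within the given plane: 1 = rows, 2 = cols
        for sign in (-1.0, 1.0):
            lateral = np.zeros(3)
            lateral[plane] = sign
            new_dir = np.cos(ang) * down + np.sin(ang) * lateral
            new_dir /= np.linalg.norm(new_dir)
            grow(p1, new_dir, length * tree.length_decay,
                 radius * tree.radius_decay, depth - 1,
                 plane=1 if plane == 2 else 2)

    grow(top, np.array([1.0, 0.0, 0.0]), tree.trachea_length_mm,
         tree.radius_mm, tree.branching_depth, plane=2)
    for p0, p1, r in segments:
        for p in (p0, p1):
            if np.any(p < 0) or np.any(p > ext):
                raise ValidationError(
                    f"airway tree exits the grid at {tuple(p)} mm")
    return segments


def make_thorax(spec: PhantomSpec = PhantomSpec()) -> Thorax:
    """Rasterise the phantom; returns the HU volume and ground-truth masks."""
    grids = _grid_mm(spec)
    ext = _extent(spec)
    center = ext / 2

    values = np.full(spec.shape, -1000.0)

    # body: elliptic cylinder through all slices
    body = (((grids[1] - center[1]) / (0.46 * ext[1])) ** 2
            + ((grids[2] - center[2]) / (0.46 * ext[2])) ** 2) <= 1.0
    values[body] = spec.body_hu

    # spine: posterior rod
    spine = (((grids[1] - 0.82 * ext[1]) ** 2
              + (grids[2] - center[2]) ** 2) <= 6.0 ** 2) & body
    values[spine] = spec.bone_hu

    # lungs: two lateral ellipsoids
    lung = np.zeros(spec.shape, bool)
    for sign in (-1.0, 1.0):
        cx = center[2] + sign * 0.22 * ext[2]
        ell = (((grids[0] - center[0]) / (0.40 * ext[0])) ** 2
               + ((grids[1] - 0.45 * ext[1]) / (0.26 * ext[1])) ** 2
               + ((grids[2] - cx) / (0.17 * ext[2])) ** 2) <= 1.0
        lung |= ell
    lung &= body & ~spine
    values[lung] = spec.lung_hu

    # airway lumen
    airway = np.zeros(spec.shape, bool)
    if spec.airway is not None:
        for p0, p1, r in _airway_segments(spec):
            _rasterise_tube(airway, grids, p0, p1, r)
        values[airway] = spec.lumen_hu

    if spec.noise_sd > 0:
        rng = np.random.default_rng(np.random.SeedSequence((spec.seed, 0)))
        values = values + rng.normal(0.0, spec.noise_sd, spec.shape)

    vol = ScalarVolume(values, spec.spacing, modality="CT")
    return Thorax(volume=vol,
                  airway=BinaryMask(airway, spec.spacing),
                  lung=BinaryMask(lung, spec.spacing))


def make_pet(spec: PhantomSpec) -> ScalarVolume:
    """PET companion on the same grid: background plus spherical hot spots."""
    grids = _grid_mm(spec)
    values = np.full(spec.shape, float(spec.pet_background))
    for spot in spec.hot_spots:
        cx, cy, cz = spot.center_mm              # (x, y, z) mm
        dist2 = ((grids[0] - cz) ** 2 + (grids[1] - cy) ** 2
                 + (grids[2] - cx) ** 2)
        values[dist2 <= spot.radius_mm ** 2] += spot.activity
    return ScalarVolume(values, spec.spacing, modality="PET")


def make_misregistered_pair(spec: PhantomSpec,
                            displacement_mm=0.0,
                            rotation_deg: float = 0.0,
                            extra_noise_sd: float = 0.0,
                            lowdose: bool = False):
    """A (fixed, moving) pair with a known applied rigid misregistration.

    ``displacement_mm`` is a scalar (applied along the row axis) or a
    3-vector per array axis (slice, row, col).  The moving image is the
    fixed one resampled under the transform with trilinear interpolation,
    optionally degraded by low-dose emulation (1.5 mm Gaussian smoothing and
    doubled noise) and independent additive noise.  With zero displacement,
    rotation and noise and ``lowdose=False`` the two volumes are identical.
    """
    thorax = make_thorax(spec)
    fixed = thorax.volume
    displacement = np.asarray(displacement_mm, float)
    if displacement.ndim == 0:
        displacement = np.array([0.0, float(displacement), 0.0])
    if not np.all(np.isfinite(displacement)):
        raise ValidationError("displacement must be finite")

    identity = (not displacement.any() and rotation_deg == 0.0
                and extra_noise_sd == 0.0 and not lowdose)
    if identity:
        return fixed, fixed.with_values(fixed.values.copy()), thorax

    values = fixed.values
    if rotation_deg != 0.0:
        values = ndimage.rotate(values, rotation_deg, axes=(1, 2),
                                reshape=False, order=1, mode="constant",
                                cval=-1000.0)
    if displacement.any():
        shift_vox = displacement / np.asarray(spec.spacing, float)
        values = ndimage.shift(values, shift_vox, order=1, mode="constant",
                               cval=-1000.0)
    noise_sd = extra_noise_sd
    if lowdose:
        sigma_vox = 1.5 / np.asarray(spec.spacing, float)
        values = ndimage.gaussian_filter(values, sigma=sigma_vox)
        noise_sd = 2.0 * extra_noise_sd if extra_noise_sd else 2.0 * spec.noise_sd
    if noise_sd > 0:
        rng = np.random.default_rng(np.random.SeedSequence((spec.seed, 1)))
        values = values + rng.normal(0.0, noise_sd, values.shape)
    moving = fixed.with_values(values)
    return fixed, moving, thorax


# ---------------------------------------------------------------------------
# synthetic landmark cohort

@dataclass(frozen=True)
class LandmarkCohort:
    table: pd.DataFrame               # landmark-table layout
    misalignment_mm: np.ndarray       # latent per-patient misalignment
    quality: np.ndarray               # exp(-misalignment/3), in (0, 1]


def make_landmark_cohort(n_patients: int,
                         misalignment_mm=None,
                         seed: int = 0,
                         na_rate: float = 0.03,
                         null_rate: float = 0.02,
                         distance_sigma: float = 0.4,
                         indicator_scale_mm: float = 2.5) -> LandmarkCohort:
    """Simulate an expert landmark table for ``n_patients`` registrations.

    Each patient carries a latent misalignment m (mm); large-airway
    distances are lognormal with median m (exactly 0 when m = 0) and
    indicators are Bernoulli(exp(-m/indicator_scale_mm)).  NA and NULL are
    injected independently at the given rates.
    """
    if n_patients < 2:
        raise ValidationError("need at least 2 patients")
    for rate in (na_rate, null_rate):
        if not (0 <= rate < 1):
            raise ValidationError(f"invalid missingness rate {rate}")
    rng = np.random.default_rng(seed)
    if misalignment_mm is None:
        m = rng.uniform(0.0, 6.0, n_patients)
    else:
        m = np.broadcast_to(np.asarray(misalignment_mm, float),
                            (n_patients,)).copy()
        if np.any(m < 0):
            raise ValidationError("misalignment must be non-negative")

    rows = []
    for i in range(n_patients):
        row = {}
        for code in LANDMARK_ORDER:
            lm = LANDMARKS[code]
            if lm.is_distance:
                value = 0.0 if m[i] == 0 else float(
                    m[i] * rng.lognormal(0.0, distance_sigma))
                value = round(value, 1)
            else:
                p_in = float(np.exp(-m[i] / indicator_scale_mm))
                value = float(rng.random() < p_in)
            u = rng.random()
            if u < na_rate:
                value = NA
            elif u < na_rate + null_rate:
                value = NULL
            row[code] = value
        rows.append(row)
    table = pd.DataFrame(rows, index=[f"s{i + 1:02d}" for i in range(n_patients)])
    table.index.name = "patient"
    return LandmarkCohort(table=table, misalignment_mm=m,
                          quality=np.exp(-m / 3.0))
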