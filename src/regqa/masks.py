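"""Lung and airway masks used by the beta and gamma masking modes.

The raw lung mask selects the Hounsfield window of airway and parenchyma
(default [-1000, -400] HU) and drops everything connected to the exterior
air (components touching the lateral faces of the volume).  The "functioning
lung-mask" repairs it for use as a registration mask: holes are filled,
discontinuities closed, and the mediastinal gap between the two lung fields
is added slice by slice so the result is a single connected component.  The
extended airway mask grows the segmented airway by a fixed mm distance
(anisotropy-aware Euclidean distance), 10 mm by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.morphology import convex_hull_image

from .errors import EmptyMaskError, ValidationError
from .volume import BinaryMask, ScalarVolume

__all__ = ["MaskRecipe", "lung_mask", "functioning_lung_mask",
           "extended_airway_mask", "apply_mask"]


@dataclass(frozen=True)
class MaskRecipe:
    """Parameters of the mask construction.

    hu_low, hu_high : HU window of lung-like voxels.
    closing_radius_mm : radius of the morphological closing that removes
        discontinuities in the functioning lung-mask.
    airway_extension_mm : thickness of the airway extension (gamma mode).
    min_component_voxels : connected components smaller than this are noise
        and are dropped from the raw lung mask.
    """

    hu_low: float = -1000.0
    hu_high: float = -400.0
    closing_radius_mm: float = 5.0
    airway_extension_mm: float = 10.0
    min_component_voxels: int = 64

    def __post_init__(self):
        if self.hu_low >= self.hu_high:
            raise ValidationError("hu_low must be below hu_high")
        if self.airway_extension_mm <= 0:
            raise ValidationError("airway_extension_mm must be positive")
        if self.closing_radius_mm <= 0:
            raise ValidationError("closing_radius_mm must be positive")


def _ball_footprint(radius_mm: float, spacing) -> np.ndarray:
    """Ellipsoidal (in voxels) structuring element = mm ball on the grid."""
    half = [max(int(np.floor(radius_mm / s)), 0) for s in spacing]
    grids = np.meshgrid(*(np.arange(-h, h + 1) * s
                          for h, s in zip(half, spacing)), indexing="ij")
    dist2 = sum(g * g for g in grids)
    return dist2 <= radius_mm ** 2


_CONN26 = np.ones((3, 3, 3), bool)


def lung_mask(ct: ScalarVolume, recipe: MaskRecipe = MaskRecipe()) -> BinaryMask:
    """Segment lung-like voxels from a CT volume.

    Keeps the connected components of the HU-window selection that do not
    touch the lateral faces of the volume (which excludes the air around the
    patient) and are at least ``min_component_voxels`` large.
    """
    window = (ct.values >= recipe.hu_low) & (ct.values <= recipe.hu_high)
    labels, n = ndimage.label(window, structure=_CONN26)
    if n == 0:
        raise EmptyMaskError("no voxels in the lung HU window")
    # labels present on any of the four lateral faces touch exterior air
    border = np.unique(np.concatenate([
        labels[:, 0, :].ravel(), labels[:, -1, :].ravel(),
        labels[:, :, 0].ravel(), labels[:, :, -1].ravel()]))
    counts = np.bincount(labels.ravel())
    keep = np.ones(n + 1, bool)
    keep[0] = False
    keep[border] = False
    keep[counts < recipe.min_component_voxels] = False
    out = keep[labels]
    if not out.any():
        raise EmptyMaskError(
            "no interior lung-like component survived filtering")
    return BinaryMask(out, ct.spacing, ct.origin)


def functioning_lung_mask(lung: BinaryMask,
                          recipe: MaskRecipe = MaskRecipe()) -> BinaryMask:
    """Repair a lung mask into a single connected registration mask.

    Applies a closing with ``closing_radius_mm``, fills internal cavities,
    then adds the mediastinal voxels by filling, on each axial slice, the
    convex-hull gap between the lung fields.  Every step is extensive, so the
    output is a superset of the input.
    """
    if not lung.values.any():
        raise EmptyMaskError("empty lung mask")
    footprint = _ball_footprint(recipe.closing_radius_mm, lung.spacing)
    # pad so the closing is not clipped by the array border
    pad = [(h, h) for h in ((s - 1) // 2 for s in footprint.shape)]
    padded = np.pad(lung.values, pad)
    closed = ndimage.binary_closing(padded, structure=footprint)
    closed = closed[tuple(slice(a, n - b) for (a, b), n
                          in zip(pad, closed.shape))]
    closed |= lung.values
    out = ndimage.binary_fill_holes(closed)
    # per-slice convex hull, iterated to a fixed point (the discrete hull of
    # a lattice set is not always stable after one pass)
    for k in range(out.shape[0]):
        while out[k].any():
            hull = convex_hull_image(out[k])
            if np.array_equal(hull, out[k]):
                break
            out[k] = hull
    return BinaryMask(out, lung.spacing, lung.origin)


def extended_airway_mask(airway: BinaryMask,
                         extension_mm: float = 10.0) -> BinaryMask:
    """All voxels within ``extension_mm`` (Euclidean mm) of the airway."""
    if extension_mm < 0:
        raise ValidationError("extension_mm must be non-negative")
    if not airway.values.any():
        raise EmptyMaskError("empty airway mask")
    dist = ndimage.distance_transform_edt(~airway.values,
                                          sampling=airway.spacing)
    return BinaryMask(airway.values | (dist <= extension_mm),
                      airway.spacing, airway.origin)


def apply_mask(ct: ScalarVolume, mask: BinaryMask) -> ScalarVolume:
    """Voxelwise product of a volume and a mask (masked intensity image)."""
    if not ct.same_grid(mask):
        raise ValidationError("volume and mask must share one grid")
    return ct.with_values(ct.values * mask.values)
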