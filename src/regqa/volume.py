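"""3-D scalar volumes and binary masks on a common voxel grid.

Arrays are indexed ``(slice, row, column)`` with 0-based indices; ``spacing``
is the voxel size in mm along those same axes (so ``spacing[0]`` is the slice
thickness).  World positions are reported as ``(x, y, z)`` mm where ``x``
runs along columns, ``y`` along rows and ``z`` along slices, i.e. the
conventional radiological axis order reversed relative to the array axes.
CT-like volumes carry Hounsfield units; PET-like volumes arbitrary activity
units.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import SimpleITK as sitk

from .errors import ValidationError

__all__ = ["ScalarVolume", "BinaryMask", "read_volume", "write_volume",
           "read_mask", "write_mask"]


def _check_grid(values: np.ndarray, spacing, origin) -> None:
    if values.ndim != 3:
        raise ValidationError(f"expected a 3-D array, got ndim={values.ndim}")
    if len(spacing) != 3 or any(s <= 0 for s in spacing):
        raise ValidationError(f"spacing must be 3 positive mm values, got {spacing}")
    if len(origin) != 3:
        raise ValidationError(f"origin must have 3 components, got {origin}")


@dataclass(frozen=True)
class ScalarVolume:
    """A 3-D scalar image with anisotropic mm spacing.

    Parameters
    ----------
    values : ndarray, shape (n_slices, n_rows, n_cols)
        Voxel values; must be finite.
    spacing : tuple of float
        Voxel size in mm per array axis (slice, row, column).
    origin : tuple of float
        World position in mm of voxel (0, 0, 0), per array axis.
    modality : {"CT", "PET"}
    """

    values: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    modality: str = "CT"

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        _check_grid(values, self.spacing, self.origin)
        if not np.all(np.isfinite(values)):
            raise ValidationError("volume contains non-finite values")
        if self.modality not in ("CT", "PET"):
            raise ValidationError(f"unknown modality {self.modality!r}")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def same_grid(self, other) -> bool:
        return (self.shape == other.shape
                and np.allclose(self.spacing, other.spacing)
                and np.allclose(self.origin, other.origin))

    def with_values(self, values: np.ndarray, modality: str | None = None) -> "ScalarVolume":
        return replace(self, values=values,
                       modality=self.modality if modality is None else modality)


@dataclass(frozen=True)
class BinaryMask:
    """A {0,1} mask sharing the grid of the volumes it restricts."""

    values: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        values = np.asarray(self.values)
        _check_grid(values, self.spacing, self.origin)
        if values.dtype != bool:
            uniq = np.unique(values)
            if not np.all(np.isin(uniq, (0, 1))):
                raise ValidationError("mask values must be 0/1")
            values = values.astype(bool)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def n_voxels(self) -> int:
        return int(self.values.sum())

    def same_grid(self, other) -> bool:
        return (self.shape == other.shape
                and np.allclose(self.spacing, other.spacing)
                and np.allclose(self.origin, other.origin))

    def with_values(self, values: np.ndarray) -> "BinaryMask":
        return replace(self, values=values)


# ---------------------------------------------------------------------------
# I/O — NIfTI-1 (.nii/.nii.gz) and MetaImage (.mha/.mhd) through SimpleITK.
# SimpleITK arrays come back (z, y, x), which is exactly our (slice, row,
# column) order; its spacing/origin are (x, y, z) and are therefore reversed.

def _from_sitk(img: sitk.Image, modality: str):
    values = sitk.GetArrayFromImage(img)
    spacing = tuple(reversed(img.GetSpacing()))
    origin = tuple(reversed(img.GetOrigin()))
    return values, spacing, origin


def read_volume(path, modality: str = "CT") -> ScalarVolume:
    img = sitk.ReadImage(str(path))
    values, spacing, origin = _from_sitk(img, modality)
    return ScalarVolume(values.astype(float), spacing, origin, modality)


def write_volume(vol: ScalarVolume, path) -> None:
    img = sitk.GetImageFromArray(vol.values)
    img.SetSpacing(tuple(reversed(vol.spacing)))
    img.SetOrigin(tuple(reversed(vol.origin)))
    sitk.WriteImage(img, str(path))


def read_mask(path) -> BinaryMask:
    img = sitk.ReadImage(str(path))
    values, spacing, origin = _from_sitk(img, "CT")
    return BinaryMask(values > 0, spacing, origin)


def write_mask(mask: BinaryMask, path) -> None:
    img = sitk.GetImageFromArray(mask.values.astype(np.uint8))
    img.SetSpacing(tuple(reversed(mask.spacing)))
    img.SetOrigin(tuple(reversed(mask.origin)))
    sitk.WriteImage(img, str(path))
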