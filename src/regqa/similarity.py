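"""Voxel-intensity (dis)similarity between a registered image pair.

Six parameters are computed on the voxels selected by a mask: Pearson
correlation, mutual information (MI), normalised mutual information
(NMI = (H(a)+H(b))/H(a,b), so NMI is in [1, 2]), a directed Kullback-Leibler
divergence (HKL) between the two marginal intensity histograms, the L1 norm
and the squared L2 norm of the voxelwise difference.  MI, NMI and HKL are
measured in nats from a shared equal-width joint histogram.

Three masking modes restrict the support:

* ``alpha`` — no mask, every voxel;
* ``beta``  — one shared "functioning lung-mask" applied to both images;
* ``gamma`` — union of the two per-image 10-mm-extended airway masks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import DegenerateInputError, EmptyMaskError, ValidationError
from .volume import BinaryMask, ScalarVolume

__all__ = ["SimilarityVector", "joint_histogram", "similarity_vector",
           "masked_pair", "METRIC_NAMES"]

METRIC_NAMES = ("pearson", "mi", "nmi", "hkl", "l1norm", "l2norm2")

#: Floor substituted for empty reference bins in the directed KL divergence.
HKL_EPS = 1e-12


@dataclass(frozen=True)
class SimilarityVector:
    """The six (dis)similarity parameters for one masked image pair."""

    pearson: float
    mi: float
    nmi: float
    hkl: float
    l1norm: float
    l2norm2: float
    masking_mode: str = "alpha"
    n_voxels: int = 0

    def as_dict(self) -> dict:
        return {"pearson": self.pearson, "mi": self.mi, "nmi": self.nmi,
                "hkl": self.hkl, "l1norm": self.l1norm,
                "l2norm2": self.l2norm2, "masking_mode": self.masking_mode,
                "n_voxels": self.n_voxels}


def _masked_values(a: ScalarVolume, b: ScalarVolume,
                   mask: BinaryMask | None):
    if mask is not None and not (a.same_grid(mask) and b.same_grid(mask)):
        raise ValidationError("volumes and mask must share one grid")
    if not a.same_grid(b):
        raise ValidationError("the two volumes must share one grid")
    sel = np.ones(a.shape, bool) if mask is None else mask.values
    if sel.sum() < 2:
        raise EmptyMaskError("mask selects fewer than 2 voxels")
    return a.values[sel], b.values[sel]


def _edges(values: np.ndarray, n_bins: int) -> np.ndarray:
    lo, hi = float(values.min()), float(values.max())
    if lo == hi:
        # constant image: centre the single occupied bin
        lo, hi = lo - 0.5, hi + 0.5
    return np.linspace(lo, hi, n_bins + 1)


def joint_histogram(a: ScalarVolume, b: ScalarVolume,
                    mask: BinaryMask | None = None, n_bins: int = 64):
    """Joint intensity histogram over the masked voxels.

    Equal-width bins span each image's own [min, max] over the mask; the top
    edge is inclusive.  Returns ``(counts, edges_a, edges_b)`` with
    ``counts.sum()`` equal to the number of masked voxels.
    """
    if n_bins < 2:
        raise ValidationError(f"n_bins must be >= 2, got {n_bins}")
    x, y = _masked_values(a, b, mask)
    edges_a, edges_b = _edges(x, n_bins), _edges(y, n_bins)
    counts, _, _ = np.histogram2d(x, y, bins=(edges_a, edges_b))
    return counts, edges_a, edges_b


def _entropies(counts: np.ndarray):
    p = counts / counts.sum()
    pa, pb = p.sum(axis=1), p.sum(axis=0)

    def h(q):
        q = q[q > 0]
        return float(-(q * np.log(q)).sum())

    return p, pa, pb, h(pa), h(pb), h(p.ravel())


def similarity_vector(a: ScalarVolume, b: ScalarVolume,
                      mask: BinaryMask | None = None, n_bins: int = 64,
                      masking_mode: str = "alpha") -> SimilarityVector:
    """Compute the six (dis)similarity parameters of a registered pair.

    ``a`` is the reference (diagnostic CT) image and ``b`` the moving
    (registered low-dose CT) image; HKL is directed from ``b``'s marginal
    histogram towards ``a``'s.  Raises :class:`DegenerateInputError` when
    either image is constant on the mask (Pearson undefined).
    """
    x, y = _masked_values(a, b, mask)
    if x.std() == 0 or y.std() == 0:
        raise DegenerateInputError(
            "Pearson correlation undefined: an image is constant on the mask")
    counts, _, _ = joint_histogram(a, b, mask, n_bins)
    p, pa, pb, ha, hb, hab = _entropies(counts)

    nz = p > 0
    outer = np.outer(pa, pb)
    mi = float((p[nz] * np.log(p[nz] / outer[nz])).sum())
    mi = max(mi, 0.0)
    nmi = (ha + hb) / hab if hab > 0 else 2.0

    # directed KL of the moving-image marginal from the reference marginal
    qa = pb.copy()
    sel = pa > 0
    q = np.where(qa[sel] > 0, qa[sel], HKL_EPS)
    hkl = float((pa[sel] * np.log(pa[sel] / q)).sum())
    hkl = max(hkl, 0.0)

    diff = x - y
    pearson = float(np.corrcoef(x, y)[0, 1])
    return SimilarityVector(
        pearson=pearson, mi=mi, nmi=nmi, hkl=hkl,
        l1norm=float(np.abs(diff).sum()),
        l2norm2=float((diff * diff).sum()),
        masking_mode=masking_mode, n_voxels=int(x.size))


def masked_pair(a: ScalarVolume, b: ScalarVolume, mode: str,
                functioning_lung: BinaryMask | None = None,
                airway_ext_a: BinaryMask | None = None,
                airway_ext_b: BinaryMask | None = None) -> BinaryMask:
    """Build the support mask for one masking mode.

    * ``alpha``: all-ones mask (no restriction);
    * ``beta``: the single functioning lung-mask, derived from the reference
      volume and applied identically to both images;
    * ``gamma``: the union of the two per-image 10-mm-extended airway masks
      (each built separately on its own image).
    """
    if not a.same_grid(b):
        raise ValidationError("volumes must share one grid")
    if mode == "alpha":
        return BinaryMask(np.ones(a.shape, bool), a.spacing, a.origin)
    if mode == "beta":
        if functioning_lung is None:
            raise ValidationError("mode beta requires a functioning lung-mask")
        return functioning_lung
    if mode == "gamma":
        if airway_ext_a is None or airway_ext_b is None:
            raise ValidationError(
                "mode gamma requires the two extended airway masks")
        return BinaryMask(airway_ext_a.values | airway_ext_b.values,
                          a.spacing, a.origin)
    raise ValidationError(f"unknown masking mode {mode!r}")
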