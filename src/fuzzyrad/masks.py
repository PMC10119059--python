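"""Delineation variants: reference/extended, binary/fuzzy.

Starting from a clinician-style reference binary mask (Ref-B) the
package derives the three companions used in the four-way comparison:

* ``Ref-F`` — Ref-B convolved with a normalized 3D Gaussian whose FWHM
  equals the imaging system's physical resolution, so the membership
  weights model the partial volume effect at the lesion boundary;
* ``Ext-B`` — Ref-B dilated with a Euclidean ball of 3 voxels radius,
  including the immediate lesion surroundings;
* ``Ext-F`` — the fuzzified Ext-B.

Fuzzification conserves total mask mass for lesions away from the array
border, and never produces weights outside [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import MaskError
from .image_io import FuzzyMask

__all__ = [
    "MaskVariantSet",
    "fwhm_to_sigma",
    "dilate_mask",
    "fuzzify_mask",
    "build_variants",
    "check_min_voxels",
]

#: FWHM = 2 sqrt(2 ln 2) sigma
FWHM_PER_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))

#: Cohort-specific PSF widths (mm) of the three clinical imaging systems.
COHORT_FWHM_MM = {"glioma": 5.0, "lung": 4.7, "prostate": 4.6}

DEFAULT_DILATION_VOXELS = 3
DEFAULT_MIN_VOXELS = 64


@dataclass
class MaskVariantSet:
    """The four delineation variants of one lesion on a common grid."""

    ref_b: FuzzyMask
    ref_f: FuzzyMask
    ext_b: FuzzyMask
    ext_f: FuzzyMask
    fwhm_mm: float
    dilation_voxels: int

    def as_dict(self) -> dict[str, FuzzyMask]:
        return {
            "Ref-B": self.ref_b,
            "Ref-F": self.ref_f,
            "Ext-B": self.ext_b,
            "Ext-F": self.ext_f,
        }


def fwhm_to_sigma(fwhm: float) -> float:
    """Convert a Gaussian full-width-at-half-maximum to its sigma (same units)."""
    if fwhm <= 0:
        raise ValueError(f"FWHM must be positive, got {fwhm}")
    return float(fwhm) / FWHM_PER_SIGMA


def _require_binary(m: FuzzyMask) -> None:
    if not m.is_binary:
        raise MaskError("operation requires a binary mask")


def dilate_mask(m: FuzzyMask, radius_voxels: int = DEFAULT_DILATION_VOXELS) -> FuzzyMask:
    """Morphological dilation with a Euclidean ball of the given voxel radius."""
    _require_binary(m)
    if radius_voxels < 1:
        raise ValueError(f"dilation radius must be >= 1 voxel, got {radius_voxels}")
    r = int(radius_voxels)
    ax = np.arange(-r, r + 1)
    gx, gy, gz = np.meshgrid(ax, ax, ax, indexing="ij")
    ball = (gx**2 + gy**2 + gz**2) <= r**2
    out = ndimage.binary_dilation(m.weights > 0, structure=ball)
    return FuzzyMask(out.astype(np.float64), m.spacing, m.origin, kind="Ext-B")


def fuzzify_mask(
    m: FuzzyMask, fwhm: float, truncate_sigmas: float = 4.0, kind: str = "Ref-F"
) -> FuzzyMask:
    """Convolve a binary mask with a normalized 3D Gaussian of the given FWHM (mm).

    Per-axis sigma in voxel units is ``fwhm_to_sigma(fwhm) / spacing``.
    The separable kernel is truncated at ``truncate_sigmas`` standard
    deviations and renormalized, so constants are preserved and total
    mass is conserved for interior lesions.
    """
    _require_binary(m)
    sigma_mm = fwhm_to_sigma(fwhm)
    sigma_vox = [sigma_mm / s for s in m.spacing]
    out = ndimage.gaussian_filter(
        m.weights, sigma=sigma_vox, mode="constant", cval=0.0, truncate=truncate_sigmas
    )
    return FuzzyMask(np.clip(out, 0.0, 1.0), m.spacing, m.origin, kind=kind)


def build_variants(
    ref_b: FuzzyMask,
    fwhm: float,
    dilation: int = DEFAULT_DILATION_VOXELS,
) -> MaskVariantSet:
    """Derive Ref-F, Ext-B and Ext-F from a reference binary delineation."""
    _require_binary(ref_b)
    if not (ref_b.weights > 0).any():
        raise MaskError("reference mask is empty")
    ref_b = FuzzyMask(ref_b.weights, ref_b.spacing, ref_b.origin, kind="Ref-B")
    ref_f = fuzzify_mask(ref_b, fwhm, kind="Ref-F")
    ext_b = dilate_mask(ref_b, dilation)
    ext_f = fuzzify_mask(ext_b, fwhm, kind="Ext-F")
    return MaskVariantSet(ref_b, ref_f, ext_b, ext_f, float(fwhm), int(dilation))


def check_min_voxels(m: FuzzyMask, threshold: int = DEFAULT_MIN_VOXELS) -> bool:
    """True iff the mask has at least ``threshold`` voxels with weight > 0."""
    return m.foreground_count(0.0) >= threshold
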