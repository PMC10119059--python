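"""Voxel lattices, NIfTI I/O, grid resampling and tumor-to-background normalization.

The two in-memory containers used throughout the package live here:

``VoxelVolume``
    a 3D scalar lattice (PET uptake in SUV or TBR units) with physical
    spacing and origin in millimetres;

``FuzzyMask``
    a delineation on the same lattice whose voxels carry membership
    weights in [0, 1].  Binary masks are the special case with weights
    in {0, 1}; the ``kind`` tag records which of the four delineation
    variants (Ref-B, Ref-F, Ext-B, Ext-F) the mask represents.

Volumes are resampled to the 2 mm isotropic analysis grid with ordinary
kriging (a Gaussian-covariance best linear unbiased interpolator solved
in a 5x5x5-node neighborhood) or with trilinear interpolation, and PET
values are converted to tumor-to-background ratio (TBR) by dividing by
the mean uptake inside a lesion-free background region.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import nibabel as nib
import numpy as np
from scipy import ndimage

from .errors import GridError, LoadError, NormalizationError

__all__ = [
    "VoxelVolume",
    "FuzzyMask",
    "load_volume",
    "save_volume",
    "load_mask",
    "save_mask",
    "resample_volume",
    "resample_mask",
    "tbr_normalize",
]

MASK_KINDS = ("Ref-B", "Ref-F", "Ext-B", "Ext-F", "background", "generic")


def _as_triple(x) -> tuple[float, float, float]:
    t = tuple(float(v) for v in np.atleast_1d(x))
    if len(t) == 1:
        t = t * 3
    if len(t) != 3:
        raise ValueError(f"expected a length-3 vector, got {x!r}")
    return t  # type: ignore[return-value]


@dataclass
class VoxelVolume:
    """A 3D scalar field on a regular lattice.

    World coordinates follow ``origin + index * spacing`` with 0-based
    voxel indices; masks and volumes must share grids exactly.
    """

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    axis_order: str = "index-xyz"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise LoadError(f"volume must be 3D, got shape {self.values.shape}")
        self.spacing = _as_triple(self.spacing)
        self.origin = _as_triple(self.origin)
        if any(s <= 0 for s in self.spacing):
            raise LoadError(f"spacing must be strictly positive, got {self.spacing}")
        if not np.all(np.isfinite(self.values)):
            raise LoadError("volume contains non-finite voxels")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def same_grid(self, other: "VoxelVolume | FuzzyMask") -> bool:
        return (
            self.values.shape == np.asarray(other_values(other)).shape
            and np.allclose(self.spacing, other.spacing)
            and np.allclose(self.origin, other.origin)
        )


def other_values(obj) -> np.ndarray:
    return obj.weights if isinstance(obj, FuzzyMask) else obj.values


@dataclass
class FuzzyMask:
    """Membership-weighted delineation on the same lattice as its volume."""

    weights: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    kind: str = "generic"

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=np.float64)
        if self.weights.ndim != 3:
            raise LoadError(f"mask must be 3D, got shape {self.weights.shape}")
        self.spacing = _as_triple(self.spacing)
        self.origin = _as_triple(self.origin)
        if any(s <= 0 for s in self.spacing):
            raise LoadError(f"spacing must be strictly positive, got {self.spacing}")
        if not np.all(np.isfinite(self.weights)):
            raise LoadError("mask contains non-finite weights")
        if self.weights.size and (self.weights.min() < 0 or self.weights.max() > 1):
            raise LoadError("mask weights must lie in [0, 1]")
        if self.kind not in MASK_KINDS:
            raise ValueError(f"unknown mask kind {self.kind!r}; expected one of {MASK_KINDS}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.weights.shape  # type: ignore[return-value]

    @property
    def is_binary(self) -> bool:
        return bool(np.all((self.weights == 0) | (self.weights == 1)))

    def foreground_count(self, epsilon: float = 0.0) -> int:
        return int(np.count_nonzero(self.weights > epsilon))


def _affine(spacing, origin) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    aff[:3, 3] = origin
    return aff


def load_volume(path) -> VoxelVolume:
    """Load a 3D NIfTI volume, validating dimensionality and finiteness."""
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(), dtype=np.float64)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise LoadError(f"{path}: expected a 3D volume, got shape {data.shape}")
    zooms = img.header.get_zooms()[:3]
    if any(not np.isfinite(z) or z <= 0 for z in zooms):
        raise LoadError(f"{path}: missing or invalid voxel spacing {zooms}")
    if not np.all(np.isfinite(data)):
        raise LoadError(f"{path}: volume contains NaN/Inf voxels")
    origin = tuple(float(v) for v in np.asarray(img.affine)[:3, 3])
    return VoxelVolume(data, tuple(float(z) for z in zooms), origin)


def save_volume(v: VoxelVolume, path) -> None:
    nib.save(nib.Nifti1Image(v.values, _affine(v.spacing, v.origin)), str(path))


def load_mask(path, kind: str = "generic") -> FuzzyMask:
    vol = load_volume(path)
    return FuzzyMask(np.clip(vol.values, 0.0, 1.0), vol.spacing, vol.origin, kind=kind)


def save_mask(m: FuzzyMask, path) -> None:
    nib.save(nib.Nifti1Image(m.weights, _affine(m.spacing, m.origin)), str(path))


# ---------------------------------------------------------------------------
# Resampling
# ---------------------------------------------------------------------------

_KRIGING_RANGE = 1.25  # Gaussian covariance range, input-voxel units
_KRIGING_NUGGET = 1e-10
_HALF = 2  # 5^3 neighborhood -> half-width 2


def _output_grid(shape, spacing, target):
    """Output node counts covering the input's physical voxel extent."""
    n_out = tuple(
        max(1, int(np.ceil(shape[a] * spacing[a] / target[a]))) for a in range(3)
    )
    return n_out


def _kriging_weights(frac: np.ndarray) -> np.ndarray:
    """Ordinary-kriging weights for a query at fractional offset ``frac``
    (input-index units, per axis in [-0.5, 0.5]) from the nearest node,
    using the 5^3 surrounding nodes and a Gaussian covariance."""
    ax = np.arange(-_HALF, _HALF + 1, dtype=np.float64)
    gx, gy, gz = np.meshgrid(ax, ax, ax, indexing="ij")
    nodes = np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1)  # (125, 3)
    d2 = np.sum((nodes[:, None, :] - nodes[None, :, :]) ** 2, axis=2)
    cov = np.exp(-d2 / _KRIGING_RANGE**2)
    n = nodes.shape[0]
    k = np.empty((n + 1, n + 1))
    k[:n, :n] = cov + _KRIGING_NUGGET * np.eye(n)
    k[n, :n] = 1.0
    k[:n, n] = 1.0
    k[n, n] = 0.0
    rhs = np.empty(n + 1)
    rhs[:n] = np.exp(-np.sum((nodes - frac[None, :]) ** 2, axis=1) / _KRIGING_RANGE**2)
    rhs[n] = 1.0
    try:
        lam = np.linalg.solve(k, rhs)[:n]
    except np.linalg.LinAlgError:
        lam = np.linalg.lstsq(k, rhs, rcond=None)[0][:n]
    return lam


def _resample_values(
    values: np.ndarray, spacing, target, method: str
) -> tuple[np.ndarray, tuple[int, int, int]]:
    n_out = _output_grid(values.shape, spacing, target)
    # output node a*target in world units -> input index a*target/spacing
    coords = [np.arange(n_out[a]) * target[a] / spacing[a] for a in range(3)]
    ix, iy, iz = np.meshgrid(*coords, indexing="ij")
    if method == "trilinear":
        out = ndimage.map_coordinates(
            values, np.stack([ix, iy, iz]), order=1, mode="nearest"
        )
        return out, n_out
    if method != "kriging":
        raise ValueError(f"unknown resampling method {method!r}")

    pos = np.stack([ix.ravel(), iy.ravel(), iz.ravel()], axis=1)
    nearest = np.rint(pos).astype(np.int64)
    frac = pos - nearest
    # snap path: queries coinciding with input nodes are copied exactly
    # (the nugget would otherwise break node-exactness)
    on_node = np.all(np.abs(frac) < 1e-9, axis=1)
    out = np.empty(pos.shape[0])
    pad = np.pad(values, _HALF, mode="edge")
    clamp = lambda idx, a: np.clip(idx, 0, values.shape[a] - 1)  # noqa: E731
    if on_node.any():
        nn = nearest[on_node]
        out[on_node] = values[
            clamp(nn[:, 0], 0), clamp(nn[:, 1], 1), clamp(nn[:, 2], 2)
        ]
    off = ~on_node
    if off.any():
        frac_off = np.round(frac[off], 9)
        uniq, inv = np.unique(frac_off, axis=0, return_inverse=True)
        base = nearest[off] + _HALF  # index into padded array
        for a in range(3):
            base[:, a] = np.clip(base[:, a], _HALF, values.shape[a] - 1 + _HALF)
        acc = np.zeros(base.shape[0])
        offs = [
            (i, j, kk)
            for i in range(-_HALF, _HALF + 1)
            for j in range(-_HALF, _HALF + 1)
            for kk in range(-_HALF, _HALF + 1)
        ]
        lam_by_group = np.stack([_kriging_weights(u) for u in uniq])  # (G, 125)
        for m, (i, j, kk) in enumerate(offs):
            vals = pad[base[:, 0] + i, base[:, 1] + j, base[:, 2] + kk]
            acc += lam_by_group[inv, m] * vals
        out[off] = acc
    return out.reshape(n_out), n_out


def resample_volume(
    v: VoxelVolume, target_spacing, method: str = "kriging"
) -> VoxelVolume:
    """Resample a volume onto a grid with the given spacing.

    The output grid shares the input origin and covers the input's
    physical extent.  ``method`` is ``"kriging"`` (ordinary kriging,
    Gaussian covariance, 5^3 neighborhood) or ``"trilinear"``.
    """
    target = _as_triple(target_spacing)
    if any(t <= 0 for t in target):
        raise ValueError(f"target spacing must be positive, got {target}")
    if v.values.size == 0:
        raise LoadError("cannot resample an empty volume")
    out, _ = _resample_values(v.values, v.spacing, target, method)
    return VoxelVolume(out, target, v.origin)


def resample_mask(
    m: FuzzyMask, target_spacing, method: str = "kriging"
) -> FuzzyMask:
    """Resample a mask with the same operator as the volume.

    Fuzzy weights are clamped back to [0, 1]; binary masks are
    re-thresholded at 0.5 so the output stays binary.
    """
    binary = m.is_binary
    target = _as_triple(target_spacing)
    out, _ = _resample_values(m.weights, m.spacing, target, method)
    out = np.clip(out, 0.0, 1.0)
    if binary:
        out = (out >= 0.5).astype(np.float64)
    return FuzzyMask(out, target, m.origin, kind=m.kind)


# ---------------------------------------------------------------------------
# TBR normalization
# ---------------------------------------------------------------------------


def tbr_normalize(v: VoxelVolume, background: FuzzyMask) -> VoxelVolume:
    """Divide every voxel by the mean uptake inside the background mask.

    Output units are tumor-to-background ratio (dimensionless).  The
    operation commutes with uniform rescaling of the volume and is
    idempotent: after one pass the background mean is exactly 1.
    """
    if not v.same_grid(background):
        raise GridError("background mask grid does not match the volume grid")
    sel = background.weights > 0
    if not sel.any():
        raise NormalizationError("background mask is empty")
    mean = float(v.values[sel].mean())
    if mean <= 0:
        raise NormalizationError(f"background mean must be positive, got {mean}")
    return replace(v, values=v.values / mean)
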