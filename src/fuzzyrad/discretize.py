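"""Fixed-bin-size intensity discretization under membership weights.

A voxel belongs to the lesion when its membership weight exceeds the
inclusion threshold ``epsilon``; discretization and all neighborhood
definitions operate on that included set.  Grey levels are assigned by
fixed bin size on the TBR scale::

    level = floor((x - min_included) / bin_width) + 1

so levels start at 1 and the number of levels N_g is the level of the
maximum included intensity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DiscretizationError, GridError
from .image_io import FuzzyMask, VoxelVolume

__all__ = ["DiscretizedLesion", "discretize_intensities", "DEFAULT_BIN_WIDTH", "DEFAULT_EPSILON"]

DEFAULT_BIN_WIDTH = 0.1  # TBR units
DEFAULT_EPSILON = 1e-3


@dataclass
class DiscretizedLesion:
    """A lesion cropped to its bounding box, binned and weighted.

    ``levels`` holds the integer grey level of each included voxel and 0
    outside the included set; ``weights`` holds the membership of each
    included voxel and 0 elsewhere.  ``values``/``flat_weights`` are the
    raw TBR intensities and memberships of the included voxels, in scan
    order, for first-order statistics.
    """

    levels: np.ndarray  # int32, 0 = excluded
    weights: np.ndarray  # float64, 0 outside the included set
    values: np.ndarray  # raw intensities of included voxels (1D)
    flat_weights: np.ndarray  # memberships of included voxels (1D)
    n_levels: int
    bin_width: float
    spacing: tuple[float, float, float]
    no_variation: bool

    @property
    def total_mass(self) -> float:
        """Total membership mass of the included voxels."""
        return float(self.flat_weights.sum())


def discretize_intensities(
    v: VoxelVolume,
    m: FuzzyMask,
    bin_width: float = DEFAULT_BIN_WIDTH,
    epsilon: float = DEFAULT_EPSILON,
) -> DiscretizedLesion:
    """Bin the intensities of the voxels with membership > ``epsilon``."""
    if bin_width <= 0:
        raise ValueError(f"bin width must be positive, got {bin_width}")
    if not v.same_grid(m):
        raise GridError("mask grid does not match the volume grid")
    included = m.weights > epsilon
    if not included.any():
        raise DiscretizationError("no voxel exceeds the membership threshold")

    # crop to bounding box with a 1-voxel margin so neighborhood
    # operators see the excluded border
    idx = np.argwhere(included)
    lo = np.maximum(idx.min(axis=0) - 1, 0)
    hi = np.minimum(idx.max(axis=0) + 2, included.shape)
    sl = tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))
    inc = included[sl]
    vals = v.values[sl]
    w = np.where(inc, m.weights[sl], 0.0)

    vmin = vals[inc].min()
    levels = np.zeros(inc.shape, dtype=np.int32)
    levels[inc] = np.floor((vals[inc] - vmin) / bin_width).astype(np.int32) + 1
    n_levels = int(levels.max())
    return DiscretizedLesion(
        levels=levels,
        weights=w,
        values=vals[inc].astype(np.float64),
        flat_weights=w[inc],
        n_levels=n_levels,
        bin_width=float(bin_width),
        spacing=v.spacing,
        no_variation=n_levels == 1,
    )
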