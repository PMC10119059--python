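"""Shared fixtures: small random lesions and cohort builders."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from fuzzyrad import FuzzyMask, PhantomSpec, VoxelVolume

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def make_random_lesion(rng, shape=(12, 12, 12), spacing=(2.0, 2.0, 2.0),
                       n_levels_hint=6, fuzzy=False):
    """A small random blob lesion with textured intensities.

    Returns (VoxelVolume, FuzzyMask).  The mask is an ellipsoid-ish blob
    of >= ~60 voxels; ``fuzzy`` adds random membership weights.
    """
    center = np.array(shape) / 2.0
    radii = rng.uniform(0.28, 0.42, size=3) * np.array(shape)
    grids = np.meshgrid(*[np.arange(n) for n in shape], indexing="ij")
    ell = sum(((g - c) / r) ** 2 for g, c, r in zip(grids, center, radii))
    support = ell <= 1.0
    values = rng.normal(4.0, 0.0, size=shape)
    values += rng.integers(0, n_levels_hint, size=shape) * 0.11  # coarse texture
    values += rng.normal(0, 0.01, size=shape)  # break ties
    if fuzzy:
        w = np.where(support, rng.uniform(0.1, 1.0, size=shape), 0.0)
    else:
        w = support.astype(float)
    return (
        VoxelVolume(values, spacing),
        FuzzyMask(w, spacing),
    )


@pytest.fixture
def lesion_factory(rng):
    def factory(**kw):
        return make_random_lesion(rng, **kw)

    return factory


@pytest.fixture
def small_spec():
    """A compact phantom spec for fast unit tests."""
    return PhantomSpec(
        lesion_count=12,
        lesion_radius_range=(5.0, 9.0),
        psf_fwhm=4.0,
        label_effect_size=1.0,
        minority_fraction=0.4,
        seed=11,
    )
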