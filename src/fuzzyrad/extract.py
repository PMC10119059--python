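"""Per-lesion feature extraction through the membership-weighted path."""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .discretize import DEFAULT_BIN_WIDTH, DEFAULT_EPSILON, discretize_intensities
from .errors import MaskError
from .image_io import FuzzyMask, VoxelVolume
from .intensity import intensity_histogram_features, weighted_intensity_statistics
from .manifest import FeatureDef, default_manifest
from .masks import DEFAULT_MIN_VOXELS, check_min_voxels
from .morphology import compute_morphology
from .texture import (
    build_fuzzy_glcm,
    build_fuzzy_glrlm,
    build_fuzzy_glszm,
    build_fuzzy_ngtdm,
    glcm_features,
    glrlm_features,
    glszm_features,
    ngtdm_features,
)

__all__ = ["EngineConfig", "FeatureVector", "extract_features"]


@dataclass
class EngineConfig:
    """Tunable parameters of the extraction engine.

    ``bin_width`` is in TBR units; ``epsilon`` is the membership below
    which a voxel is outside the lesion; the pair/run/zone schemes set
    how memberships enter the texture matrices.
    """

    bin_width: float = DEFAULT_BIN_WIDTH
    epsilon: float = DEFAULT_EPSILON
    modality: str = "PET"
    min_voxels: int = DEFAULT_MIN_VOXELS
    glcm_symmetric: bool = True
    glcm_pair_scheme: str = "product"
    run_zone_scheme: str = "mean"
    manifest: list[FeatureDef] | None = None

    def resolve_manifest(self) -> list[FeatureDef]:
        return self.manifest if self.manifest is not None else default_manifest(self.modality)


@dataclass
class FeatureVector:
    """Named feature values in manifest order plus per-feature validity."""

    values: dict[str, float]
    invalid: frozenset[str]
    no_variation: bool = False

    def to_series(self) -> pd.Series:
        return pd.Series(self.values, dtype=float)

    @property
    def names(self) -> list[str]:
        return list(self.values)

    def __len__(self) -> int:
        return len(self.values)


def extract_features(
    v: VoxelVolume, m: FuzzyMask, config: EngineConfig | None = None
) -> FeatureVector:
    """Extract the configured feature list (default 153 features).

    Every feature is computed through the weighted path; a binary mask
    therefore reproduces classic radiomics exactly.  Degenerate
    features (undefined denominators, missing 0.5-isosurface, single
    grey level) are returned as NaN and listed in ``invalid``.
    """
    config = config or EngineConfig()
    if not check_min_voxels(m, config.min_voxels):
        raise MaskError(
            f"mask has fewer than {config.min_voxels} foreground voxels"
        )
    manifest = config.resolve_manifest()
    mod = config.modality

    raw: dict[str, float] = {}
    raw.update({f"{mod}_{k}": x for k, x in compute_morphology(m).items()})

    d = discretize_intensities(v, m, config.bin_width, config.epsilon)
    raw.update(
        {f"{mod}_{k}": x for k, x in
         weighted_intensity_statistics(d.values, d.flat_weights).items()}
    )
    raw.update(
        {f"{mod}_{k}": x for k, x in
         intensity_histogram_features(d.levels[d.levels > 0], d.weights[d.levels > 0],
                                      d.n_levels).items()}
    )
    for agg in ("avg", "mrg"):
        cm = build_fuzzy_glcm(
            d, symmetric=config.glcm_symmetric, aggregation=agg,
            pair_scheme=config.glcm_pair_scheme,
        )
        raw.update(
            {f"{mod}_cm_{k}_3d_{agg}": x for k, x in glcm_features(cm).items()}
        )
        rlm = build_fuzzy_glrlm(d, aggregation=agg, run_scheme=config.run_zone_scheme)
        raw.update(
            {f"{mod}_rlm_{k}_3d_{agg}": x for k, x in glrlm_features(rlm).items()}
        )
    szm = build_fuzzy_glszm(d, zone_scheme=config.run_zone_scheme)
    raw.update({f"{mod}_szm_{k}": x for k, x in glszm_features(szm).items()})
    s, n = build_fuzzy_ngtdm(d)
    raw.update({f"{mod}_ngt_{k}": x for k, x in ngtdm_features(s, n).items()})

    values: dict[str, float] = {}
    invalid: set[str] = set()
    for fd in manifest:
        x = raw.get(fd.name, math.nan)
        if not math.isfinite(x):
            invalid.add(fd.name)
            x = math.nan
        values[fd.name] = float(x)
    return FeatureVector(values, frozenset(invalid), no_variation=d.no_variation)
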