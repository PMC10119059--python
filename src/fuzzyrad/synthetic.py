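"""Synthetic PET-like lesion phantoms and labeled cohorts.

No clinical cohort ships with the package; this module generates
phantoms with the statistical structure the pipeline assumes so every
downstream stage is testable end to end:

* blob-like lesions — axis-perturbed ellipsoids rasterized on the
  2 mm analysis grid — with a spatially correlated intra-lesion
  intensity texture (stationary Gaussian random field obtained by
  smoothing white noise; the smoothing length sets the correlation
  length);
* system blur by an isotropic Gaussian point-spread function of
  configurable FWHM, plus additive Gaussian noise;
* a lesion-free background shell, two voxels thick and at least three
  PSF widths away from the lesion, used as the TBR denominator;
* binary class labels whose association with the lesion-level mean
  uptake and texture contrast is controlled by a standardized effect
  size (0 = pure null);
* patient grouping with a configurable number of lesions per patient
  (prostate-like cohorts have several).

Cohort generation is a pure function of the spec (including its seed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import DegenerateSpecError
from .image_io import FuzzyMask, VoxelVolume
from .masks import fwhm_to_sigma

__all__ = ["PhantomSpec", "LesionSample", "generate_lesion_phantom", "generate_cohort", "write_cohort"]

_MAX_REGEN = 50


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of a synthetic cohort.

    Physical quantities are in millimetres / TBR units.  The label
    effect size is the standardized shift of the lesion-level mean
    uptake and texture contrast between the two classes; zero gives a
    cohort with no class signal.
    """

    lesion_count: int = 84
    voxel_spacing: tuple[float, float, float] = (2.0, 2.0, 2.0)
    lesion_radius_range: tuple[float, float] = (6.0, 14.0)
    texture_granularity: float = 6.0
    psf_fwhm: float = 5.0
    noise_sd: float = 0.05
    label_effect_size: float = 1.0
    minority_fraction: float = 0.39
    lesions_per_patient: int | tuple[int, int] = 1
    seed: int = 0
    base_tbr_mean: float = 4.0
    base_tbr_sd: float = 0.8
    contrast_mean: float = 0.8
    contrast_sd: float = 0.15
    axis_jitter: float = 0.2

    def __post_init__(self) -> None:
        if self.lesion_count < 1:
            raise ValueError("lesion_count must be positive")
        if any(s <= 0 for s in self.voxel_spacing):
            raise ValueError("voxel spacing must be strictly positive")
        lo, hi = self.lesion_radius_range
        if lo <= 0 or hi < lo:
            raise ValueError("lesion radius range must be positive and ordered")
        if self.texture_granularity <= 0:
            raise ValueError("texture granularity must be strictly positive")
        if self.psf_fwhm < 0 or self.noise_sd < 0:
            raise ValueError("PSF FWHM and noise SD must be non-negative")
        if not (0 < self.minority_fraction <= 0.5):
            raise ValueError("minority fraction must lie in (0, 0.5]")


@dataclass
class LesionSample:
    """One lesion: uptake volume, reference mask, background, metadata."""

    lesion_id: str
    patient_id: str
    label: int
    volume: VoxelVolume
    ref_b: FuzzyMask
    background: FuzzyMask
    true_volume_mm3: float


def _texture_field(shape, spacing, granularity, rng):
    noise = rng.standard_normal(shape)
    sigma_vox = [granularity / s for s in spacing]
    f = ndimage.gaussian_filter(noise, sigma=sigma_vox, mode="reflect")
    sd = f.std()
    if sd == 0:
        return np.zeros(shape)
    return (f - f.mean()) / sd


def generate_lesion_phantom(
    spec: PhantomSpec, class_label: int, rng: np.random.Generator
) -> tuple[VoxelVolume, FuzzyMask, FuzzyMask]:
    """One ellipsoid lesion with textured uptake, PSF blur and noise.

    Returns the uptake volume, the pre-blur binary lesion support
    (Ref-B) and the lesion-free background shell.
    """
    sp = spec.voxel_spacing
    lo, hi = spec.lesion_radius_range
    r_mean = rng.uniform(lo, hi)
    radii = r_mean * rng.uniform(1 - spec.axis_jitter, 1 + spec.axis_jitter, size=3)

    shell_lo = max(3.0 * spec.psf_fwhm, 4.0)
    shell_hi = shell_lo + 2.0 * max(sp)
    half = radii.max() + shell_hi + 2.0 * max(sp)
    shape = tuple(int(np.ceil(2 * half / s)) + 1 for s in sp)
    center = [(n - 1) / 2.0 * s for n, s in zip(shape, sp)]
    grids = np.meshgrid(
        *[np.arange(n) * s - c for n, s, c in zip(shape, sp, center)], indexing="ij"
    )
    ell = sum((g / r) ** 2 for g, r in zip(grids, radii))
    support = ell <= 1.0
    if not support.any():
        raise DegenerateSpecError(
            f"lesion radii {radii} produce no voxel at spacing {sp}"
        )

    # lesion-level parameters, shifted between classes by the effect size
    eff = spec.label_effect_size * int(class_label)
    mean_tbr = rng.normal(spec.base_tbr_mean + eff * spec.base_tbr_sd, spec.base_tbr_sd)
    mean_tbr = max(mean_tbr, 1.5)
    contrast = rng.normal(spec.contrast_mean + eff * spec.contrast_sd, spec.contrast_sd)
    contrast = max(contrast, 0.05)

    tex = _texture_field(shape, sp, spec.texture_granularity, rng)
    img = np.ones(shape)
    img[support] = mean_tbr + contrast * tex[support]
    if spec.psf_fwhm > 0:
        sigma_vox = [fwhm_to_sigma(spec.psf_fwhm) / s for s in sp]
        img = ndimage.gaussian_filter(img, sigma=sigma_vox, mode="nearest")
    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, size=shape)

    dist = ndimage.distance_transform_edt(~support, sampling=sp)
    shell = (dist >= shell_lo) & (dist < shell_hi)

    vol = VoxelVolume(img, sp)
    ref_b = FuzzyMask(support.astype(np.float64), sp, kind="Ref-B")
    background = FuzzyMask(shell.astype(np.float64), sp, kind="background")
    return vol, ref_b, background


def _patient_layout(spec: PhantomSpec, rng: np.random.Generator) -> list[int]:
    """Number of lesions per patient, totalling exactly lesion_count."""
    lpp = spec.lesions_per_patient
    sizes: list[int] = []
    remaining = spec.lesion_count
    while remaining > 0:
        if isinstance(lpp, int):
            k = lpp
        else:
            k = int(rng.integers(lpp[0], lpp[1] + 1))
        k = min(max(1, k), remaining)
        sizes.append(k)
        remaining -= k
    return sizes


def generate_cohort(
    spec: PhantomSpec, min_voxels: int = 64
) -> tuple[list[LesionSample], pd.DataFrame]:
    """A full labeled cohort of lesion phantoms.

    Labels are assigned at patient level (all lesions of a patient
    share the label); the minority lesion count matches
    ``round(minority_fraction * lesion_count)`` to within one lesion.
    Lesions whose support falls below ``min_voxels`` are regenerated.
    """
    master = np.random.SeedSequence(spec.seed)
    layout_rng = np.random.default_rng(master.spawn(1)[0])
    sizes = _patient_layout(spec, layout_rng)

    n_minority = int(round(spec.minority_fraction * spec.lesion_count))
    # assign patient labels so minority lesion count lands within +-1
    order = layout_rng.permutation(len(sizes))
    labels_by_patient = np.zeros(len(sizes), dtype=int)
    acc = 0
    for pi in order:
        if acc >= n_minority:
            break
        labels_by_patient[pi] = 1
        acc += sizes[pi]

    samples: list[LesionSample] = []
    rows = []
    lesion_seeds = master.spawn(spec.lesion_count + 1)[1:]
    li = 0
    for pi, size in enumerate(sizes):
        patient_id = f"P{pi:04d}"
        label = int(labels_by_patient[pi])
        for _ in range(size):
            rng = np.random.default_rng(lesion_seeds[li])
            for attempt in range(_MAX_REGEN):
                vol, ref_b, background = generate_lesion_phantom(spec, label, rng)
                if ref_b.foreground_count() >= min_voxels:
                    break
            else:
                raise DegenerateSpecError(
                    f"could not draw a lesion with >= {min_voxels} voxels"
                )
            lesion_id = f"L{li:04d}"
            true_vol = ref_b.foreground_count() * vol.voxel_volume_mm3
            samples.append(
                LesionSample(lesion_id, patient_id, label, vol, ref_b, background, true_vol)
            )
            rows.append(
                {
                    "lesion_id": lesion_id,
                    "patient_id": patient_id,
                    "label": label,
                    "true_volume_mm3": true_vol,
                }
            )
            li += 1
    return samples, pd.DataFrame(rows)


def write_cohort(samples: list[LesionSample], table: pd.DataFrame, outdir) -> None:
    """Write NIfTI volume/mask/background triplets plus the CSV label table."""
    from pathlib import Path

    from .image_io import save_mask, save_volume

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    for s in samples:
        save_volume(s.volume, out / f"{s.lesion_id}_pet.nii.gz")
        save_mask(s.ref_b, out / f"{s.lesion_id}_refb.nii.gz")
        save_mask(s.background, out / f"{s.lesion_id}_bg.nii.gz")
    table.to_csv(out / "labels.csv", index=False)
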