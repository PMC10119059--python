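"""Extract the 153-feature vector through the membership-weighted path.

Compares a binary and a fuzzy delineation of the same lesion: the
fuzzy mask down-weights boundary voxels the way the scanner's point
spread function mixes them with background, which shifts intensity and
texture features.
"""

import numpy as np

from fuzzyrad import (
    EngineConfig,
    PhantomSpec,
    build_variants,
    extract_features,
    generate_lesion_phantom,
    tbr_normalize,
)

spec = PhantomSpec(lesion_count=1, lesion_radius_range=(9.0, 9.0), seed=3)
rng = np.random.default_rng(3)
volume, ref_b, background = generate_lesion_phantom(spec, class_label=0, rng=rng)
tbr = tbr_normalize(volume, background)
variants = build_variants(ref_b, fwhm=5.0)

fv_binary = extract_features(tbr, variants.ref_b, EngineConfig())
fv_fuzzy = extract_features(tbr, variants.ref_f, EngineConfig())
print(f"features per lesion: {len(fv_binary)} (binary) / {len(fv_fuzzy)} (fuzzy)")

show = [
    "PET_stat_mean", "PET_stat_var", "PET_ih_entropy",
    "PET_cm_contrast_3d_avg", "PET_ngt_coarseness", "PET_morph_vol_count",
]
print(f"{'feature':28s} {'Ref-B':>10s} {'Ref-F':>10s}")
for name in show:
    print(f"{name:28s} {fv_binary.values[name]:10.4f} {fv_fuzzy.values[name]:10.4f}")
# The weighted volume is identical for both masks: PSF-matched
# smoothing redistributes membership without creating or destroying
# it.  Variance and texture contrast rise for the fuzzy mask because
# partially-included boundary voxels now contribute fractionally.
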