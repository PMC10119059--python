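"""Generate one PET-like lesion phantom and its four delineation variants.

Builds a synthetic lesion (textured ellipsoid, PSF blur, noise,
background shell), normalizes it to tumor-to-background ratio, and
derives the Ref-F / Ext-B / Ext-F masks from the reference binary one.
"""

import numpy as np

from fuzzyrad import (
    PhantomSpec,
    build_variants,
    generate_lesion_phantom,
    tbr_normalize,
)

spec = PhantomSpec(lesion_count=1, lesion_radius_range=(8.0, 12.0), seed=7)
rng = np.random.default_rng(7)
volume, ref_b, background = generate_lesion_phantom(spec, class_label=1, rng=rng)
tbr = tbr_normalize(volume, background)

print(f"lesion support: {ref_b.foreground_count()} voxels "
      f"({ref_b.foreground_count() * volume.voxel_volume_mm3:.0f} mm^3)")
print(f"mean TBR inside lesion: {tbr.values[ref_b.weights > 0].mean():.2f} "
      "(background is 1.0 by construction)")

variants = build_variants(ref_b, fwhm=5.0, dilation=3)
for name, mask in variants.as_dict().items():
    print(f"{name:6s} support {mask.foreground_count(1e-3):5d} voxels, "
          f"membership mass {mask.weights.sum():8.1f}")
# Ref-F conserves the mass of Ref-B (Gaussian smoothing redistributes,
# it does not create or destroy membership); Ext-* are supersets.
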