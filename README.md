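# fuzzyrad

Membership-weighted ("fuzzy") IBSI radiomics for PET, with the full
four-delineation comparison pipeline and a synthetic phantom cohort
generator.

## The problem

Radiomics quantifies a delineated lesion with intensity, texture and
shape features. Conventional pipelines use a **binary** volume of
interest: a voxel is in or out. In PET this is a poor model at lesion
boundaries, where the scanner's point spread function (FWHM ≈ 4.6–5
mm) mixes tumor and background signal, and where manual delineations
are least certain. **Fuzzy radiomics** keeps the IBSI feature formulas
but lets every voxel carry a membership weight w ∈ [0, 1] — e.g. a
delineation smoothed by a Gaussian matched to the system PSF — so the
partial volume effect is modelled inside the feature computation
itself. With a {0, 1} mask the weighted formulas reduce *exactly* to
classic radiomics.

The package is for imaging scientists who want to (a) extract
weighted IBSI-style features from NIfTI volumes and masks, and (b)
compare delineation strategies the way delineation studies do:
four mask variants per lesion —

| variant | construction |
|---|---|
| Ref-B | the reference binary delineation |
| Ref-F | Ref-B ⊛ Gaussian(FWHM = system resolution) |
| Ext-B | Ref-B dilated by a 3-voxel Euclidean ball |
| Ext-F | Ext-B ⊛ the same Gaussian |

— feature tables per variant, cross-variant harmonization, Spearman
redundancy reduction (|ρ| ≥ 0.9 clusters, keep the highest-variance
member), and a harmonized 100-fold Monte-Carlo cross-validation with
exactly class-balanced test sets, patient-level leakage control,
SMOTE training balance, univariate R² feature ranking with the budget
f = ⌈√(0.9·2·M)⌉ (M = majority-class count), and a fixed 5-voter
ensemble (4 random forests + 1 class-conditional multi-Gaussian,
majority vote).

No clinical data ships with the package: a phantom module generates
PET-like cohorts (textured ellipsoid lesions, PSF blur, noise,
background shells for TBR normalization, patient grouping, and a
controllable label effect size) so every stage is testable end to
end. See `docs/methods.md` for the model details and their
assumptions.

## Worked example

Extract binary and fuzzy features for one phantom lesion
(`examples/02_fuzzy_features.py`):

```text
features per lesion: 153 (binary) / 153 (fuzzy)
feature                           Ref-B      Ref-F
PET_stat_mean                    3.1282     2.8058
PET_stat_var                     0.3305     0.8099
PET_ih_entropy                   4.3494     4.8854
PET_cm_contrast_3d_avg          29.7057    33.3156
PET_ngt_coarseness               6.8600    11.8103
PET_morph_vol_count           3064.0000  3064.0000
```

Each lesion yields the same 153 named features for every mask
variant. The weighted voxel volume (`morph_vol_count`) is identical
for Ref-B and Ref-F because PSF-matched smoothing conserves
membership mass; intensity variance and texture contrast rise under
the fuzzy mask because partially-included boundary voxels now
contribute fractionally instead of being cut off.

The full comparison (`examples/04_full_experiment.py`, a scaled-down
30-lesion / 25-fold run) prints per-delineation cross-validation
summaries:

```text
delineation  features_original  features_harmonized  features_redundancy_reduced  features_selected
      Ref-B                153                  152                           18                  6
      Ref-F                153                  152                           10                  6
      Ext-B                153                  152                           14                  6
      Ext-F                153                  152                           11                  6

Ref-B  mean CV AUC 0.640 [0.475, 0.805]  ACC 0.620
Ref-F  mean CV AUC 0.780 [0.666, 0.894]  ACC 0.740  ANOVA p vs Ref-B: 0.178
Ext-B  mean CV AUC 0.580 [0.404, 0.756]  ACC 0.600  ANOVA p vs Ref-B: 0.628
Ext-F  mean CV AUC 0.780 [0.652, 0.908]  ACC 0.760  ANOVA p vs Ref-B: 0.195
```

On this run both fuzzy variants beat their binary counterparts by
~0.14 AUC — the injected class effect survives the PSF-matched soft
boundary better than the crisp one — while the ANOVA p-values show
the 25-fold sample is too small to call the difference significant.
With `label_effect_size=0` the same pipeline hovers around 0.5. A
larger post-reduction feature count means the delineation produced
less mutually redundant information; on these single-texture-factor
phantoms the fuzzy tables are *more* internally correlated than the
binary ones (see `docs/methods.md` for why this differs from clinical
reports).

The same pipeline is scriptable from the shell:

```sh
fuzzyrad simulate --lesions 84 --seed 0 --out cohort/
fuzzyrad build-masks --ref-mask cohort/L0000_refb.nii.gz --fwhm-mm 5 --out masks/
fuzzyrad extract --volume cohort/L0000_pet.nii.gz --mask masks/Ref_F.nii.gz \
         --background cohort/L0000_bg.nii.gz --out features.csv
fuzzyrad run-all --lesions 84 --n-folds 100 --seed 0 --out run/
```

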