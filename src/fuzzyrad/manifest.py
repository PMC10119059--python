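"""The feature manifest: names, families and weight-scaling classes.

The default manifest enumerates the 153 features extracted per lesion:
9 morphology, 18 intensity statistics, 23 intensity histogram, 25 GLCM
in two aggregations (matrix-averaged over the 13 unique 3D directions,
and merged), 16 GLRLM in the same two aggregations, 16 GLSZM and 5
NGTDM features.  Names follow ``<modality>_<family>_<id>`` with IBSI-
style identifiers, e.g. ``PET_cm_contrast_3d_avg``.

Each entry carries a scaling class describing how the feature responds
to multiplying every mask weight by a constant c in (0, 1]:

* ``intensive`` — invariant (normalized matrices, weighted moments);
* ``extensive`` — proportional to c (total-mass quantities);
* ``geometric`` — tied to the 0.5-level set of the mask, neither.

The manifest is editable: trim or reorder it and the extraction engine
emits exactly the listed features in the listed order.
"""

from __future__ import annotations

from dataclasses import dataclass

from .intensity import intensity_histogram_features, weighted_intensity_statistics  # noqa: F401
from .morphology import MORPH_NAMES

__all__ = ["FeatureDef", "default_manifest", "save_manifest", "load_manifest"]


@dataclass(frozen=True)
class FeatureDef:
    name: str  # full name including modality prefix
    family: str  # morph | stat | ih | glcm | glrlm | glszm | ngtdm
    scaling: str  # intensive | extensive | geometric


_STAT_NAMES = (
    "mean", "var", "skew", "kurt", "median", "min", "p10", "p90", "max",
    "iqr", "range", "mad", "rmad", "medad", "cov", "qcod", "energy", "rms",
)
_IH_NAMES = (
    "mean", "var", "skew", "kurt", "median", "min", "p10", "p90", "max",
    "mode", "iqr", "range", "mad", "rmad", "medad", "cov", "qcod",
    "entropy", "uniformity", "max_grad", "max_grad_g", "min_grad", "min_grad_g",
)
_GLCM_NAMES = (
    "joint_max", "joint_avg", "joint_var", "joint_entr", "diff_avg",
    "diff_var", "diff_entr", "sum_avg", "sum_var", "sum_entr", "energy",
    "contrast", "dissimilarity", "inv_diff", "inv_diff_norm", "inv_diff_mom",
    "inv_diff_mom_norm", "inv_var", "corr", "auto_corr", "clust_tend",
    "clust_shade", "clust_prom", "info_corr1", "info_corr2",
)
_GLRLM_NAMES = (
    "sre", "lre", "lgre", "hgre", "srlge", "srhge", "lrlge", "lrhge",
    "glnu", "glnu_norm", "rlnu", "rlnu_norm", "r_perc", "gl_var",
    "rl_var", "rl_entr",
)
_GLSZM_NAMES = (
    "sze", "lze", "lgze", "hgze", "szlge", "szhge", "lzlge", "lzhge",
    "glnu", "glnu_norm", "zsnu", "zsnu_norm", "z_perc", "gl_var",
    "zs_var", "zs_entr",
)
_NGTDM_NAMES = ("coarseness", "contrast", "busyness", "complexity", "strength")

_EXTENSIVE = {
    ("stat", "energy"),
    ("glrlm", "glnu"),
    ("glrlm", "rlnu"),
    ("glszm", "glnu"),
    ("glszm", "zsnu"),
}


def default_manifest(modality: str = "PET") -> list[FeatureDef]:
    """The default 153-entry feature manifest."""
    out: list[FeatureDef] = []
    for name in MORPH_NAMES:
        scaling = "extensive" if name == "morph_vol_count" else "geometric"
        out.append(FeatureDef(f"{modality}_{name}", "morph", scaling))
    for n in _STAT_NAMES:
        scaling = "extensive" if ("stat", n) in _EXTENSIVE else "intensive"
        out.append(FeatureDef(f"{modality}_stat_{n}", "stat", scaling))
    for n in _IH_NAMES:
        out.append(FeatureDef(f"{modality}_ih_{n}", "ih", "intensive"))
    for agg in ("3d_avg", "3d_mrg"):
        for n in _GLCM_NAMES:
            out.append(FeatureDef(f"{modality}_cm_{n}_{agg}", "glcm", "intensive"))
    for agg in ("3d_avg", "3d_mrg"):
        for n in _GLRLM_NAMES:
            scaling = "extensive" if ("glrlm", n) in _EXTENSIVE else "intensive"
            out.append(FeatureDef(f"{modality}_rlm_{n}_{agg}", "glrlm", scaling))
    for n in _GLSZM_NAMES:
        scaling = "extensive" if ("glszm", n) in _EXTENSIVE else "intensive"
        out.append(FeatureDef(f"{modality}_szm_{n}", "glszm", scaling))
    for n in _NGTDM_NAMES:
        out.append(FeatureDef(f"{modality}_ngt_{n}", "ngtdm", "intensive"))
    return out


def save_manifest(manifest: list[FeatureDef], path) -> None:
    """Write a manifest as tab-separated ``name family scaling`` lines."""
    with open(path, "w") as fh:
        fh.write("# fuzzyrad feature manifest: name<TAB>family<TAB>scaling\n")
        for fd in manifest:
            fh.write(f"{fd.name}\t{fd.family}\t{fd.scaling}\n")


def load_manifest(path) -> list[FeatureDef]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            name, family, scaling = line.split("\t")
            out.append(FeatureDef(name, family, scaling))
    return out
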