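"""Per-delineation feature tables, cross-delineation harmonization and
Spearman redundancy reduction.

A cohort yields four tables (Ref-B, Ref-F, Ext-B, Ext-F) over the same
lesions.  Harmonization enforces the comparison contract: a feature
that is unusable in any one table (invalid everywhere, or without
variation) is dropped from all four, and a lesion with any remaining
invalid value in any table is dropped from all four, iterated to the
fixed point so the result does not depend on rule order.

Redundancy reduction builds the graph whose edges connect feature pairs
with |Spearman rho| >= the threshold, takes connected components as
redundant clusters, and keeps exactly the highest-variance feature of
each cluster (ties broken by name), so surviving features from
different clusters are pairwise below the threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .errors import HarmonizationError

__all__ = [
    "FeatureTable",
    "build_feature_table",
    "validate_and_harmonize",
    "reduce_redundancy",
]

META_COLUMNS = ("lesion_id", "patient_id", "label", "lesion_volume_mm3")

DEFAULT_RHO_THRESHOLD = 0.9


@dataclass
class FeatureTable:
    """Lesions x features for one delineation variant.

    ``data`` holds one row per lesion indexed by ``lesion_id`` with the
    metadata columns followed by the feature columns; ``valid`` is a
    boolean frame aligned with the feature columns.
    """

    data: pd.DataFrame
    delineation: str
    valid: pd.DataFrame | None = None
    dropped_features: list[str] = field(default_factory=list)
    clusters: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.data.index.name != "lesion_id":
            if "lesion_id" in self.data.columns:
                self.data = self.data.set_index("lesion_id")
            else:
                raise ValueError("feature table needs a lesion_id index or column")
        if not self.data.index.is_unique:
            raise ValueError("lesion_ids must be unique")
        if self.valid is None:
            self.valid = self.data[self.feature_names].notna() & np.isfinite(
                self.data[self.feature_names]
            )

    @property
    def feature_names(self) -> list[str]:
        return [c for c in self.data.columns if c not in META_COLUMNS]

    @property
    def features(self) -> pd.DataFrame:
        return self.data[self.feature_names]

    @property
    def labels(self) -> pd.Series:
        return self.data["label"].astype(int)

    def select(self, lesion_ids=None, features=None) -> "FeatureTable":
        data = self.data
        valid = self.valid
        if lesion_ids is not None:
            data = data.loc[list(lesion_ids)]
            valid = valid.loc[list(lesion_ids)]
        if features is not None:
            keep_meta = [c for c in data.columns if c in META_COLUMNS]
            data = data[keep_meta + list(features)]
            valid = valid[list(features)]
        return FeatureTable(data.copy(), self.delineation, valid.copy(),
                            list(self.dropped_features), dict(self.clusters))


def build_feature_table(
    feature_vectors, meta: pd.DataFrame, delineation: str
) -> FeatureTable:
    """Assemble per-lesion feature vectors into a table.

    ``feature_vectors`` maps lesion_id -> FeatureVector; ``meta`` has
    columns lesion_id, patient_id, label and lesion volume (either
    ``lesion_volume_mm3`` or ``true_volume_mm3``).
    """
    meta = meta.copy()
    if "lesion_volume_mm3" not in meta.columns and "true_volume_mm3" in meta.columns:
        meta = meta.rename(columns={"true_volume_mm3": "lesion_volume_mm3"})
    rows = {lid: fv.to_series() for lid, fv in feature_vectors.items()}
    feats = pd.DataFrame(rows).T
    feats.index.name = "lesion_id"
    meta = meta.set_index("lesion_id").loc[feats.index]
    data = pd.concat([meta[["patient_id", "label", "lesion_volume_mm3"]], feats], axis=1)
    valid = pd.DataFrame(
        [[name not in fv.invalid and np.isfinite(fv.values[name])
          for name in feats.columns] for lid, fv in feature_vectors.items()],
        index=feats.index, columns=feats.columns,
    )
    return FeatureTable(data, delineation, valid)


def _zero_variance(col: pd.Series, valid: pd.Series) -> bool:
    # "no variation" needs at least two valid values to be assessable
    vals = col[valid]
    return len(vals) >= 2 and bool(np.nanmax(vals) == np.nanmin(vals))


def validate_and_harmonize(tables: list[FeatureTable]) -> list[FeatureTable]:
    """Apply the cross-delineation feature- and lesion-drop rules.

    Iterates (a) drop features that, in any table, are invalid for every
    lesion or constant over their valid values; (b) drop lesions with
    any invalid remaining value in any table; until stable.
    """
    names = tables[0].feature_names
    for t in tables[1:]:
        if t.feature_names != names:
            raise HarmonizationError("tables must share an identical column manifest")
    ids = set(tables[0].data.index)
    for t in tables[1:]:
        if set(t.data.index) != ids:
            raise HarmonizationError("tables must cover the same lesions")

    keep_features = list(names)
    keep_ids = list(tables[0].data.index)
    while True:
        changed = False
        # rule (a): feature unusable in any table
        bad_features = set()
        for t in tables:
            sub = t.data.loc[keep_ids, keep_features]
            val = t.valid.loc[keep_ids, keep_features]
            for f in keep_features:
                if f in bad_features:
                    continue
                if not val[f].any() or _zero_variance(sub[f], val[f]):
                    bad_features.add(f)
        if bad_features:
            keep_features = [f for f in keep_features if f not in bad_features]
            changed = True
        if not keep_features:
            raise HarmonizationError("harmonization removed every feature")
        # rule (b): lesion with any invalid cell in any table
        bad_ids = set()
        for t in tables:
            val = t.valid.loc[keep_ids, keep_features]
            bad_ids |= set(val.index[~val.all(axis=1)])
        if bad_ids:
            keep_ids = [i for i in keep_ids if i not in bad_ids]
            changed = True
        if not keep_ids:
            raise HarmonizationError("harmonization removed every lesion")
        if not changed:
            break

    out = []
    for t in tables:
        sel = t.select(keep_ids, keep_features)
        sel.dropped_features = [f for f in names if f not in keep_features]
        out.append(sel)
    return out


def reduce_redundancy(
    t: FeatureTable, rho_threshold: float = DEFAULT_RHO_THRESHOLD
) -> FeatureTable:
    """Keep one highest-variance representative per redundant cluster.

    Clusters are connected components of the |Spearman rho| >=
    threshold graph; variance is computed on the raw feature values.
    Idempotent, and never increases the feature count.
    """
    feats = t.features
    if len(feats) < 3:
        raise ValueError("Spearman correlation needs at least 3 lesions")
    names = list(feats.columns)
    if len(names) < 2:
        return t.select(features=names)
    x = feats.to_numpy(dtype=float)
    rho = stats.spearmanr(x, axis=0).statistic
    if np.ndim(rho) == 0:  # scipy collapses the 2-feature case to a scalar
        rho = np.array([[1.0, float(rho)], [float(rho), 1.0]])
    adj = (np.abs(rho) >= rho_threshold).astype(np.int8)
    np.fill_diagonal(adj, 0)
    n_comp, comp = connected_components(csr_matrix(adj), directed=False)

    variances = feats.var(axis=0, ddof=1)
    keep = []
    clusters: dict[str, list[str]] = {}
    for c in range(n_comp):
        members = [names[i] for i in range(len(names)) if comp[i] == c]
        # highest variance wins; ties broken by name for determinism
        best = max(members, key=lambda f: (variances[f], f))
        keep.append(best)
        clusters[best] = members
    keep = [f for f in names if f in set(keep)]  # preserve manifest order
    out = t.select(features=keep)
    out.clusters = clusters
    out.dropped_features = [f for f in names if f not in set(keep)]
    return out
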