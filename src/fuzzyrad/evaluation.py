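"""Confusion-matrix analytics, ROC/AUC, ANOVA comparison and the
volume-percentile aggregate analysis.

Per-fold AUC uses the rank-based (Mann-Whitney) estimator with
half-credit for tied vote scores.  Cross-validation summaries report
the mean per-fold AUC with a normal-approximation 95% CI
(mean +- 1.96 SD / sqrt(n_folds)), a pooled-score AUC for the ROC
curve, and pooled confusion metrics.  Delineations are compared by
one-way ANOVA of per-fold AUCs, reference-binary versus each
alternative.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "confusion_metrics",
    "compute_auc",
    "fold_metrics",
    "aggregate_cv",
    "anova_compare",
    "volume_percentile_accuracy",
    "volume_to_voxels",
    "COMMON_VOLUME_RANGE_MM3",
]

#: Common lesion-volume range (mm^3) of the aggregate analysis; closed bounds.
COMMON_VOLUME_RANGE_MM3 = (938.0, 354_987.0)


def confusion_metrics(tp: int, tn: int, fp: int, fn: int) -> dict[str, float]:
    """SNS/SPC/PPV/NPV/ACC and balanced accuracy from a confusion matrix.

    Zero-denominator metrics are returned as NaN (undefined), never 0.
    """
    if min(tp, tn, fp, fn) < 0 or tp + tn + fp + fn == 0:
        raise ValueError("counts must be non-negative and not all zero")
    div = lambda a, b: a / b if b > 0 else math.nan  # noqa: E731
    sns = div(tp, tp + fn)
    spc = div(tn, tn + fp)
    return {
        "SNS": sns,
        "SPC": spc,
        "PPV": div(tp, tp + fp),
        "NPV": div(tn, tn + fn),
        "ACC": (tp + tn) / (tp + tn + fp + fn),
        "BACC": (sns + spc) / 2.0,
    }


def compute_auc(scores, labels) -> float:
    """Rank-based AUC (Mann-Whitney) with half-credit for ties."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs both classes")
    ranks = stats.rankdata(s)
    u = ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def fold_metrics(predictions: pd.DataFrame) -> pd.DataFrame:
    """Per-fold confusion counts and AUC from pooled prediction rows.

    ``predictions`` has columns fold_id, true, predicted, vote_score.
    """
    rows = []
    for fold_id, grp in predictions.groupby("fold_id", sort=True):
        t = grp["true"].to_numpy()
        p = grp["predicted"].to_numpy()
        tp = int(((t == 1) & (p == 1)).sum())
        tn = int(((t == 0) & (p == 0)).sum())
        fp = int(((t == 0) & (p == 1)).sum())
        fn = int(((t == 1) & (p == 0)).sum())
        rows.append(
            {
                "fold_id": fold_id, "TP": tp, "TN": tn, "FP": fp, "FN": fn,
                "AUC": compute_auc(grp["vote_score"], t),
                **confusion_metrics(tp, tn, fp, fn),
            }
        )
    return pd.DataFrame(rows).set_index("fold_id")


@dataclass
class CVSummary:
    mean_auc: float
    auc_ci: tuple[float, float]
    pooled_auc: float
    pooled_metrics: dict[str, float]
    per_fold: pd.DataFrame


def aggregate_cv(predictions: pd.DataFrame) -> CVSummary:
    """Cross-validation summary over >= 2 folds."""
    per_fold = fold_metrics(predictions)
    if len(per_fold) < 2:
        raise ValueError("need at least two folds")
    aucs = per_fold["AUC"].to_numpy()
    mean = float(aucs.mean())
    half = 1.96 * float(aucs.std(ddof=1)) / math.sqrt(len(aucs))
    t = predictions["true"].to_numpy()
    p = predictions["predicted"].to_numpy()
    tp = int(((t == 1) & (p == 1)).sum())
    tn = int(((t == 0) & (p == 0)).sum())
    fp = int(((t == 0) & (p == 1)).sum())
    fn = int(((t == 1) & (p == 0)).sum())
    return CVSummary(
        mean_auc=mean,
        auc_ci=(mean - half, mean + half),
        pooled_auc=compute_auc(predictions["vote_score"], t),
        pooled_metrics=confusion_metrics(tp, tn, fp, fn),
        per_fold=per_fold,
    )


def anova_compare(auc_sets: dict[str, np.ndarray], reference: str = "Ref-B") -> dict[str, float]:
    """One-way ANOVA p-values: reference delineation vs each other one.

    Groups with zero variance in both members give p = 1 by convention.
    """
    ref = np.asarray(auc_sets[reference], dtype=float)
    out = {}
    for name, vals in auc_sets.items():
        if name == reference:
            continue
        v = np.asarray(vals, dtype=float)
        if len(v) != len(ref):
            raise ValueError("harmonized folds required: AUC lists must be equal length")
        if np.ptp(ref) == 0 and np.ptp(v) == 0:
            out[name] = 1.0
            continue
        out[name] = float(stats.f_oneway(ref, v).pvalue)
    return out


def volume_to_voxels(volume_mm3: float, spacing=(2.0, 2.0, 2.0)) -> int:
    """Whole-voxel equivalent of a physical volume at the given spacing."""
    return int(volume_mm3 / float(np.prod(spacing)))


def volume_percentile_accuracy(
    predictions: pd.DataFrame,
    volumes: pd.Series,
    range_mm3: tuple[float, float] = COMMON_VOLUME_RANGE_MM3,
    n_clusters: int = 10,
) -> pd.DataFrame:
    """Correct-classification counts per volume-percentile cluster.

    Lesions are restricted to the closed common volume range; decile
    boundaries come from the restricted volume distribution; boundary
    lesions fall into the lower decile.  Returns one row per
    (delineation, decile) with the number of lesions and of correct
    pooled test classifications, plus the per-decile AUC when both
    classes are present.
    """
    lo, hi = range_mm3
    vol = volumes.loc[predictions["lesion_id"]].to_numpy(dtype=float)
    in_range = (vol >= lo) & (vol <= hi)
    if not in_range.any():
        raise ValueError("no lesion falls inside the volume range")
    sub = predictions.iloc[np.flatnonzero(in_range)].copy()
    v = vol[in_range]
    edges = np.percentile(v, np.linspace(0, 100, n_clusters + 1))
    # right-closed bins; boundary values join the lower decile
    dec = np.searchsorted(edges[1:-1], v, side="left") + 1
    sub["decile"] = dec
    rows = []
    for (delin, d), grp in sub.groupby(["delineation", "decile"], sort=True):
        t = grp["true"].to_numpy()
        correct = int((t == grp["predicted"].to_numpy()).sum())
        try:
            auc = compute_auc(grp["vote_score"], t)
        except ValueError:
            auc = math.nan
        rows.append(
            {
                "delineation": delin,
                "decile": int(d),
                "n": len(grp),
                "correct": correct,
                "auc": auc,
            }
        )
    return pd.DataFrame(rows)
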