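"""Membership-weighted first-order features: intensity statistics and
intensity histogram.

Every formula uses the membership weights as frequency weights with the
total mass as denominator (population forms), so a mask containing only
weights of 1.0 reproduces the classic unweighted definitions exactly.
Weighted quantiles follow the inverse-empirical-CDF rule: the q-quantile
is the smallest value whose cumulative weight reaches q times the total
mass, which with unit weights coincides with ``np.percentile(...,
method="inverted_cdf")``.

Features that are undefined for a given lesion (e.g. coefficient of
variation at zero mean) are returned as NaN; the extraction layer flags
them invalid rather than dropping them.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "weighted_quantile",
    "weighted_intensity_statistics",
    "intensity_histogram_features",
]

_Q_TOL = 1e-12


def weighted_quantile(values: np.ndarray, weights: np.ndarray, q: float) -> float:
    """Smallest value whose cumulative weight reaches ``q`` of the total."""
    order = np.argsort(values, kind="stable")
    v = np.asarray(values, dtype=np.float64)[order]
    w = np.asarray(weights, dtype=np.float64)[order]
    cw = np.cumsum(w)
    total = cw[-1]
    if total <= 0:
        raise ValueError("total weight must be positive")
    pos = np.searchsorted(cw, q * total - _Q_TOL, side="left")
    pos = min(pos, len(v) - 1)
    return float(v[pos])


def weighted_intensity_statistics(values, weights) -> dict[str, float]:
    """The 18 intensity-statistics features under frequency weights."""
    x = np.asarray(values, dtype=np.float64)
    w = np.asarray(weights, dtype=np.float64)
    total = w.sum()
    if total <= 0:
        raise ValueError("total weight must be positive")

    mu = float((w * x).sum() / total)
    var = float((w * (x - mu) ** 2).sum() / total)
    sd = np.sqrt(var)
    if var > 0:
        skew = float((w * (x - mu) ** 3).sum() / total / sd**3)
        kurt = float((w * (x - mu) ** 4).sum() / total / var**2) - 3.0
    else:
        skew = 0.0
        kurt = 0.0

    q = lambda p: weighted_quantile(x, w, p)  # noqa: E731
    p10, p25, median, p75, p90 = q(0.10), q(0.25), q(0.50), q(0.75), q(0.90)
    xmin, xmax = float(x.min()), float(x.max())

    mad = float((w * np.abs(x - mu)).sum() / total)
    # robust MAD: restrict to the closed [P10, P90] band
    band = (x >= p10) & (x <= p90)
    wb, xb = w[band], x[band]
    if wb.sum() > 0:
        mu_b = float((wb * xb).sum() / wb.sum())
        rmad = float((wb * np.abs(xb - mu_b)).sum() / wb.sum())
    else:
        rmad = np.nan
    medad = float((w * np.abs(x - median)).sum() / total)
    cov = sd / mu if mu != 0 else np.nan
    qcod = (p75 - p25) / (p75 + p25) if (p75 + p25) != 0 else np.nan

    return {
        "stat_mean": mu,
        "stat_var": var,
        "stat_skew": skew,
        "stat_kurt": kurt,
        "stat_median": median,
        "stat_min": xmin,
        "stat_p10": p10,
        "stat_p90": p90,
        "stat_max": xmax,
        "stat_iqr": p75 - p25,
        "stat_range": xmax - xmin,
        "stat_mad": mad,
        "stat_rmad": rmad,
        "stat_medad": medad,
        "stat_cov": cov,
        "stat_qcod": qcod,
        "stat_energy": float((w * x**2).sum()),
        "stat_rms": float(np.sqrt((w * x**2).sum() / total)),
    }


def intensity_histogram_features(levels, weights, n_levels: int) -> dict[str, float]:
    """The 23 intensity-histogram features on binned grey levels.

    ``levels``/``weights`` are the per-voxel grey levels (1..N_g) and
    memberships of the included voxels.  The histogram gradient is taken
    on the mass-normalized histogram so the feature is invariant under
    uniform weight scaling.
    """
    g = np.asarray(levels, dtype=np.int64)
    w = np.asarray(weights, dtype=np.float64)
    total = w.sum()
    if total <= 0 or n_levels < 1:
        raise ValueError("histogram requires positive total weight and N_g >= 1")
    mass = np.bincount(g, weights=w, minlength=n_levels + 1)[1:]
    p = mass / total
    lev = np.arange(1, n_levels + 1, dtype=np.float64)

    mu = float((p * lev).sum())
    var = float((p * (lev - mu) ** 2).sum())
    sd = np.sqrt(var)
    if var > 0:
        skew = float((p * (lev - mu) ** 3).sum() / sd**3)
        kurt = float((p * (lev - mu) ** 4).sum() / var**2) - 3.0
    else:
        skew, kurt = 0.0, 0.0

    gq = lambda q: weighted_quantile(lev, p, q)  # noqa: E731
    p10, p25, median, p75, p90 = gq(0.10), gq(0.25), gq(0.50), gq(0.75), gq(0.90)
    present = np.flatnonzero(mass > 0) + 1
    gmin, gmax = float(present.min()), float(present.max())
    mode = float(np.argmax(mass) + 1)  # lowest level on ties

    mad = float((p * np.abs(lev - mu)).sum())
    band = (lev >= p10) & (lev <= p90)
    pb = p[band]
    if pb.sum() > 0:
        mu_b = float((pb * lev[band]).sum() / pb.sum())
        rmad = float((pb * np.abs(lev[band] - mu_b)).sum() / pb.sum())
    else:
        rmad = np.nan
    medad = float((p * np.abs(lev - median)).sum())
    cov = sd / mu if mu != 0 else np.nan
    qcod = (p75 - p25) / (p75 + p25) if (p75 + p25) != 0 else np.nan

    pos = p[p > 0]
    entropy = float(-(pos * np.log2(pos)).sum())
    uniformity = float((pos**2).sum())

    if n_levels == 1:
        grad = np.zeros(1)
    else:
        grad = np.empty(n_levels)
        grad[0] = p[1] - p[0]
        grad[-1] = p[-1] - p[-2]
        if n_levels > 2:
            grad[1:-1] = (p[2:] - p[:-2]) / 2.0
    gmax_i = int(np.argmax(grad))
    gmin_i = int(np.argmin(grad))

    return {
        "ih_mean": mu,
        "ih_var": var,
        "ih_skew": skew,
        "ih_kurt": kurt,
        "ih_median": median,
        "ih_min": gmin,
        "ih_p10": p10,
        "ih_p90": p90,
        "ih_max": gmax,
        "ih_mode": mode,
        "ih_iqr": p75 - p25,
        "ih_range": gmax - gmin,
        "ih_mad": mad,
        "ih_rmad": rmad,
        "ih_medad": medad,
        "ih_cov": cov,
        "ih_qcod": qcod,
        "ih_entropy": entropy,
        "ih_uniformity": uniformity,
        "ih_max_grad": float(grad[gmax_i]),
        "ih_max_grad_g": float(gmax_i + 1),
        "ih_min_grad": float(grad[gmin_i]),
        "ih_min_grad_g": float(gmin_i + 1),
    }
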