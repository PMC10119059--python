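"""Membership-weighted texture matrices and their features.

The four families keep the classic IBSI feature formulas; the only
change is how voxels enter the intermediate matrices:

* GLCM — a co-occurring voxel pair contributes the *product* of its two
  membership weights (configurable to the arithmetic mean);
* GLRLM — a run contributes the *mean* membership of its member voxels
  (configurable to the product);
* GLSZM — a connected zone likewise contributes its mean membership;
* NGTDM — each voxel's absolute deviation from the membership-weighted
  mean level of its included neighbors is itself weighted by the
  voxel's membership, and the per-level occurrence masses are sums of
  memberships.

With all weights equal to 1.0 every matrix reduces exactly to its
classic integer-count form, so binary masks reproduce classic
radiomics.  NGTDM ratio features use occurrence-mass-normalized
deviations (s_i / N) so that they are invariant under uniform scaling
of all weights; for NGTDM contrast and complexity this coincides with
the standard printed formulas.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "FuzzyTextureMatrix",
    "DIRECTIONS_3D",
    "build_fuzzy_glcm",
    "build_fuzzy_glrlm",
    "build_fuzzy_glszm",
    "build_fuzzy_ngtdm",
    "glcm_features",
    "glrlm_features",
    "glszm_features",
    "ngtdm_features",
]

#: The 13 unique 3D direction offsets (one per axis pair, no opposites).
DIRECTIONS_3D: tuple[tuple[int, int, int], ...] = tuple(
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) > (0, 0, 0)
)

_COARSENESS_CAP = 1e6


@dataclass
class FuzzyTextureMatrix:
    """A normalized texture matrix plus the scalars its features need.

    ``p`` is the normalized matrix (rows indexed by grey level from 1).
    ``ns`` is the total matrix mass before normalization — for the
    matrix-averaged aggregation, the mean per-direction mass.  ``nv``
    is the total membership mass of the included voxels and
    ``n_directions`` the number of directions merged (1 for
    direction-free families).
    """

    kind: str  # "GLCM" | "GLRLM" | "GLSZM" | "NGTDM"
    p: np.ndarray
    ns: float
    nv: float
    aggregation: str  # "avg" | "mrg" | "single"
    n_directions: int = 1
    degenerate: bool = False


def _shifted_pairs(shape, d):
    """Index slices selecting (voxel, voxel+d) pairs inside the array."""
    src, dst = [], []
    for n, step in zip(shape, d):
        if step == 0:
            src.append(slice(None))
            dst.append(slice(None))
        elif step > 0:
            src.append(slice(0, n - step))
            dst.append(slice(step, n))
        else:
            src.append(slice(-step, n))
            dst.append(slice(0, n + step))
    return tuple(src), tuple(dst)


def build_fuzzy_glcm(
    d,
    directions=DIRECTIONS_3D,
    symmetric: bool = True,
    aggregation: str = "avg",
    pair_scheme: str = "product",
) -> FuzzyTextureMatrix:
    """Grey-level co-occurrence matrix with membership-weighted pairs."""
    ng = d.n_levels
    levels, w = d.levels, d.weights
    per_dir = []
    for off in directions:
        s_src, s_dst = _shifted_pairs(levels.shape, off)
        ga, gb = levels[s_src], levels[s_dst]
        wa, wb = w[s_src], w[s_dst]
        valid = (ga > 0) & (gb > 0)
        if not valid.any():
            per_dir.append(None)
            continue
        if pair_scheme == "product":
            pw = wa[valid] * wb[valid]
        elif pair_scheme == "mean":
            pw = 0.5 * (wa[valid] + wb[valid])
        else:
            raise ValueError(f"unknown pair scheme {pair_scheme!r}")
        mat = np.zeros((ng, ng))
        np.add.at(mat, (ga[valid] - 1, gb[valid] - 1), pw)
        if symmetric:
            mat = mat + mat.T
        per_dir.append(mat)

    live = [m for m in per_dir if m is not None and m.sum() > 0]
    if not live:
        return FuzzyTextureMatrix("GLCM", np.zeros((ng, ng)), 0.0, d.total_mass,
                                  aggregation, len(directions), degenerate=True)
    if aggregation == "avg":
        p = np.mean([m / m.sum() for m in live], axis=0)
        ns = float(np.mean([m.sum() for m in live]))
    elif aggregation == "mrg":
        merged = np.sum(live, axis=0)
        ns = float(merged.sum())
        p = merged / ns
    else:
        raise ValueError(f"unknown aggregation {aggregation!r}")
    return FuzzyTextureMatrix("GLCM", p, ns, d.total_mass, aggregation, len(live))


def _runs_along(levels, weights, off):
    """Yield (level, length, mean_weight, prod_weight) for each run along ``off``."""
    shape = levels.shape
    step = np.array(off)
    # run starts: included voxels whose predecessor along -off is absent
    # or has a different level
    included = levels > 0
    prev_ok = np.zeros(shape, dtype=bool)
    s_src, s_dst = _shifted_pairs(shape, off)
    # dst voxels have a predecessor (src) inside the array
    same = (levels[s_src] == levels[s_dst]) & included[s_src] & included[s_dst]
    prev_ok[s_dst] = same
    starts = np.argwhere(included & ~prev_ok)
    runs = []
    for x, y, z in starts:
        g = levels[x, y, z]
        total_w = 0.0
        prod_w = 1.0
        length = 0
        cx, cy, cz = int(x), int(y), int(z)
        while (
            0 <= cx < shape[0]
            and 0 <= cy < shape[1]
            and 0 <= cz < shape[2]
            and levels[cx, cy, cz] == g
        ):
            total_w += weights[cx, cy, cz]
            prod_w *= weights[cx, cy, cz]
            length += 1
            cx += step[0]
            cy += step[1]
            cz += step[2]
        runs.append((int(g), length, total_w / length, prod_w))
    return runs


def build_fuzzy_glrlm(
    d,
    directions=DIRECTIONS_3D,
    aggregation: str = "avg",
    run_scheme: str = "mean",
) -> FuzzyTextureMatrix:
    """Grey-level run-length matrix; each run carries its mean membership."""
    ng = d.n_levels
    per_dir = []
    max_len = 1
    for off in directions:
        runs = _runs_along(d.levels, d.weights, off)
        if runs:
            max_len = max(max_len, max(r[1] for r in runs))
        per_dir.append(runs)
    mats = []
    for runs in per_dir:
        mat = np.zeros((ng, max_len))
        for g, length, mean_w, prod_w in runs:
            mat[g - 1, length - 1] += mean_w if run_scheme == "mean" else prod_w
        mats.append(mat)
    live = [m for m in mats if m.sum() > 0]
    if not live:
        return FuzzyTextureMatrix("GLRLM", np.zeros((ng, max_len)), 0.0,
                                  d.total_mass, aggregation, len(directions),
                                  degenerate=True)
    if aggregation == "avg":
        p = np.mean([m / m.sum() for m in live], axis=0)
        ns = float(np.mean([m.sum() for m in live]))
    elif aggregation == "mrg":
        merged = np.sum(live, axis=0)
        ns = float(merged.sum())
        p = merged / ns
    else:
        raise ValueError(f"unknown aggregation {aggregation!r}")
    return FuzzyTextureMatrix("GLRLM", p, ns, d.total_mass, aggregation, len(live))


def build_fuzzy_glszm(d, zone_scheme: str = "mean") -> FuzzyTextureMatrix:
    """Grey-level size-zone matrix over 26-connected equal-level zones."""
    ng = d.n_levels
    structure = np.ones((3, 3, 3), dtype=bool)
    zones = []  # (level, size, weight)
    for g in range(1, ng + 1):
        lab, n = ndimage.label(d.levels == g, structure=structure)
        if n == 0:
            continue
        index = np.arange(1, n + 1)
        sizes = ndimage.sum_labels(np.ones_like(lab, dtype=float), lab, index=index)
        if zone_scheme == "mean":
            wsums = ndimage.sum_labels(d.weights, lab, index=index)
            zones += [(g, int(s), ws / s) for s, ws in zip(sizes, wsums)]
        elif zone_scheme == "product":
            zones += [
                (g, int(sizes[i - 1]), float(np.prod(d.weights[lab == i])))
                for i in index
            ]
        else:
            raise ValueError(f"unknown zone scheme {zone_scheme!r}")
    if not zones:
        return FuzzyTextureMatrix("GLSZM", np.zeros((ng, 1)), 0.0, d.total_mass,
                                  "single", degenerate=True)
    max_size = max(s for _, s, _ in zones)
    mat = np.zeros((ng, max_size))
    for g, s, wz in zones:
        mat[g - 1, s - 1] += wz
    ns = float(mat.sum())
    return FuzzyTextureMatrix("GLSZM", mat / ns, ns, d.total_mass, "single")


def build_fuzzy_ngtdm(d) -> tuple[np.ndarray, np.ndarray]:
    """Neighborhood grey-tone difference vectors ``(s, n)``.

    ``s[i]`` accumulates ``w_k * |g_k - Abar_k|`` over included voxels of
    level ``i+1`` where ``Abar_k`` is the membership-weighted mean level
    of the voxel's included 26-neighbors; ``n[i]`` is the membership
    mass of the voxels counted (those with at least one included
    neighbor).
    """
    ng = d.n_levels
    kernel = np.ones((3, 3, 3))
    kernel[1, 1, 1] = 0.0
    wg = d.weights * d.levels
    nb_wg = ndimage.convolve(wg, kernel, mode="constant", cval=0.0)
    nb_w = ndimage.convolve(d.weights, kernel, mode="constant", cval=0.0)
    included = d.levels > 0
    counted = included & (nb_w > 0)
    s = np.zeros(ng)
    n = np.zeros(ng)
    if counted.any():
        abar = nb_wg[counted] / nb_w[counted]
        dev = d.weights[counted] * np.abs(d.levels[counted] - abar)
        np.add.at(s, d.levels[counted] - 1, dev)
        np.add.at(n, d.levels[counted] - 1, d.weights[counted])
    return s, n


# ---------------------------------------------------------------------------
# Feature formulas
# ---------------------------------------------------------------------------


def _safe_log2(x):
    out = np.zeros_like(x)
    pos = x > 0
    out[pos] = np.log2(x[pos])
    return out


def glcm_features(tm: FuzzyTextureMatrix) -> dict[str, float]:
    """The 25 co-occurrence features from a normalized GLCM."""
    p = tm.p
    ng = p.shape[0]
    i = np.arange(1, ng + 1, dtype=np.float64)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mu_x = float((i * px).sum())
    mu_y = float((i * py).sum())
    sd_x = float(np.sqrt(((i - mu_x) ** 2 * px).sum()))
    sd_y = float(np.sqrt(((i - mu_y) ** 2 * py).sum()))

    k_diff = np.arange(0, ng, dtype=np.float64)
    p_diff = np.zeros(ng)
    np.add.at(p_diff, np.abs(ii - jj).astype(int).ravel(), p.ravel())
    k_sum = np.arange(2, 2 * ng + 1, dtype=np.float64)
    p_sum = np.zeros(2 * ng - 1)
    np.add.at(p_sum, (ii + jj).astype(int).ravel() - 2, p.ravel())

    joint_avg = float((ii * p).sum())
    joint_var = float(((ii - joint_avg) ** 2 * p).sum())
    diff_avg = float((k_diff * p_diff).sum())
    sum_avg = float((k_sum * p_sum).sum())

    hxy = float(-(p * _safe_log2(p)).sum())
    pxy = np.outer(px, py)
    hxy1 = float(-(p * _safe_log2(pxy)).sum())
    hxy2 = float(-(pxy * _safe_log2(pxy)).sum())
    hx = float(-(px * _safe_log2(px)).sum())
    hy = float(-(py * _safe_log2(py)).sum())
    denom = max(hx, hy)
    ic1 = (hxy - hxy1) / denom if denom > 0 else np.nan
    ic2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy)))))

    inv_var = float((p_diff[1:] / k_diff[1:] ** 2).sum()) if ng > 1 else 0.0
    corr = (
        (float((ii * jj * p).sum()) - mu_x * mu_y) / (sd_x * sd_y)
        if sd_x > 0 and sd_y > 0
        else np.nan
    )

    return {
        "joint_max": float(p.max()),
        "joint_avg": joint_avg,
        "joint_var": joint_var,
        "joint_entr": hxy,
        "diff_avg": diff_avg,
        "diff_var": float(((k_diff - diff_avg) ** 2 * p_diff).sum()),
        "diff_entr": float(-(p_diff * _safe_log2(p_diff)).sum()),
        "sum_avg": sum_avg,
        "sum_var": float(((k_sum - sum_avg) ** 2 * p_sum).sum()),
        "sum_entr": float(-(p_sum * _safe_log2(p_sum)).sum()),
        "energy": float((p**2).sum()),
        "contrast": float(((ii - jj) ** 2 * p).sum()),
        "dissimilarity": float((np.abs(ii - jj) * p).sum()),
        "inv_diff": float((p / (1.0 + np.abs(ii - jj))).sum()),
        "inv_diff_norm": float((p / (1.0 + np.abs(ii - jj) / ng)).sum()),
        "inv_diff_mom": float((p / (1.0 + (ii - jj) ** 2)).sum()),
        "inv_diff_mom_norm": float((p / (1.0 + (ii - jj) ** 2 / ng**2)).sum()),
        "inv_var": inv_var,
        "corr": corr,
        "auto_corr": float((ii * jj * p).sum()),
        "clust_tend": float(((ii + jj - mu_x - mu_y) ** 2 * p).sum()),
        "clust_shade": float(((ii + jj - mu_x - mu_y) ** 3 * p).sum()),
        "clust_prom": float(((ii + jj - mu_x - mu_y) ** 4 * p).sum()),
        "info_corr1": ic1,
        "info_corr2": ic2,
    }


def _rlm_szm_features(tm: FuzzyTextureMatrix, prefix_j: str) -> dict[str, float]:
    """Shared run-length / size-zone formulas on a normalized (g, j) matrix."""
    p = tm.p
    ng, nj = p.shape
    g = np.arange(1, ng + 1, dtype=np.float64)
    j = np.arange(1, nj + 1, dtype=np.float64)
    gg, jj = np.meshgrid(g, j, indexing="ij")
    pg = p.sum(axis=1)
    pj = p.sum(axis=0)

    mu_g = float((gg * p).sum())
    mu_j = float((jj * p).sum())
    ns, nv = tm.ns, tm.nv
    if tm.aggregation == "mrg":
        perc = ns / (tm.n_directions * nv) if nv > 0 else np.nan
    else:
        perc = ns / nv if nv > 0 else np.nan

    return {
        "s%se" % prefix_j[0]: float((pj / j**2).sum()),
        "l%se" % prefix_j[0]: float((pj * j**2).sum()),
        "lg%se" % prefix_j[0]: float((pg / g**2).sum()),
        "hg%se" % prefix_j[0]: float((pg * g**2).sum()),
        "s%slge" % prefix_j[0]: float((p / (gg**2 * jj**2)).sum()),
        "s%shge" % prefix_j[0]: float((p * gg**2 / jj**2).sum()),
        "l%slge" % prefix_j[0]: float((p * jj**2 / gg**2).sum()),
        "l%shge" % prefix_j[0]: float((p * gg**2 * jj**2).sum()),
        "glnu": float(ns * (pg**2).sum()),
        "glnu_norm": float((pg**2).sum()),
        "%snu" % prefix_j: float(ns * (pj**2).sum()),
        "%snu_norm" % prefix_j: float((pj**2).sum()),
        "%s_perc" % prefix_j[0]: perc,
        "gl_var": float(((gg - mu_g) ** 2 * p).sum()),
        "%s_var" % prefix_j[0]: float(((jj - mu_j) ** 2 * p).sum()),
        "%s_entr" % prefix_j[0]: float(-(p * _safe_log2(p)).sum()),
    }


def glrlm_features(tm: FuzzyTextureMatrix) -> dict[str, float]:
    """The 16 run-length features (j axis = run length)."""
    f = _rlm_szm_features(tm, "rl")
    return {
        "sre": f["sre"],
        "lre": f["lre"],
        "lgre": f["lgre"],
        "hgre": f["hgre"],
        "srlge": f["srlge"],
        "srhge": f["srhge"],
        "lrlge": f["lrlge"],
        "lrhge": f["lrhge"],
        "glnu": f["glnu"],
        "glnu_norm": f["glnu_norm"],
        "rlnu": f["rlnu"],
        "rlnu_norm": f["rlnu_norm"],
        "r_perc": f["r_perc"],
        "gl_var": f["gl_var"],
        "rl_var": f["r_var"],
        "rl_entr": f["r_entr"],
    }


def glszm_features(tm: FuzzyTextureMatrix) -> dict[str, float]:
    """The 16 size-zone features (j axis = zone size)."""
    f = _rlm_szm_features(tm, "zs")
    return {
        "sze": f["sze"],
        "lze": f["lze"],
        "lgze": f["lgze"],
        "hgze": f["hgze"],
        "szlge": f["szlge"],
        "szhge": f["szhge"],
        "lzlge": f["lzlge"],
        "lzhge": f["lzhge"],
        "glnu": f["glnu"],
        "glnu_norm": f["glnu_norm"],
        "zsnu": f["zsnu"],
        "zsnu_norm": f["zsnu_norm"],
        "z_perc": f["z_perc"],
        "gl_var": f["gl_var"],
        "zs_var": f["z_var"],
        "zs_entr": f["z_entr"],
    }


def ngtdm_features(s: np.ndarray, n: np.ndarray) -> dict[str, float]:
    """The 5 neighborhood grey-tone difference features.

    ``s`` and ``n`` are the weighted deviation sums and occurrence
    masses from :func:`build_fuzzy_ngtdm`.  Deviations are normalized by
    the total occurrence mass before entering the ratio formulas.
    """
    total = n.sum()
    if total <= 0:
        return {k: np.nan for k in
                ("coarseness", "contrast", "busyness", "complexity", "strength")}
    p = n / total
    s_hat = s / total
    present = p > 0
    ngp = int(present.sum())
    i = np.arange(1, len(n) + 1, dtype=np.float64)

    dot = float((p * s_hat).sum())
    coarseness = min(1.0 / dot, _COARSENESS_CAP) if dot > 0 else _COARSENESS_CAP

    if ngp > 1:
        pi, pj = np.meshgrid(p[present], p[present], indexing="ij")
        gi, gj = np.meshgrid(i[present], i[present], indexing="ij")
        contrast = float((pi * pj * (gi - gj) ** 2).sum() / (ngp * (ngp - 1))) * float(
            s_hat.sum()
        )
        denom_busy = float(np.abs(gi * pi - gj * pj)[gi != gj].sum())
        busyness = dot / denom_busy if denom_busy > 0 else 0.0
        si, sj = np.meshgrid(s_hat[present], s_hat[present], indexing="ij")
        complexity = float(
            (np.abs(gi - gj) * (pi * si + pj * sj) / (pi + pj)).sum()
        )
        s_total = float(s_hat.sum())
        strength = (
            float(((pi + pj) * (gi - gj) ** 2)[gi != gj].sum()) / s_total
            if s_total > 0
            else 0.0
        )
    else:
        contrast = 0.0
        busyness = 0.0
        complexity = 0.0
        strength = 0.0

    return {
        "coarseness": coarseness,
        "contrast": contrast,
        "busyness": busyness,
        "complexity": complexity,
        "strength": strength,
    }
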