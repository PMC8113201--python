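"""Radiomics feature computation.

Implements the IBSI strong-consensus feature families used by the
lesion risk models: first-order intensity statistics, discretized
intensity-histogram statistics, grey level co-occurrence (GLCM, merged
over the 13 unique 3D directions at Chebyshev distances 1 and 2), grey
level run length (GLRLM, merged directions), grey level size zone
(GLSZM, 26-connectivity), grey level distance zone (GLDZM, zone
distance = minimum Chebyshev distance of the zone to the mask border,
in voxels, >= 1), neighbourhood grey tone difference (NGTDM), mask-only
morphology, and the conventional PET uptake metrics SUV_max, SUV_peak,
SUV_mean and SUV_TLG.

Discretization is fixed-bin-number (default 32 bins) on the in-mask
intensity range.  Features that are undefined on degenerate regions
(e.g. coefficient of variation at zero mean, GLCM correlation on a
single grey level) are imputed as 0 with a warning, so every feature
vector is finite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial.distance import pdist

from .grids import LesionVOI, Modality, VolumeGrid
from .registry import SUV_NAMES, FeatureFamily, FeatureRegistry

__all__ = [
    "FeatureVector",
    "discretize_fbn",
    "compute_intensity_stats",
    "compute_intensity_histogram",
    "compute_glcm_features",
    "compute_glrlm_features",
    "compute_glszm_features",
    "compute_gldzm_features",
    "compute_ngtdm_features",
    "compute_morphology_features",
    "compute_suv_metrics",
    "compute_modality_features",
    "assemble_feature_vector",
    "extract_lesion_features",
]

_STRUCT26 = np.ones((3, 3, 3), dtype=bool)

#: The 13 unique direction vectors of the 26-neighbourhood (one per
#: antipodal pair), used by GLCM and GLRLM.
DIRECTIONS_13 = tuple(
    (i, j, k)
    for i in (0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1)
    if (i, j, k) > (0, 0, 0)
)


@dataclass
class FeatureVector:
    """Ordered, named 446-entry feature vector of one lesion."""

    lesion_id: str
    names: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.names) != len(self.values):
            raise ValueError("names/values length mismatch")
        if not np.all(np.isfinite(self.values)):
            bad = [n for n, v in zip(self.names, self.values) if not np.isfinite(v)]
            raise ValueError(f"non-finite features for lesion {self.lesion_id}: {bad}")

    def __len__(self) -> int:
        return len(self.values)

    def to_series(self) -> pd.Series:
        return pd.Series(self.values, index=list(self.names), name=self.lesion_id)


# ---------------------------------------------------------------------------
# discretization


def discretize_fbn(values: np.ndarray, mask: np.ndarray, bins: int) -> np.ndarray:
    """Fixed-bin-number discretization of in-mask voxels to 1..bins.

    Returns an integer array shaped like `values`, 0 outside the mask.
    A constant region maps to level 1.
    """
    if bins < 2:
        raise ValueError("need at least 2 bins")
    mask = np.asarray(mask, dtype=bool)
    x = np.asarray(values, dtype=float)
    levels = np.zeros(x.shape, dtype=np.int32)
    inside = x[mask]
    lo, hi = inside.min(), inside.max()
    if hi > lo:
        lv = np.floor(bins * (inside - lo) / (hi - lo)).astype(np.int32) + 1
        np.clip(lv, 1, bins, out=lv)
    else:
        lv = np.ones(inside.shape, dtype=np.int32)
    levels[mask] = lv
    return levels


# ---------------------------------------------------------------------------
# first-order statistics


def _skew_kurt(x: np.ndarray) -> tuple[float, float]:
    m = x.mean()
    m2 = ((x - m) ** 2).mean()
    if m2 <= 0:
        return 0.0, 0.0
    m3 = ((x - m) ** 3).mean()
    m4 = ((x - m) ** 4).mean()
    return float(m3 / m2**1.5), float(m4 / m2**2 - 3.0)


def compute_intensity_stats(voxels: np.ndarray) -> dict[str, float]:
    """IBSI first-order intensity statistics of in-mask voxel values.

    Coefficient of variation at zero mean and the quartile coefficient
    of dispersion at P25+P75 = 0 are imputed as 0 with a warning.
    """
    x = np.asarray(voxels, dtype=float).ravel()
    if x.size < 2:
        raise ValueError("need at least 2 voxels for intensity statistics")
    mean = float(x.mean())
    var = float(x.var())
    skew, kurt = _skew_kurt(x)
    p10, p25, median, p75, p90 = np.percentile(x, [10, 25, 50, 75, 90])
    mad = float(np.abs(x - mean).mean())
    sel = x[(x >= p10) & (x <= p90)]
    rmad = float(np.abs(sel - sel.mean()).mean()) if sel.size else 0.0
    medad = float(np.abs(x - median).mean())
    sd = var**0.5
    if mean != 0:
        cov = sd / mean
    else:
        warnings.warn("zero mean: coefficient of variation imputed as 0")
        cov = 0.0
    qcod = float((p75 - p25) / (p75 + p25)) if (p75 + p25) != 0 else 0.0
    return {
        "mean": mean, "var": var, "skew": skew, "kurt": kurt,
        "median": float(median), "min": float(x.min()), "p10": float(p10),
        "p90": float(p90), "max": float(x.max()), "iqr": float(p75 - p25),
        "range": float(x.max() - x.min()), "mad": mad, "rmad": rmad,
        "medad": medad, "cov": float(cov), "qcod": qcod,
        "energy": float((x**2).sum()), "rms": float(np.sqrt((x**2).mean())),
    }


def compute_intensity_histogram(levels: np.ndarray, bins: int) -> dict[str, float]:
    """Intensity-histogram statistics on discretized grey levels 1..bins."""
    g = np.asarray(levels, dtype=float).ravel()
    g = g[g > 0]
    if g.size < 2:
        raise ValueError("need at least 2 discretized voxels")
    counts = np.bincount(g.astype(int), minlength=bins + 1)[1:].astype(float)
    p = counts / counts.sum()
    stats = compute_intensity_stats(g)
    out = {k: stats[k] for k in ("mean", "var", "skew", "kurt", "median", "min",
                                 "p10", "p90", "max", "iqr", "range", "mad",
                                 "rmad", "medad", "cov", "qcod")}
    out["mode"] = float(np.argmax(counts) + 1)
    nz = p[p > 0]
    out["entropy"] = float(-(nz * np.log2(nz)).sum())
    out["uniformity"] = float((p**2).sum())
    grad = np.empty(bins)
    grad[1:-1] = (counts[2:] - counts[:-2]) / 2.0
    grad[0] = counts[1] - counts[0]
    grad[-1] = counts[-1] - counts[-2]
    out["max_grad"] = float(grad.max())
    out["max_grad_g"] = float(np.argmax(grad) + 1)
    out["min_grad"] = float(grad.min())
    out["min_grad_g"] = float(np.argmin(grad) + 1)
    return out


# ---------------------------------------------------------------------------
# GLCM


def _shift_pairs(levels: np.ndarray, offset: tuple[int, int, int]) -> tuple[np.ndarray, np.ndarray]:
    """In-mask level pairs (a, b) with b at `offset` from a."""
    sl_a, sl_b = [], []
    for o, n in zip(offset, levels.shape):
        if o >= 0:
            sl_a.append(slice(0, n - o))
            sl_b.append(slice(o, n))
        else:
            sl_a.append(slice(-o, n))
            sl_b.append(slice(0, n + o))
    a = levels[tuple(sl_a)].ravel()
    b = levels[tuple(sl_b)].ravel()
    keep = (a > 0) & (b > 0)
    return a[keep], b[keep]


def glcm_matrix(levels: np.ndarray, bins: int, distance: int = 1) -> np.ndarray:
    """Symmetric co-occurrence count matrix merged over the 13 unique 3D
    directions at Chebyshev distance `distance`."""
    counts = np.zeros((bins, bins))
    for d in DIRECTIONS_13:
        off = tuple(distance * c for c in d)
        a, b = _shift_pairs(levels, off)
        if a.size:
            np.add.at(counts, (a - 1, b - 1), 1.0)
    return counts + counts.T


def _entropy2(p: np.ndarray) -> float:
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum()) if nz.size else 0.0


def glcm_features_from_matrix(counts: np.ndarray) -> dict[str, float]:
    ng = counts.shape[0]
    total = counts.sum()
    if total <= 0:
        # single voxel / no valid pairs: all features degenerate
        return {k: 0.0 for k in _GLCM_KEYS} | {"joint_max": 1.0, "energy": 1.0,
                                               "inv_diff": 1.0, "inv_diff_norm": 1.0,
                                               "inv_diff_mom": 1.0, "inv_diff_mom_norm": 1.0}
    p = counts / total
    i = np.arange(1, ng + 1)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)
    mu = float((ii * p).sum())
    joint_var = float(((ii - mu) ** 2 * p).sum())

    dabs = np.abs(ii - jj)
    p_diff = np.bincount(dabs.ravel(), weights=p.ravel(), minlength=ng)[:ng]
    kd = np.arange(ng)
    diff_avg = float((kd * p_diff).sum())
    diff_var = float(((kd - diff_avg) ** 2 * p_diff).sum())
    ks = np.arange(2, 2 * ng + 1)
    p_sum = np.bincount((ii + jj).ravel(), weights=p.ravel(), minlength=2 * ng + 1)[2:]
    sum_avg = float((ks * p_sum).sum())
    sum_var = float(((ks - sum_avg) ** 2 * p_sum).sum())

    sigma2 = float(((i - mu) ** 2 * px).sum())
    auto = float((ii * jj * p).sum())
    corr = (auto - mu * mu) / sigma2 if sigma2 > 0 else 0.0

    hxy = _entropy2(p)
    hx = _entropy2(px)
    outer = px[:, None] * px[None, :]
    valid = (p > 0) & (outer > 0)
    hxy1 = float(-(p[valid] * np.log2(outer[valid])).sum())
    hxy2 = _entropy2(outer)
    ic1 = (hxy - hxy1) / hx if hx > 0 else 0.0
    ic2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy)))))

    offdiag = dabs > 0
    inv_var = float((p[offdiag] / dabs[offdiag] ** 2).sum())

    cplus = ii + jj - 2 * mu
    return {
        "joint_max": float(p.max()),
        "joint_avg": mu,
        "joint_var": joint_var,
        "joint_entr": hxy,
        "diff_avg": diff_avg,
        "diff_var": diff_var,
        "diff_entr": _entropy2(p_diff),
        "sum_avg": sum_avg,
        "sum_var": sum_var,
        "sum_entr": _entropy2(p_sum),
        "energy": float((p**2).sum()),
        "contrast": float((dabs**2 * p).sum()),
        "dissimilarity": float((dabs * p).sum()),
        "inv_diff": float((p / (1.0 + dabs)).sum()),
        "inv_diff_norm": float((p / (1.0 + dabs / ng)).sum()),
        "inv_diff_mom": float((p / (1.0 + dabs**2)).sum()),
        "inv_diff_mom_norm": float((p / (1.0 + dabs**2 / ng**2)).sum()),
        "inv_var": inv_var,
        "corr": float(corr),
        "auto_corr": auto,
        "clust_tend": float((cplus**2 * p).sum()),
        "clust_shade": float((cplus**3 * p).sum()),
        "clust_prom": float((cplus**4 * p).sum()),
        "info_corr_1": float(ic1),
        "info_corr_2": ic2,
    }


_GLCM_KEYS = ("joint_max", "joint_avg", "joint_var", "joint_entr", "diff_avg",
              "diff_var", "diff_entr", "sum_avg", "sum_var", "sum_entr", "energy",
              "contrast", "dissimilarity", "inv_diff", "inv_diff_norm",
              "inv_diff_mom", "inv_diff_mom_norm", "inv_var", "corr", "auto_corr",
              "clust_tend", "clust_shade", "clust_prom", "info_corr_1", "info_corr_2")


def compute_glcm_features(volume: VolumeGrid | np.ndarray, mask: np.ndarray,
                          bins: int = 32, distance: int = 1) -> dict[str, float]:
    values = volume.values if isinstance(volume, VolumeGrid) else np.asarray(volume)
    levels = discretize_fbn(values, mask, bins)
    return glcm_features_from_matrix(glcm_matrix(levels, bins, distance))


# ---------------------------------------------------------------------------
# generic zone/run-length feature block


def _rs_features(counts: np.ndarray, n_voxels: int, prefix: tuple[str, ...]) -> dict[str, float]:
    """Shared feature formulas for run-length / size-zone / distance-zone
    matrices: counts[g-1, j-1] with grey level g and run/size/distance j."""
    ns = counts.sum()
    if ns <= 0:
        raise ValueError("empty run/zone matrix")
    ng, nj = counts.shape
    g = np.arange(1, ng + 1, dtype=float)
    j = np.arange(1, nj + 1, dtype=float)
    rg = counts.sum(axis=1)
    rj = counts.sum(axis=0)
    p = counts / ns
    mu_g = float((g * rg).sum() / ns)
    mu_j = float((j * rj).sum() / ns)
    gg, jj = np.meshgrid(g, j, indexing="ij")
    (k_sj, k_lj, k_lg, k_hg, k_slg, k_shg, k_llg, k_lhg,
     k_gln, k_glnn, k_jn, k_jnn, k_perc, k_gv, k_jv, k_entr) = prefix
    return {
        k_sj: float((rj / j**2).sum() / ns),
        k_lj: float((rj * j**2).sum() / ns),
        k_lg: float((rg / g**2).sum() / ns),
        k_hg: float((rg * g**2).sum() / ns),
        k_slg: float((counts / (gg**2 * jj**2)).sum() / ns),
        k_shg: float((counts * gg**2 / jj**2).sum() / ns),
        k_llg: float((counts * jj**2 / gg**2).sum() / ns),
        k_lhg: float((counts * gg**2 * jj**2).sum() / ns),
        k_gln: float((rg**2).sum() / ns),
        k_glnn: float((rg**2).sum() / ns**2),
        k_jn: float((rj**2).sum() / ns),
        k_jnn: float((rj**2).sum() / ns**2),
        k_perc: float(ns / n_voxels),
        k_gv: float((p * (gg - mu_g) ** 2).sum()),
        k_jv: float((p * (jj - mu_j) ** 2).sum()),
        k_entr: _entropy2(p),
    }


# ---------------------------------------------------------------------------
# GLRLM


def glrlm_matrix(levels: np.ndarray, bins: int) -> np.ndarray:
    """Run-length count matrix merged over the 13 unique 3D directions."""
    max_run = max(levels.shape)
    counts = np.zeros((bins, max_run))
    inmask = levels > 0
    coords = np.argwhere(inmask)
    flat_levels = levels
    for d in DIRECTIONS_13:
        d = np.asarray(d)
        prev = coords - d
        ok = np.all((prev >= 0) & (prev < levels.shape), axis=1)
        prev_same = np.zeros(len(coords), dtype=bool)
        pv = prev[ok]
        prev_same[ok] = (flat_levels[pv[:, 0], pv[:, 1], pv[:, 2]]
                         == flat_levels[coords[ok, 0], coords[ok, 1], coords[ok, 2]])
        starts = coords[~prev_same]
        gvals = flat_levels[starts[:, 0], starts[:, 1], starts[:, 2]]
        lengths = np.ones(len(starts), dtype=int)
        active = np.arange(len(starts))
        pos = starts.copy()
        while active.size:
            nxt = pos[active] + d
            ok2 = np.all((nxt >= 0) & (nxt < levels.shape), axis=1)
            same = np.zeros(active.size, dtype=bool)
            nv = nxt[ok2]
            same[ok2] = flat_levels[nv[:, 0], nv[:, 1], nv[:, 2]] == gvals[active[ok2]]
            cont = active[same]
            lengths[cont] += 1
            pos[cont] += d
            active = cont
        np.add.at(counts, (gvals - 1, lengths - 1), 1.0)
    return counts


_GLRLM_KEYS = ("sre", "lre", "lgre", "hgre", "srlge", "srhge", "lrlge", "lrhge",
               "glnu", "glnu_norm", "rlnu", "rlnu_norm", "r_perc", "gl_var",
               "rl_var", "rl_entr")


def compute_glrlm_features(volume, mask: np.ndarray, bins: int = 32) -> dict[str, float]:
    values = volume.values if isinstance(volume, VolumeGrid) else np.asarray(volume)
    levels = discretize_fbn(values, mask, bins)
    counts = glrlm_matrix(levels, bins)
    # run percentage denominator: voxels times number of directions
    feats = _rs_features(counts, int((levels > 0).sum()) * len(DIRECTIONS_13), _GLRLM_KEYS)
    return feats


# ---------------------------------------------------------------------------
# GLSZM / GLDZM


def _zones(levels: np.ndarray, bins: int):
    """Yield (grey level, zone voxel-coordinate array) for all 26-connected
    same-level zones inside the mask."""
    for g in range(1, bins + 1):
        region = levels == g
        if not region.any():
            continue
        labels, nlab = ndimage.label(region, structure=_STRUCT26)
        objs = ndimage.find_objects(labels)
        for lab in range(1, nlab + 1):
            sl = objs[lab - 1]
            local = np.argwhere(labels[sl] == lab)
            local += np.array([s.start for s in sl])
            yield g, local


def glszm_matrix(levels: np.ndarray, bins: int) -> np.ndarray:
    n_in = int((levels > 0).sum())
    counts = np.zeros((bins, max(1, n_in)))
    for g, vox in _zones(levels, bins):
        counts[g - 1, len(vox) - 1] += 1.0
    return counts


def compute_glszm_features(volume, mask: np.ndarray, bins: int = 32) -> dict[str, float]:
    values = volume.values if isinstance(volume, VolumeGrid) else np.asarray(volume)
    levels = discretize_fbn(values, mask, bins)
    counts = glszm_matrix(levels, bins)
    return _rs_features(counts, int((levels > 0).sum()), _GLSZM_KEYS)


_GLSZM_KEYS = ("sze", "lze", "lgze", "hgze", "szlge", "szhge", "lzlge", "lzhge",
               "glnu", "glnu_norm", "zsnu", "zsnu_norm", "z_perc", "gl_var",
               "zs_var", "zs_entr")


def border_distance_map(mask: np.ndarray) -> np.ndarray:
    """Chebyshev distance (in voxels) of each in-mask voxel to the mask
    border; voxels on the border (adjacent to background or the array
    edge) have distance 1."""
    padded = np.pad(np.asarray(mask, dtype=bool), 1)
    dist = ndimage.distance_transform_cdt(padded, metric="chessboard")
    return dist[1:-1, 1:-1, 1:-1]


def gldzm_matrix(levels: np.ndarray, mask: np.ndarray, bins: int) -> np.ndarray:
    dist = border_distance_map(mask)
    max_d = int(dist.max()) if dist.size else 1
    counts = np.zeros((bins, max(1, max_d)))
    for g, vox in _zones(levels, bins):
        d = int(dist[vox[:, 0], vox[:, 1], vox[:, 2]].min())
        counts[g - 1, d - 1] += 1.0
    return counts


_GLDZM_KEYS = ("sde", "lde", "lgze", "hgze", "sdlge", "sdhge", "ldlge", "ldhge",
               "glnu", "glnu_norm", "zdnu", "zdnu_norm", "z_perc", "gl_var",
               "zd_var", "zd_entr")


def compute_gldzm_features(volume, mask: np.ndarray, bins: int = 32) -> dict[str, float]:
    values = volume.values if isinstance(volume, VolumeGrid) else np.asarray(volume)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    levels = discretize_fbn(values, mask, bins)
    counts = gldzm_matrix(levels, mask, bins)
    return _rs_features(counts, int(mask.sum()), _GLDZM_KEYS)


# ---------------------------------------------------------------------------
# NGTDM


def compute_ngtdm_features(volume, mask: np.ndarray, bins: int = 32) -> dict[str, float]:
    values = volume.values if isinstance(volume, VolumeGrid) else np.asarray(volume)
    levels = discretize_fbn(values, mask, bins)
    inmask = levels > 0
    lv = levels.astype(float)
    nb_sum = np.zeros(lv.shape)
    nb_cnt = np.zeros(lv.shape)
    for d in DIRECTIONS_13:
        for off in (d, tuple(-c for c in d)):
            a_idx, b_idx = [], []
            for o, n in zip(off, lv.shape):
                if o >= 0:
                    a_idx.append(slice(0, n - o))
                    b_idx.append(slice(o, n))
                else:
                    a_idx.append(slice(-o, n))
                    b_idx.append(slice(0, n + o))
            a_idx, b_idx = tuple(a_idx), tuple(b_idx)
            valid = inmask[b_idx]
            nb_sum[a_idx] += np.where(valid, lv[b_idx], 0.0)
            nb_cnt[a_idx] += valid

    use = inmask & (nb_cnt > 0)
    nvc = int(use.sum())
    if nvc == 0:
        raise ValueError("no voxels with valid neighbourhood")
    avg = nb_sum[use] / nb_cnt[use]
    g = levels[use]
    s = np.zeros(bins)
    np.add.at(s, g - 1, np.abs(g - avg))
    n_g = np.bincount(g, minlength=bins + 1)[1:].astype(float)
    p = n_g / nvc
    i = np.arange(1, bins + 1, dtype=float)
    present = p > 0
    ngp = int(present.sum())

    denom_coarse = float((p * s).sum())
    coarseness = 1.0 / denom_coarse if denom_coarse > 0 else 1e6

    if ngp > 1:
        pi, pj = np.meshgrid(p, p, indexing="ij")
        di = (i[:, None] - i[None, :])
        contrast = float((pi * pj * di**2).sum()) / (ngp * (ngp - 1)) * float(s.sum()) / nvc
        ipi = i * p
        busy_den = float(np.abs(ipi[present][:, None] - ipi[present][None, :]).sum())
        busyness = float((p * s).sum()) / busy_den if busy_den > 0 else 0.0
        both = present[:, None] & present[None, :]
        with np.errstate(invalid="ignore", divide="ignore"):
            comp_terms = np.abs(di) * (pi * s[:, None] + pj * s[None, :]) / (pi + pj)
        complexity = float(comp_terms[both].sum()) / nvc
        s_sum = float(s.sum())
        strength = float(((pi + pj) * di**2)[both].sum()) / s_sum if s_sum > 0 else 0.0
    else:
        contrast = busyness = complexity = strength = 0.0

    return {"coarseness": float(coarseness), "contrast": float(contrast),
            "busyness": float(busyness), "complexity": float(complexity),
            "strength": float(strength)}


# ---------------------------------------------------------------------------
# morphology


def compute_morphology_features(mask: np.ndarray, spacing_mm) -> dict[str, float]:
    """Mask-only morphology: voxel-face surface area, compactness family,
    maximum 3D diameter and PCA elongation/flatness."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    spacing = np.asarray(spacing_mm, dtype=float)
    nvox = int(mask.sum())
    vol_mm3 = nvox * float(spacing.prod())

    padded = np.pad(mask, 1)
    surface = 0.0
    for axis in range(3):
        face_area = float(spacing.prod() / spacing[axis])
        diff = np.diff(padded.astype(np.int8), axis=axis)
        surface += np.abs(diff).sum() * face_area

    coords = np.argwhere(mask) * spacing
    eroded = ndimage.binary_erosion(mask, structure=_STRUCT26, border_value=0)
    border = np.argwhere(mask & ~eroded) * spacing
    if len(border) < 2:
        max_diam = 0.0
    else:
        if len(border) > 1500:
            from scipy.spatial import ConvexHull
            try:
                border = border[ConvexHull(border).vertices]
            except Exception:  # degenerate (coplanar) hull
                pass
        max_diam = float(pdist(border).max())

    if nvox > 1:
        cov = np.cov(coords.T)
        eig = np.sort(np.linalg.eigvalsh(cov))[::-1]
        eig = np.clip(eig, 0.0, None)
        elong = float(np.sqrt(eig[1] / eig[0])) if eig[0] > 0 else 1.0
        flat = float(np.sqrt(eig[2] / eig[0])) if eig[0] > 0 else 1.0
    else:
        elong = flat = 1.0

    return {
        "volume_ml": vol_mm3 / 1000.0,
        "surface_area_mm2": surface,
        "surface_to_volume": surface / vol_mm3,
        "compactness_1": vol_mm3 / (np.sqrt(np.pi) * surface**1.5),
        "compactness_2": 36.0 * np.pi * vol_mm3**2 / surface**3,
        "sphericity": (36.0 * np.pi * vol_mm3**2) ** (1.0 / 3.0) / surface,
        "asphericity": (surface**3 / (36.0 * np.pi * vol_mm3**2)) ** (1.0 / 3.0) - 1.0,
        "max_diameter_3d": max_diam,
        "elongation": elong,
        "flatness": flat,
    }


# ---------------------------------------------------------------------------
# conventional SUV metrics


def _peak_kernel(spacing_mm) -> np.ndarray:
    """Boolean sphere of 1 cm^3 (radius ~6.2 mm) on the voxel lattice."""
    radius = (3.0 * 1000.0 / (4.0 * np.pi)) ** (1.0 / 3.0)
    half = [int(np.floor(radius / s)) for s in spacing_mm]
    axes = [np.arange(-h, h + 1) * s for h, s in zip(half, spacing_mm)]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    return gx**2 + gy**2 + gz**2 <= radius**2


def compute_suv_metrics(pet: VolumeGrid, mask: np.ndarray) -> dict[str, float]:
    """SUV_max / SUV_peak / SUV_mean / SUV_TLG of a lesion on the PET volume.

    SUV_peak is the highest sphere-averaged uptake over spheres of 1 cm^3
    centred on in-mask voxels; near the volume edge the average runs over
    the available in-sphere voxels.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    values = pet.values
    kernel = _peak_kernel(pet.spacing_mm).astype(float)
    num = ndimage.convolve(values, kernel, mode="constant", cval=0.0)
    den = ndimage.convolve(np.ones_like(values), kernel, mode="constant", cval=0.0)
    sphere_mean = num / den
    suv_mean = float(values[mask].mean())
    volume_ml = float(mask.sum()) * pet.voxel_volume_ml
    return {
        "suv_max": float(values[mask].max()),
        "suv_peak": float(sphere_mean[mask].max()),
        "suv_mean": suv_mean,
        "suv_tlg": suv_mean * volume_ml,
    }


# ---------------------------------------------------------------------------
# per-lesion assembly


_FAMILY_DISPATCH = {
    FeatureFamily.GLRLM: ("rlm_", compute_glrlm_features),
    FeatureFamily.GLSZM: ("szm_", compute_glszm_features),
    FeatureFamily.GLDZM: ("dzm_", compute_gldzm_features),
    FeatureFamily.NGTDM: ("ngt_", compute_ngtdm_features),
}


def _crop_to_mask(values: np.ndarray, mask: np.ndarray, margin: int = 1):
    """Bounding-box crop (with margin) — texture features only see
    in-mask voxels, so cropping is exact and much faster."""
    idx = np.argwhere(mask)
    lo = np.maximum(idx.min(axis=0) - margin, 0)
    hi = np.minimum(idx.max(axis=0) + margin + 1, mask.shape)
    sl = tuple(slice(l, h) for l, h in zip(lo, hi))
    return values[sl], mask[sl]


def compute_modality_features(volume: VolumeGrid, mask: np.ndarray, bins: int) -> dict[str, float]:
    """All per-modality (intensity + texture) features of one lesion."""
    values, cmask = _crop_to_mask(volume.values, np.asarray(mask, dtype=bool))
    voxels = values[cmask]
    levels = discretize_fbn(values, cmask, bins)
    out: dict[str, float] = {}
    for name, v in compute_intensity_stats(voxels).items():
        out[f"stat_{name}"] = v
    for name, v in compute_intensity_histogram(levels, bins).items():
        out[f"ih_{name}"] = v
    for dist in (1, 2):
        feats = glcm_features_from_matrix(glcm_matrix(levels, bins, dist))
        for name, v in feats.items():
            out[f"cm_d{dist}_{name}"] = v
    for prefix, fn in _FAMILY_DISPATCH.values():
        for name, v in fn(values, cmask, bins).items():
            out[f"{prefix}{name}"] = v
    return out


def assemble_feature_vector(per_modality: dict[Modality, dict[str, float]],
                            morphology: dict[str, float],
                            suv: dict[str, float],
                            registry: FeatureRegistry,
                            lesion_id: str = "") -> FeatureVector:
    """Order computed features per the registry and append the four SUV
    metrics; any missing registry entry raises a hard error naming it,
    any non-finite value is imputed as 0 with a warning."""
    values = []
    from .registry import _MOD_PREFIX  # noqa: PLC0415

    for entry in registry.entries:
        if entry.modality is None:
            source, key = morphology, entry.name
        else:
            source, key = per_modality.get(entry.modality, {}), entry.name
        if key not in source:
            raise KeyError(f"missing feature for registry entry {entry.full_name!r}")
        values.append(source[key])
    for key in SUV_NAMES:
        if key not in suv:
            raise KeyError(f"missing SUV metric {key!r}")
        values.append(suv[key])
    values = np.asarray(values, dtype=float)
    bad = ~np.isfinite(values)
    if bad.any():
        names_all = list(registry.feature_names) + list(SUV_NAMES)
        warnings.warn("non-finite features imputed as 0: "
                      f"{[names_all[i] for i in np.flatnonzero(bad)]}")
        values[bad] = 0.0
    return FeatureVector(lesion_id, tuple(registry.feature_names) + tuple(SUV_NAMES), values)


def extract_lesion_features(volumes: dict[Modality, VolumeGrid], voi: LesionVOI,
                            registry: FeatureRegistry) -> FeatureVector:
    """Compute the full 446-entry feature vector of one lesion from its
    three co-registered modality volumes."""
    per_modality = {
        modality: compute_modality_features(volumes[modality], voi.mask,
                                            registry.bins[modality])
        for modality in (Modality.PSMA_PET, Modality.ADC, Modality.T2W)
    }
    pet = volumes[Modality.PSMA_PET]
    morphology = compute_morphology_features(voi.mask, pet.spacing_mm)
    suv = compute_suv_metrics(pet, voi.mask)
    return assemble_feature_vector(per_modality, morphology, suv, registry, voi.lesion_id)
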