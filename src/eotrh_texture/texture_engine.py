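"""Masked-ROI gray-level quantization and the 93-feature texture panel.

Six families are computed on a discretized tooth patch: first-order
statistics (FOS, 18 features), gray level co-occurrence matrix (GLCM, 24),
neighbouring gray tone difference matrix (NGTDM, 5), gray level dependence
matrix (GLDM, 14), gray level run length matrix (GLRLM, 16) and gray level
size zone matrix (GLSZM, 16).

Conventions (all configurable):

* discretization by fixed bin width: ``level = floor((I - min_I)/w) + 1``;
* GLCM/GLRLM over four 2D directions (0, 45, 90, 135 degrees) at distance
  delta = 1, features averaged over directions, which makes them invariant
  to 90-degree patch rotation;
* NGTDM/GLDM neighbourhoods are the 8 Chebyshev delta = 1 neighbours;
  GLSZM zones are 8-connected components;
* GLDM dependence: a neighbour is dependent iff its level differs from the
  centre by at most alpha (default 0); the matrix stores the dependent
  neighbour count j and features use the 1-based dependence size j + 1;
* pairs, runs, neighbourhoods and zones never cross the mask boundary;
* features undefined on degenerate input return NaN, except NGTDM
  Coarseness which is capped at 1e6 when its denominator vanishes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from typing import Iterable

import numpy as np
from skimage import measure

from .errors import EmptyROIError

MIN_PIXELS = 16

#: Direction offsets (dr, dc) for GLCM/GLRLM: 0, 45, 90, 135 degrees.
DIRECTIONS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}

COARSENESS_CAP = 1e6

FOS_NAMES = [
    "mean", "median", "minimum", "maximum", "percentile_10", "percentile_90",
    "variance", "root_mean_squared", "kurtosis", "skewness", "uniformity",
    "range", "interquartile_range", "mean_absolute_deviation",
    "robust_mean_absolute_deviation", "energy", "total_energy", "entropy",
]

GLCM_NAMES = [
    "autocorrelation", "cluster_prominence", "cluster_shade",
    "cluster_tendency", "contrast", "correlation", "difference_average",
    "difference_entropy", "difference_variance", "inverse_difference",
    "inverse_difference_moment", "inverse_difference_moment_normalized",
    "inverse_difference_normalized", "imc1", "imc2", "inverse_variance",
    "joint_average", "joint_energy", "joint_entropy",
    "maximal_correlation_coefficient", "maximum_probability", "sum_average",
    "sum_entropy", "sum_of_squares",
]

NGTDM_NAMES = ["busyness", "coarseness", "complexity", "contrast", "strength"]

GLDM_NAMES = [
    "dependence_entropy", "dependence_non_uniformity",
    "dependence_non_uniformity_normalized", "dependence_variance",
    "gray_level_non_uniformity", "gray_level_variance",
    "high_gray_level_emphasis", "large_dependence_emphasis",
    "large_dependence_high_gray_level_emphasis",
    "large_dependence_low_gray_level_emphasis", "low_gray_level_emphasis",
    "small_dependence_emphasis", "small_dependence_high_gray_level_emphasis",
    "small_dependence_low_gray_level_emphasis",
]

GLRLM_NAMES = [
    "gray_level_non_uniformity", "gray_level_non_uniformity_normalized",
    "gray_level_variance", "high_gray_level_run_emphasis",
    "long_run_emphasis", "long_run_high_gray_level_emphasis",
    "long_run_low_gray_level_emphasis", "low_gray_level_run_emphasis",
    "run_entropy", "run_length_non_uniformity",
    "run_length_non_uniformity_normalized", "run_percentage",
    "run_variance", "short_run_emphasis",
    "short_run_high_gray_level_emphasis", "short_run_low_gray_level_emphasis",
]

GLSZM_NAMES = [
    "gray_level_non_uniformity", "gray_level_non_uniformity_normalized",
    "gray_level_variance", "high_gray_level_zone_emphasis",
    "large_area_emphasis", "large_area_high_gray_level_emphasis",
    "large_area_low_gray_level_emphasis", "low_gray_level_zone_emphasis",
    "size_zone_non_uniformity", "size_zone_non_uniformity_normalized",
    "small_area_emphasis", "small_area_high_gray_level_emphasis",
    "small_area_low_gray_level_emphasis", "zone_entropy", "zone_percentage",
    "zone_variance",
]

FAMILY_NAMES = {
    "FOS": FOS_NAMES,
    "GLCM": GLCM_NAMES,
    "NGTDM": NGTDM_NAMES,
    "GLDM": GLDM_NAMES,
    "GLRLM": GLRLM_NAMES,
    "GLSZM": GLSZM_NAMES,
}

FAMILIES = tuple(FAMILY_NAMES)


def feature_manifest() -> list[str]:
    """The 93 canonical ``<family>_<feature>`` names, in serialization order."""
    return [
        f"{family.lower()}_{name}"
        for family in FAMILIES
        for name in FAMILY_NAMES[family]
    ]


def read_shipped_manifest() -> list[str]:
    """Read the manifest file shipped with the package (one name per line)."""
    text = resources.files("eotrh_texture").joinpath("feature_manifest.txt").read_text()
    return [line for line in text.splitlines() if line.strip()]


@dataclass
class QuantizedPatch:
    """Masked ROI discretized to integer gray levels 1..n_g (0 outside mask)."""

    levels: np.ndarray
    n_g: int
    bin_width: float
    mask: np.ndarray

    @property
    def n_p(self) -> int:
        return int(self.mask.sum())

    @property
    def masked_levels(self) -> np.ndarray:
        return self.levels[self.mask]


def discretize(
    patch: np.ndarray, mask: np.ndarray, bin_width: float = 25.0
) -> QuantizedPatch:
    """Discretize masked intensities: ``level = floor((I - min)/w) + 1``."""
    if bin_width <= 0:
        raise ValueError(f"bin_width must be > 0, got {bin_width}")
    patch = np.asarray(patch, dtype=np.float64)
    mask = np.asarray(mask, dtype=bool)
    if patch.shape != mask.shape:
        raise ValueError("patch and mask shapes differ")
    vals = patch[mask]
    if vals.size < MIN_PIXELS:
        raise EmptyROIError(f"only {vals.size} masked pixels (< {MIN_PIXELS})")
    levels = np.zeros(patch.shape, dtype=np.int64)
    levels[mask] = np.floor((vals - vals.min()) / bin_width).astype(np.int64) + 1
    return QuantizedPatch(levels=levels, n_g=int(levels.max()), bin_width=bin_width, mask=mask)


# ---------------------------------------------------------------------------
# First-order statistics
# ---------------------------------------------------------------------------

def fos_features(
    patch: np.ndarray, mask: np.ndarray, bin_width: float = 25.0
) -> dict[str, float]:
    """18 first-order features of the raw masked intensities.

    Uniformity and entropy are computed on the fixed-bin-width histogram;
    everything else uses undiscretized values.  Variance and the absolute
    deviations are population-style (divide by N).  Percentiles interpolate
    linearly between order statistics.  Skewness and kurtosis (Pearson,
    i.e. not excess) are NaN on a constant region.
    """
    patch = np.asarray(patch, dtype=np.float64)
    mask = np.asarray(mask, dtype=bool)
    x = patch[mask]
    if x.size < 2:
        raise EmptyROIError("need at least 2 masked pixels for first-order features")
    n = x.size
    mean = x.mean()
    centered = x - mean
    m2 = np.mean(centered**2)
    m3 = np.mean(centered**3)
    m4 = np.mean(centered**4)
    p10, p25, p75, p90 = np.percentile(x, [10, 25, 75, 90])
    robust = x[(x >= p10) & (x <= p90)]
    rmad = float(np.abs(robust - robust.mean()).mean()) if robust.size else float("nan")
    q = discretize(patch, mask, bin_width) if n >= MIN_PIXELS else None
    if q is not None:
        counts = np.bincount(q.masked_levels)[1:]
        p = counts[counts > 0] / n
    else:  # tiny regions: histogram on the raw values with the same rule
        lev = np.floor((x - x.min()) / bin_width).astype(int)
        counts = np.bincount(lev)
        p = counts[counts > 0] / n
    energy = float(np.sum(x**2))
    return {
        "mean": float(mean),
        "median": float(np.median(x)),
        "minimum": float(x.min()),
        "maximum": float(x.max()),
        "percentile_10": float(p10),
        "percentile_90": float(p90),
        "variance": float(m2),
        "root_mean_squared": float(np.sqrt(np.mean(x**2))),
        "kurtosis": float(m4 / m2**2) if m2 > 0 else float("nan"),
        "skewness": float(m3 / m2**1.5) if m2 > 0 else float("nan"),
        "uniformity": float(np.sum(p**2)),
        "range": float(x.max() - x.min()),
        "interquartile_range": float(p75 - p25),
        "mean_absolute_deviation": float(np.abs(centered).mean()),
        "robust_mean_absolute_deviation": rmad,
        "energy": energy,
        "total_energy": energy * 1.0,  # unit pixel area when spacing unknown
        "entropy": float(-np.sum(p * np.log2(p))),
    }


# ---------------------------------------------------------------------------
# GLCM
# ---------------------------------------------------------------------------

def _shifted_pairs(
    q: QuantizedPatch, offset: tuple[int, int]
) -> tuple[np.ndarray, np.ndarray]:
    """Level pairs (a, b) for pixels at distance ``offset`` with both in mask."""
    dr, dc = offset
    h, w = q.levels.shape
    r0s, r0e = max(0, -dr), min(h, h - dr)
    c0s, c0e = max(0, -dc), min(w, w - dc)
    src = (slice(r0s, r0e), slice(c0s, c0e))
    dst = (slice(r0s + dr, r0e + dr), slice(c0s + dc, c0e + dc))
    valid = q.mask[src] & q.mask[dst]
    return q.levels[src][valid], q.levels[dst][valid]


def glcm_matrix(
    q: QuantizedPatch, delta: int = 1, directions: Iterable[int] = (0, 45, 90, 135)
) -> dict[int, np.ndarray]:
    """Per-direction symmetric, normalized co-occurrence matrices.

    Directions with no valid in-mask pair are omitted from the result.
    """
    out = {}
    for angle in directions:
        dr, dc = DIRECTIONS[angle]
        a, b = _shifted_pairs(q, (dr * delta, dc * delta))
        if a.size == 0:
            continue
        counts = np.bincount((a - 1) * q.n_g + (b - 1), minlength=q.n_g**2)
        mat = counts.reshape(q.n_g, q.n_g).astype(np.float64)
        mat = mat + mat.T  # symmetric: count both orderings
        out[angle] = mat / mat.sum()
    return out


def _glcm_features_single(p: np.ndarray) -> dict[str, float]:
    ng = p.shape[0]
    i = np.arange(1, ng + 1, dtype=np.float64)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)  # symmetric => px == py
    mu = float(np.sum(ii * p))
    sig2 = float(np.sum((ii - mu) ** 2 * p))
    sig = np.sqrt(sig2)

    # p_{x-y}(k), k = 0..ng-1 and p_{x+y}(k), k = 2..2ng
    k_diff = np.arange(ng, dtype=np.float64)
    p_diff = np.zeros(ng)
    np.add.at(p_diff, np.abs(ii - jj).astype(int), p)
    k_sum = np.arange(2, 2 * ng + 1, dtype=np.float64)
    p_sum = np.zeros(2 * ng - 1)
    np.add.at(p_sum, (ii + jj).astype(int) - 2, p)

    def ent(v: np.ndarray) -> float:
        v = v[v > 0]
        return float(-np.sum(v * np.log2(v)))

    da = float(np.sum(k_diff * p_diff))
    hxy = ent(p)
    hx = ent(px)
    outer = np.outer(px, px)
    pos = (p > 0) & (outer > 0)
    hxy1 = float(-np.sum(p[pos] * np.log2(outer[pos])))
    hxy2 = float(-np.sum(outer[outer > 0] * np.log2(outer[outer > 0])))
    imc1 = (hxy - hxy1) / hx if hx > 0 else 0.0  # symmetric: HX == HY

    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy)))))

    if sig2 > 0:
        correlation = float((np.sum(ii * jj * p) - mu * mu) / sig2)
    else:
        correlation = float("nan")

    # Maximal correlation coefficient: sqrt of second-largest eigenvalue of Q
    keep = px > 0
    if keep.sum() <= 1:
        mcc = 1.0
    else:
        pk = p[np.ix_(keep, keep)]
        pxk = px[keep]
        # Q(i,j) = sum_k p(i,k) p(j,k) / (p_x(i) p_y(k))
        q_mat = np.einsum("ik,jk->ij", pk, pk / pxk[None, :]) / pxk[:, None]
        eig = np.sort(np.real(np.linalg.eigvals(q_mat)))
        mcc = float(np.sqrt(max(0.0, eig[-2])))

    inv_var_mask = k_diff > 0
    return {
        "autocorrelation": float(np.sum(ii * jj * p)),
        "cluster_prominence": float(np.sum((ii + jj - 2 * mu) ** 4 * p)),
        "cluster_shade": float(np.sum((ii + jj - 2 * mu) ** 3 * p)),
        "cluster_tendency": float(np.sum((ii + jj - 2 * mu) ** 2 * p)),
        "contrast": float(np.sum((ii - jj) ** 2 * p)),
        "correlation": correlation,
        "difference_average": da,
        "difference_entropy": ent(p_diff),
        "difference_variance": float(np.sum((k_diff - da) ** 2 * p_diff)),
        "inverse_difference": float(np.sum(p_diff / (1.0 + k_diff))),
        "inverse_difference_moment": float(np.sum(p_diff / (1.0 + k_diff**2))),
        "inverse_difference_moment_normalized": float(
            np.sum(p_diff / (1.0 + (k_diff / ng) ** 2))
        ),
        "inverse_difference_normalized": float(np.sum(p_diff / (1.0 + k_diff / ng))),
        "imc1": imc1,
        "imc2": imc2,
        "inverse_variance": float(
            np.sum(p_diff[inv_var_mask] / k_diff[inv_var_mask] ** 2)
        ),
        "joint_average": mu,
        "joint_energy": float(np.sum(p**2)),
        "joint_entropy": hxy,
        "maximal_correlation_coefficient": mcc,
        "maximum_probability": float(p.max()),
        "sum_average": float(np.sum(k_sum * p_sum)),
        "sum_entropy": ent(p_sum),
        "sum_of_squares": sig2,
    }


def glcm_features(
    q: QuantizedPatch, delta: int = 1, directions: Iterable[int] = (0, 45, 90, 135)
) -> dict[str, float]:
    """24 GLCM features averaged over the requested directions."""
    mats = glcm_matrix(q, delta=delta, directions=directions)
    if not mats:
        warnings.warn("GLCM: no valid in-mask pixel pairs in any direction")
        return {name: float("nan") for name in GLCM_NAMES}
    per_dir = [_glcm_features_single(p) for p in mats.values()]
    return {
        name: float(np.mean([d[name] for d in per_dir])) for name in GLCM_NAMES
    }


# ---------------------------------------------------------------------------
# NGTDM
# ---------------------------------------------------------------------------

def ngtdm_vectors(
    q: QuantizedPatch, delta: int = 1
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(n_i, p_i, s_i) for levels 1..n_g.

    For every masked pixel with at least one masked Chebyshev-``delta``
    neighbour, the absolute difference between its level and the mean level
    of those neighbours is accumulated into ``s`` at its own level.
    """
    nb_sum = np.zeros(q.levels.shape, dtype=np.float64)
    nb_cnt = np.zeros(q.levels.shape, dtype=np.float64)
    offsets = [
        (dr, dc)
        for dr in range(-delta, delta + 1)
        for dc in range(-delta, delta + 1)
        if (dr, dc) != (0, 0)
    ]
    masked_levels = np.where(q.mask, q.levels, 0).astype(np.float64)
    for dr, dc in offsets:
        shifted_lv = _shift(masked_levels, dr, dc)
        shifted_mk = _shift(q.mask.astype(np.float64), dr, dc)
        nb_sum += shifted_lv
        nb_cnt += shifted_mk
    valid = q.mask & (nb_cnt > 0)
    diffs = np.zeros(q.levels.shape)
    diffs[valid] = np.abs(q.levels[valid] - nb_sum[valid] / nb_cnt[valid])
    n = np.zeros(q.n_g)
    s = np.zeros(q.n_g)
    lv = q.levels[valid]
    np.add.at(n, lv - 1, 1.0)
    np.add.at(s, lv - 1, diffs[valid])
    nvp = n.sum()
    p = n / nvp if nvp > 0 else n
    return n, p, s


def _shift(arr: np.ndarray, dr: int, dc: int) -> np.ndarray:
    """Shift with zero fill (values falling outside contribute nothing)."""
    out = np.zeros_like(arr)
    h, w = arr.shape
    rs, re = max(0, dr), min(h, h + dr)
    cs, ce = max(0, dc), min(w, w + dc)
    out[rs:re, cs:ce] = arr[rs - dr : re - dr, cs - dc : ce - dc]
    return out


def ngtdm_features(q: QuantizedPatch, delta: int = 1) -> dict[str, float]:
    """The 5 NGTDM features: busyness, coarseness, complexity, contrast, strength."""
    n, p, s = ngtdm_vectors(q, delta=delta)
    nvp = n.sum()
    if nvp == 0:
        warnings.warn("NGTDM: no masked pixel has a masked neighbour")
        return {name: float("nan") for name in NGTDM_NAMES}
    i = np.arange(1, q.n_g + 1, dtype=np.float64)
    act = p > 0
    ngp = int(act.sum())
    ps = float(np.sum(p * s))
    s_tot = float(s.sum())

    coarseness = 1.0 / ps if ps > 0 else COARSENESS_CAP

    if ngp > 1:
        ia, pa, sa = i[act], p[act], s[act]
        dij2 = (ia[:, None] - ia[None, :]) ** 2
        contrast = float(
            np.sum(pa[:, None] * pa[None, :] * dij2) / (ngp * (ngp - 1))
        ) * (s_tot / nvp)
        busy_den = float(np.sum(np.abs(ia[:, None] * pa[:, None] - ia[None, :] * pa[None, :])))
        busyness = ps / busy_den if busy_den > 0 else 0.0
        ps_i = pa * sa
        complexity = float(
            np.sum(
                np.abs(ia[:, None] - ia[None, :])
                * (ps_i[:, None] + ps_i[None, :])
                / (pa[:, None] + pa[None, :])
            )
            / nvp
        )
        strength = (
            float(np.sum((pa[:, None] + pa[None, :]) * dij2)) / s_tot
            if s_tot > 0
            else 0.0
        )
    else:
        contrast, busyness, complexity, strength = 0.0, 0.0, 0.0, 0.0

    return {
        "busyness": busyness,
        "coarseness": coarseness,
        "complexity": complexity,
        "contrast": contrast,
        "strength": strength,
    }


# ---------------------------------------------------------------------------
# GLDM
# ---------------------------------------------------------------------------

def gldm_matrix(q: QuantizedPatch, delta: int = 1, alpha: int = 0) -> np.ndarray:
    """P(i, j): masked pixels of level i with j dependent neighbours.

    A neighbour within Chebyshev distance ``delta`` is dependent iff its
    level differs from the centre by at most ``alpha``.  Column j is the raw
    dependent-neighbour count (starting at 0); feature formulas use the
    1-based dependence size j + 1.
    """
    offsets = [
        (dr, dc)
        for dr in range(-delta, delta + 1)
        for dc in range(-delta, delta + 1)
        if (dr, dc) != (0, 0)
    ]
    dep = np.zeros(q.levels.shape, dtype=np.int64)
    for dr, dc in offsets:
        lv = _shift(q.levels.astype(np.float64), dr, dc)
        mk = _shift(q.mask.astype(np.float64), dr, dc) > 0
        dep += (mk & (np.abs(lv - q.levels) <= alpha)).astype(np.int64)
    max_dep = len(offsets)
    mat = np.zeros((q.n_g, max_dep + 1))
    np.add.at(mat, (q.levels[q.mask] - 1, dep[q.mask]), 1.0)
    return mat


def gldm_features(
    q: QuantizedPatch, delta: int = 1, alpha: int = 0
) -> dict[str, float]:
    """14 GLDM features from the dependence matrix."""
    mat = gldm_matrix(q, delta=delta, alpha=alpha)
    nz = mat.sum()
    p = mat / nz
    i = np.arange(1, mat.shape[0] + 1, dtype=np.float64)
    d = np.arange(1, mat.shape[1] + 1, dtype=np.float64)  # dependence size j+1
    ii = i[:, None]
    dd = d[None, :]
    pi = p.sum(axis=1)
    pd = p.sum(axis=0)
    mu_i = float(np.sum(i * pi))
    mu_d = float(np.sum(d * pd))
    pos = p[p > 0]
    return {
        "dependence_entropy": float(-np.sum(pos * np.log2(pos))),
        "dependence_non_uniformity": float(np.sum(mat.sum(axis=0) ** 2) / nz),
        "dependence_non_uniformity_normalized": float(np.sum(pd**2)),
        "dependence_variance": float(np.sum((dd - mu_d) ** 2 * p)),
        "gray_level_non_uniformity": float(np.sum(mat.sum(axis=1) ** 2) / nz),
        "gray_level_variance": float(np.sum((ii - mu_i) ** 2 * p)),
        "high_gray_level_emphasis": float(np.sum(ii**2 * p)),
        "large_dependence_emphasis": float(np.sum(dd**2 * p)),
        "large_dependence_high_gray_level_emphasis": float(np.sum(ii**2 * dd**2 * p)),
        "large_dependence_low_gray_level_emphasis": float(np.sum(dd**2 / ii**2 * p)),
        "low_gray_level_emphasis": float(np.sum(p / ii**2)),
        "small_dependence_emphasis": float(np.sum(p / dd**2)),
        "small_dependence_high_gray_level_emphasis": float(np.sum(ii**2 / dd**2 * p)),
        "small_dependence_low_gray_level_emphasis": float(np.sum(p / (ii**2 * dd**2))),
    }


# ---------------------------------------------------------------------------
# GLRLM
# ---------------------------------------------------------------------------

def _run_lengths(line: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(values, lengths) of maximal constant nonzero runs in a 1D array."""
    if line.size == 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    change = np.flatnonzero(line[1:] != line[:-1])
    starts = np.concatenate(([0], change + 1))
    ends = np.concatenate((change + 1, [line.size]))
    vals = line[starts]
    keep = vals > 0
    return vals[keep], (ends - starts)[keep]


def _direction_flat(levels: np.ndarray, angle: int) -> np.ndarray:
    """All lines of one direction concatenated, zero-separated, as 1D array.

    Diagonal directions are handled by shearing the raster so that each
    diagonal becomes a column; the zero fill of the shear doubles as the
    run separator.
    """
    h, w = levels.shape
    if angle == 0:
        arr = levels
    elif angle == 90:
        arr = levels.T
    elif angle in (45, 135):
        rows = np.arange(h)[:, None]
        cols = np.arange(w)[None, :]
        sheared = np.zeros((h, w + h - 1), dtype=levels.dtype)
        if angle == 45:  # (r, c) -> column c + r: neighbours differ by (1, -1)
            sheared[rows, cols + rows] = levels
        else:  # (r, c) -> column c + (h-1-r): neighbours differ by (1, 1)
            sheared[rows, cols + (h - 1 - rows)] = levels
        arr = sheared.T
    else:
        raise ValueError(f"unsupported direction {angle}")
    padded = np.concatenate([arr, np.zeros((arr.shape[0], 1), dtype=arr.dtype)], axis=1)
    return padded.ravel()


def glrlm_matrix(
    q: QuantizedPatch, directions: Iterable[int] = (0, 45, 90, 135)
) -> dict[int, np.ndarray]:
    """Per-direction run length matrices P(i, j), runs broken by the mask."""
    levels = np.where(q.mask, q.levels, 0)
    max_len = max(q.levels.shape)
    out = {}
    for angle in directions:
        vals, lens = _run_lengths(_direction_flat(levels, angle))
        if vals.size:
            mat = np.zeros((q.n_g, max_len))
            np.add.at(mat, (vals - 1, lens - 1), 1.0)
            out[angle] = mat
    return out


def _rl_features(mat: np.ndarray, n_p: int) -> dict[str, float]:
    nr = mat.sum()
    p = mat / nr
    i = np.arange(1, mat.shape[0] + 1, dtype=np.float64)[:, None]
    j = np.arange(1, mat.shape[1] + 1, dtype=np.float64)[None, :]
    pi = p.sum(axis=1)
    pj = p.sum(axis=0)
    mu_i = float(np.sum(i[:, 0] * pi))
    mu_j = float(np.sum(j[0, :] * pj))
    pos = p[p > 0]
    return {
        "gray_level_non_uniformity": float(np.sum(mat.sum(axis=1) ** 2) / nr),
        "gray_level_non_uniformity_normalized": float(np.sum(pi**2)),
        "gray_level_variance": float(np.sum((i - mu_i) ** 2 * p)),
        "high_gray_level_run_emphasis": float(np.sum(i**2 * p)),
        "long_run_emphasis": float(np.sum(j**2 * p)),
        "long_run_high_gray_level_emphasis": float(np.sum(i**2 * j**2 * p)),
        "long_run_low_gray_level_emphasis": float(np.sum(j**2 / i**2 * p)),
        "low_gray_level_run_emphasis": float(np.sum(p / i**2)),
        "run_entropy": float(-np.sum(pos * np.log2(pos))),
        "run_length_non_uniformity": float(np.sum(mat.sum(axis=0) ** 2) / nr),
        "run_length_non_uniformity_normalized": float(np.sum(pj**2)),
        "run_percentage": float(nr / n_p),
        "run_variance": float(np.sum((j - mu_j) ** 2 * p)),
        "short_run_emphasis": float(np.sum(p / j**2)),
        "short_run_high_gray_level_emphasis": float(np.sum(i**2 / j**2 * p)),
        "short_run_low_gray_level_emphasis": float(np.sum(p / (i**2 * j**2))),
    }


def glrlm_features(
    q: QuantizedPatch, directions: Iterable[int] = (0, 45, 90, 135)
) -> dict[str, float]:
    """16 GLRLM features averaged over the requested directions."""
    mats = glrlm_matrix(q, directions=directions)
    if not mats:
        warnings.warn("GLRLM: no runs in any direction")
        return {name: float("nan") for name in GLRLM_NAMES}
    per_dir = [_rl_features(m, q.n_p) for m in mats.values()]
    return {
        name: float(np.mean([d[name] for d in per_dir])) for name in GLRLM_NAMES
    }


# ---------------------------------------------------------------------------
# GLSZM
# ---------------------------------------------------------------------------

def glszm_matrix(q: QuantizedPatch) -> np.ndarray:
    """P(i, j): number of 8-connected zones of level i and size j."""
    masked = np.where(q.mask, q.levels, 0)
    # skimage connects neighbouring pixels only when they share a value, so
    # one labelling pass yields every constant-level zone at once
    lab, n_zones = measure.label(masked, connectivity=2, background=0, return_num=True)
    sizes = np.bincount(lab.ravel())[1:]
    zone_level = np.zeros(n_zones + 1, dtype=np.int64)
    zone_level[lab] = masked
    mat = np.zeros((q.n_g, int(sizes.max())))
    np.add.at(mat, (zone_level[1:] - 1, sizes - 1), 1.0)
    return mat


def glszm_features(q: QuantizedPatch) -> dict[str, float]:
    """16 GLSZM features from 8-connected constant-level zones."""
    mat = glszm_matrix(q)
    nz = mat.sum()
    p = mat / nz
    i = np.arange(1, mat.shape[0] + 1, dtype=np.float64)[:, None]
    j = np.arange(1, mat.shape[1] + 1, dtype=np.float64)[None, :]
    pi = p.sum(axis=1)
    pj = p.sum(axis=0)
    mu_i = float(np.sum(i[:, 0] * pi))
    mu_j = float(np.sum(j[0, :] * pj))
    pos = p[p > 0]
    return {
        "gray_level_non_uniformity": float(np.sum(mat.sum(axis=1) ** 2) / nz),
        "gray_level_non_uniformity_normalized": float(np.sum(pi**2)),
        "gray_level_variance": float(np.sum((i - mu_i) ** 2 * p)),
        "high_gray_level_zone_emphasis": float(np.sum(i**2 * p)),
        "large_area_emphasis": float(np.sum(j**2 * p)),
        "large_area_high_gray_level_emphasis": float(np.sum(i**2 * j**2 * p)),
        "large_area_low_gray_level_emphasis": float(np.sum(j**2 / i**2 * p)),
        "low_gray_level_zone_emphasis": float(np.sum(p / i**2)),
        "size_zone_non_uniformity": float(np.sum(mat.sum(axis=0) ** 2) / nz),
        "size_zone_non_uniformity_normalized": float(np.sum(pj**2)),
        "small_area_emphasis": float(np.sum(p / j**2)),
        "small_area_high_gray_level_emphasis": float(np.sum(i**2 / j**2 * p)),
        "small_area_low_gray_level_emphasis": float(np.sum(p / (i**2 * j**2))),
        "zone_entropy": float(-np.sum(pos * np.log2(pos))),
        "zone_percentage": float(nz / q.n_p),
        "zone_variance": float(np.sum((j - mu_j) ** 2 * p)),
    }


# ---------------------------------------------------------------------------
# Full panel
# ---------------------------------------------------------------------------

def extract_all(
    patch: np.ndarray,
    mask: np.ndarray,
    bin_width: float = 25.0,
    delta: int = 1,
    alpha: int = 0,
    directions: Iterable[int] = (0, 45, 90, 135),
) -> dict[str, float]:
    """All 93 features keyed by canonical ``<family>_<feature>`` name."""
    q = discretize(patch, mask, bin_width)
    by_family = {
        "FOS": fos_features(patch, mask, bin_width),
        "GLCM": glcm_features(q, delta=delta, directions=directions),
        "NGTDM": ngtdm_features(q, delta=delta),
        "GLDM": gldm_features(q, delta=delta, alpha=alpha),
        "GLRLM": glrlm_features(q, directions=directions),
        "GLSZM": glszm_features(q),
    }
    out: dict[str, float] = {}
    for family in FAMILIES:
        values = by_family[family]
        for name in FAMILY_NAMES[family]:
            out[f"{family.lower()}_{name}"] = values[name]
    return out
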