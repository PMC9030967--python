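"""Independent brute-force oracles: direct loops over pixels, pairs, runs,
zones and neighbourhoods. Deliberately slow and simple — these check the
vectorized implementations, so they share no code with them."""

from __future__ import annotations

import math

import numpy as np


def pad_replicate(img: np.ndarray, r: int) -> np.ndarray:
    return np.pad(img, r, mode="edge")


def mean_bf(img: np.ndarray, w: int) -> np.ndarray:
    r = w // 2
    p = pad_replicate(img, r)
    out = np.empty_like(img, dtype=float)
    for i in range(img.shape[0]):
        for j in range(img.shape[1]):
            out[i, j] = p[i : i + w, j : j + w].mean()
    return out


def median_bf(img: np.ndarray, w: int) -> np.ndarray:
    r = w // 2
    p = pad_replicate(img, r)
    out = np.empty_like(img, dtype=float)
    for i in range(img.shape[0]):
        for j in range(img.shape[1]):
            out[i, j] = np.median(p[i : i + w, j : j + w])
    return out


def conv2_bf(img: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Direct correlation with replicate border padding."""
    kh, kw = kernel.shape
    rh, rw = kh // 2, kw // 2
    p = np.pad(img, ((rh, rh), (rw, rw)), mode="edge")
    out = np.empty_like(img, dtype=float)
    for i in range(img.shape[0]):
        for j in range(img.shape[1]):
            out[i, j] = np.sum(p[i : i + kh, j : j + kw] * kernel)
    return out


def binomial_bf(img: np.ndarray, repetitions: int) -> np.ndarray:
    k1 = np.array([1.0, 2.0, 1.0]) / 4.0
    kernel = np.outer(k1, k1)
    out = img.astype(float)
    for _ in range(repetitions):
        out = conv2_bf(out, kernel)
    return out


def laplacian_sharpen_bf(img: np.ndarray) -> np.ndarray:
    lap = np.array([[0.0, 1.0, 0.0], [1.0, -4.0, 1.0], [0.0, 1.0, 0.0]])
    return img - conv2_bf(img, lap)


def bilateral_bf(img: np.ndarray, domain_sigma: float, range_sigma: float) -> np.ndarray:
    radius = max(1, int(math.ceil(2.5 * domain_sigma)))
    p = pad_replicate(img, radius)
    out = np.empty_like(img, dtype=float)
    for i in range(img.shape[0]):
        for j in range(img.shape[1]):
            num = den = 0.0
            for di in range(-radius, radius + 1):
                for dj in range(-radius, radius + 1):
                    v = p[i + radius + di, j + radius + dj]
                    wgt = math.exp(
                        -(di * di + dj * dj) / (2 * domain_sigma**2)
                        - (v - img[i, j]) ** 2 / (2 * range_sigma**2)
                    )
                    num += wgt * v
                    den += wgt
            out[i, j] = num / den
    return out


def gaussian_fir_bf(img: np.ndarray, sigma: float, truncate: float = 4.0) -> np.ndarray:
    """Direct FIR Gaussian: 2D convolution with the sampled, normalized kernel."""
    radius = int(truncate * sigma + 0.5)
    x = np.arange(-radius, radius + 1)
    k1 = np.exp(-(x**2) / (2.0 * sigma**2))
    k1 /= k1.sum()
    return conv2_bf(img, np.outer(k1, k1))


def curvature_flow_bf(img: np.ndarray, iterations: int, dt: float) -> np.ndarray:
    """Pixelwise explicit curvature flow with edge-replicated ghost pixels."""
    out = img.astype(float).copy()
    h, w = img.shape
    for _ in range(iterations):
        p = np.pad(out, 1, mode="edge")
        nxt = out.copy()
        for i in range(h):
            for j in range(w):
                c = p[i + 1, j + 1]
                ix = (p[i + 1, j + 2] - p[i + 1, j]) / 2.0
                iy = (p[i + 2, j + 1] - p[i, j + 1]) / 2.0
                ixx = p[i + 1, j + 2] - 2 * c + p[i + 1, j]
                iyy = p[i + 2, j + 1] - 2 * c + p[i, j + 1]
                ixy = (p[i + 2, j + 2] - p[i + 2, j] - p[i, j + 2] + p[i, j]) / 4.0
                g2 = ix * ix + iy * iy
                if g2 > 1e-12:
                    speed = (ixx * iy * iy - 2 * ix * iy * ixy + iyy * ix * ix) / (
                        g2 + 1e-12
                    )
                else:
                    speed = 0.0
                nxt[i, j] = c + dt * speed
        out = nxt
    return out


# --- texture matrices -------------------------------------------------------

ANGLE_OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


def glcm_bf(levels: np.ndarray, mask: np.ndarray, n_g: int, angle: int, delta: int = 1):
    """Symmetric normalized co-occurrence matrix by pair enumeration."""
    dr, dc = ANGLE_OFFSETS[angle]
    dr, dc = dr * delta, dc * delta
    h, w = levels.shape
    mat = np.zeros((n_g, n_g))
    for i in range(h):
        for j in range(w):
            if not mask[i, j]:
                continue
            i2, j2 = i + dr, j + dc
            if 0 <= i2 < h and 0 <= j2 < w and mask[i2, j2]:
                a, b = levels[i, j] - 1, levels[i2, j2] - 1
                mat[a, b] += 1
                mat[b, a] += 1
    s = mat.sum()
    return mat / s if s > 0 else None


def glrlm_bf(levels: np.ndarray, mask: np.ndarray, n_g: int, angle: int):
    """Run length matrix by walking every line pixel-by-pixel."""
    dr, dc = ANGLE_OFFSETS[angle]
    h, w = levels.shape
    lv = np.where(mask, levels, 0)
    max_len = max(h, w)
    mat = np.zeros((n_g, max_len))
    visited = np.zeros((h, w), dtype=bool)
    for i in range(h):
        for j in range(w):
            if lv[i, j] == 0 or visited[i, j]:
                continue
            pi, pj = i - dr, j - dc
            # only start a run at the head of its line segment
            if 0 <= pi < h and 0 <= pj < w and lv[pi, pj] == lv[i, j]:
                continue
            length = 0
            ci, cj = i, j
            while 0 <= ci < h and 0 <= cj < w and lv[ci, cj] == lv[i, j]:
                visited[ci, cj] = True
                length += 1
                ci, cj = ci + dr, cj + dc
            mat[lv[i, j] - 1, length - 1] += 1
    visited[:] = False
    return mat if mat.sum() > 0 else None


def glszm_bf(levels: np.ndarray, mask: np.ndarray, n_g: int):
    """Size zone matrix by breadth-first flood fill (8-connected)."""
    h, w = levels.shape
    lv = np.where(mask, levels, 0)
    seen = np.zeros((h, w), dtype=bool)
    zones = []
    for i in range(h):
        for j in range(w):
            if lv[i, j] == 0 or seen[i, j]:
                continue
            level = lv[i, j]
            queue = [(i, j)]
            seen[i, j] = True
            size = 0
            while queue:
                ci, cj = queue.pop()
                size += 1
                for di in (-1, 0, 1):
                    for dj in (-1, 0, 1):
                        ni, nj = ci + di, cj + dj
                        if (
                            0 <= ni < h
                            and 0 <= nj < w
                            and not seen[ni, nj]
                            and lv[ni, nj] == level
                        ):
                            seen[ni, nj] = True
                            queue.append((ni, nj))
            zones.append((level, size))
    max_size = max(size for _, size in zones)
    mat = np.zeros((n_g, max_size))
    for level, size in zones:
        mat[level - 1, size - 1] += 1
    return mat


def gldm_bf(levels: np.ndarray, mask: np.ndarray, n_g: int, delta: int = 1, alpha: int = 0):
    """Dependence matrix by counting dependent neighbours per pixel."""
    h, w = levels.shape
    max_dep = (2 * delta + 1) ** 2 - 1
    mat = np.zeros((n_g, max_dep + 1))
    for i in range(h):
        for j in range(w):
            if not mask[i, j]:
                continue
            dep = 0
            for di in range(-delta, delta + 1):
                for dj in range(-delta, delta + 1):
                    if (di, dj) == (0, 0):
                        continue
                    ni, nj = i + di, j + dj
                    if (
                        0 <= ni < h
                        and 0 <= nj < w
                        and mask[ni, nj]
                        and abs(int(levels[ni, nj]) - int(levels[i, j])) <= alpha
                    ):
                        dep += 1
            mat[levels[i, j] - 1, dep] += 1
    return mat


def ngtdm_bf(levels: np.ndarray, mask: np.ndarray, n_g: int, delta: int = 1):
    """(n_i, p_i, s_i) by direct neighbourhood-mean enumeration."""
    h, w = levels.shape
    n = np.zeros(n_g)
    s = np.zeros(n_g)
    for i in range(h):
        for j in range(w):
            if not mask[i, j]:
                continue
            vals = []
            for di in range(-delta, delta + 1):
                for dj in range(-delta, delta + 1):
                    if (di, dj) == (0, 0):
                        continue
                    ni, nj = i + di, j + dj
                    if 0 <= ni < h and 0 <= nj < w and mask[ni, nj]:
                        vals.append(levels[ni, nj])
            if not vals:
                continue
            lv = levels[i, j]
            n[lv - 1] += 1
            s[lv - 1] += abs(lv - sum(vals) / len(vals))
    tot = n.sum()
    p = n / tot if tot > 0 else n
    return n, p, s
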