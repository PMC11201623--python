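"""Numba kernels for per-voxel co-occurrence (Haralick / gradient-orientation)
statistics.

Each mask voxel gets its own co-occurrence matrix, built from label pairs at
the configured offsets inside a window centered on the voxel (both endpoints
must lie in the window and in the mask), symmetrized, normalized, and reduced
to the 13 classical Haralick statistics. Entropies use log base 2 with the
0*log(0) = 0 convention.
"""

from __future__ import annotations

import numpy as np
from numba import njit

#: Order of the emitted statistics (fixed across the package).
HARALICK_STAT_NAMES = (
    "energy",
    "contrast",
    "correlation",
    "variance",
    "inverse_difference_moment",
    "sum_average",
    "sum_variance",
    "sum_entropy",
    "entropy",
    "difference_variance",
    "difference_entropy",
    "imc1",
    "imc2",
)

_LOG2 = 0.6931471805599453  # ln 2


@njit(cache=True)
def _log2(x):
    return np.log(x) / _LOG2


@njit(cache=True)
def glcm_statistics(counts):
    """13 Haralick statistics of a (symmetric) co-occurrence count matrix.

    A degenerate matrix (all pairs in a single cell, or no pairs at all)
    yields energy 1, entropies 0, contrast 0 and correlation 0.
    """
    L = counts.shape[0]
    out = np.zeros(13)
    total = 0.0
    for i in range(L):
        for j in range(L):
            total += counts[i, j]
    if total <= 0.0:
        out[0] = 1.0  # energy of an (empty ⇒ degenerate single-cell) GLCM
        return out

    px = np.zeros(L)
    pxy_sum = np.zeros(2 * L - 1)  # index k = i + j
    pxy_diff = np.zeros(L)  # index k = |i - j|
    energy = 0.0
    contrast = 0.0
    idm = 0.0
    entropy = 0.0
    corr_num = 0.0
    for i in range(L):
        for j in range(L):
            p = counts[i, j] / total
            if p <= 0.0:
                continue
            px[i] += p
            pxy_sum[i + j] += p
            pxy_diff[abs(i - j)] += p
            energy += p * p
            contrast += (i - j) * (i - j) * p
            idm += p / (1.0 + (i - j) * (i - j))
            entropy -= p * _log2(p)
            corr_num += i * j * p

    mu = 0.0
    for i in range(L):
        mu += i * px[i]
    var = 0.0
    for i in range(L):
        var += (i - mu) * (i - mu) * px[i]
    if var > 1e-12:
        correlation = (corr_num - mu * mu) / var
    else:
        correlation = 0.0

    sum_avg = 0.0
    for k in range(2 * L - 1):
        sum_avg += k * pxy_sum[k]
    sum_var = 0.0
    sum_ent = 0.0
    for k in range(2 * L - 1):
        if pxy_sum[k] > 0.0:
            sum_var += (k - sum_avg) * (k - sum_avg) * pxy_sum[k]
            sum_ent -= pxy_sum[k] * _log2(pxy_sum[k])

    diff_avg = 0.0
    for k in range(L):
        diff_avg += k * pxy_diff[k]
    diff_var = 0.0
    diff_ent = 0.0
    for k in range(L):
        if pxy_diff[k] > 0.0:
            diff_var += (k - diff_avg) * (k - diff_avg) * pxy_diff[k]
            diff_ent -= pxy_diff[k] * _log2(pxy_diff[k])

    # information measures of correlation (symmetric GLCM: py = px)
    hx = 0.0
    for i in range(L):
        if px[i] > 0.0:
            hx -= px[i] * _log2(px[i])
    hxy1 = 0.0
    hxy2 = 0.0
    for i in range(L):
        for j in range(L):
            pp = px[i] * px[j]
            if pp > 0.0:
                lg = _log2(pp)
                hxy2 -= pp * lg
                p = counts[i, j] / total
                if p > 0.0:
                    hxy1 -= p * lg
    if hx > 1e-12:
        imc1 = (entropy - hxy1) / hx
    else:
        imc1 = 0.0
    arg = 1.0 - np.exp(-2.0 * (hxy2 - entropy))
    imc2 = np.sqrt(arg) if arg > 0.0 else 0.0

    out[0] = energy
    out[1] = contrast
    out[2] = correlation
    out[3] = var
    out[4] = idm
    out[5] = sum_avg
    out[6] = sum_var
    out[7] = sum_ent
    out[8] = entropy
    out[9] = diff_var
    out[10] = diff_ent
    out[11] = imc1
    out[12] = imc2
    return out


@njit(cache=True)
def per_voxel_glcm_stats_3d(labels, mask, coords, n_levels, radius, offsets):
    """13 Haralick statistics per mask voxel from a 3D windowed GLCM.

    labels : int32 3D quantized values (only mask voxels are read)
    mask   : uint8 3D
    coords : (n, 3) int32 voxel coordinates at which to evaluate
    radius : window half-size (window edge = 2*radius + 1)
    offsets: (m, 3) int32 symmetric co-occurrence directions
    """
    n = coords.shape[0]
    out = np.zeros((n, 13))
    sx, sy, sz = labels.shape
    counts = np.zeros((n_levels, n_levels))
    for v in range(n):
        cx, cy, cz = coords[v, 0], coords[v, 1], coords[v, 2]
        counts[:, :] = 0.0
        x0, x1 = max(cx - radius, 0), min(cx + radius, sx - 1)
        y0, y1 = max(cy - radius, 0), min(cy + radius, sy - 1)
        z0, z1 = max(cz - radius, 0), min(cz + radius, sz - 1)
        for x in range(x0, x1 + 1):
            for y in range(y0, y1 + 1):
                for z in range(z0, z1 + 1):
                    if mask[x, y, z] == 0:
                        continue
                    a = labels[x, y, z]
                    for o in range(offsets.shape[0]):
                        px = x + offsets[o, 0]
                        py = y + offsets[o, 1]
                        pz = z + offsets[o, 2]
                        if px < x0 or px > x1 or py < y0 or py > y1 \
                                or pz < z0 or pz > z1:
                            continue
                        if mask[px, py, pz] == 0:
                            continue
                        b = labels[px, py, pz]
                        counts[a, b] += 1.0
                        counts[b, a] += 1.0  # symmetrize
        out[v] = glcm_statistics(counts)
    return out


@njit(cache=True)
def per_pixel_cooc_stats_2d(labels, mask, coords, n_levels, radius, offsets):
    """Same as the 3D kernel but for one 2D slice (orientation co-occurrence)."""
    n = coords.shape[0]
    out = np.zeros((n, 13))
    sx, sy = labels.shape
    counts = np.zeros((n_levels, n_levels))
    for v in range(n):
        cx, cy = coords[v, 0], coords[v, 1]
        counts[:, :] = 0.0
        x0, x1 = max(cx - radius, 0), min(cx + radius, sx - 1)
        y0, y1 = max(cy - radius, 0), min(cy + radius, sy - 1)
        for x in range(x0, x1 + 1):
            for y in range(y0, y1 + 1):
                if mask[x, y] == 0:
                    continue
                a = labels[x, y]
                for o in range(offsets.shape[0]):
                    px = x + offsets[o, 0]
                    py = y + offsets[o, 1]
                    if px < x0 or px > x1 or py < y0 or py > y1:
                        continue
                    if mask[px, py] == 0:
                        continue
                    b = labels[px, py]
                    counts[a, b] += 1.0
                    counts[b, a] += 1.0
        out[v] = glcm_statistics(counts)
    return out
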