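"""Per-voxel texture feature banks and their region-level aggregation.

Five families of per-voxel texture definitions are computed inside a tumor
region mask and each map is reduced to five first-order statistics (mean,
median, standard deviation, skewness, kurtosis):

======================  =====  ==========================================
family                  maps   description
======================  =====  ==========================================
gradient                13     derivative / local-statistics operators
haralick                13     windowed 3D gray-level co-occurrence stats
laws                    125    all 5^3 separable Laws energy combinations
gabor                   50     per-slice 2D Gabor magnitudes (5 λ x 10 θ)
collage                 13     co-occurrence stats of locally dominant
                               gradient orientations ("gradient entropy")
======================  =====  ==========================================

214 per-voxel definitions x 5 statistics = 1070 values per region.
Convolution edge handling is replicate padding throughout; entropies use
log base 2.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd
from scipy import ndimage

from ._cooccurrence import (
    HARALICK_STAT_NAMES,
    per_pixel_cooc_stats_2d,
    per_voxel_glcm_stats_3d,
)
from .containers import Volume

STAT_NAMES = ("mean", "median", "std", "skewness", "kurtosis")

LAWS_KERNELS = {
    "L5": np.array([1.0, 4.0, 6.0, 4.0, 1.0]),
    "E5": np.array([-1.0, -2.0, 0.0, 2.0, 1.0]),
    "S5": np.array([-1.0, 0.0, 2.0, 0.0, -1.0]),
    "R5": np.array([1.0, -4.0, 6.0, -4.0, 1.0]),
    "W5": np.array([-1.0, 2.0, 0.0, -2.0, 1.0]),
}

GRADIENT_NAMES = (
    "dx", "dy", "dz", "gradient_magnitude",
    "sobel_x", "sobel_y", "sobel_z", "sobel_magnitude",
    "laplacian", "local_mean", "local_std", "local_range",
    "directional_max",
)


def _symmetric_offsets_3d() -> np.ndarray:
    """The 13 unique 3D directions among the 26 unit-cube neighbors."""
    offs = [d for d in product((-1, 0, 1), repeat=3) if d != (0, 0, 0) and d > (0, 0, 0)]
    return np.asarray(offs, dtype=np.int32)


@dataclass
class TextureBankConfig:
    """Configuration of all five texture banks (defaults = canonical bank)."""

    # haralick
    n_gray_levels: int = 64
    haralick_window: int = 5
    robust_quantization: bool = False  # clip at 1st/99th percentile before binning
    # laws
    laws_energy_window: int = 5
    # gabor
    gabor_wavelengths_vox: tuple[float, ...] = (2.0, 4.0, 8.0, 16.0, 32.0)
    gabor_n_orientations: int = 10
    # collage
    collage_window: int = 5
    collage_gradient_window: int = 5
    collage_orientation_bins: int = 64

    def __post_init__(self) -> None:
        if self.n_gray_levels < 2:
            raise ValueError("need at least 2 gray levels")
        for w in (self.haralick_window, self.laws_energy_window,
                  self.collage_window, self.collage_gradient_window):
            if w < 1 or w % 2 == 0:
                raise ValueError("windows must be odd and positive")

    # -- enumeration of the bank -------------------------------------------
    def family_feature_names(self) -> dict[str, list[str]]:
        laws = ["".join(c) for c in product(LAWS_KERNELS, repeat=3)]
        gabor = [
            f"lam{int(l) if float(l).is_integer() else l}_theta{k}"
            for l in self.gabor_wavelengths_vox
            for k in range(self.gabor_n_orientations)
        ]
        return {
            "gradient": list(GRADIENT_NAMES),
            "haralick": list(HARALICK_STAT_NAMES),
            "laws": laws,
            "gabor": gabor,
            "collage": list(HARALICK_STAT_NAMES),
        }

    @property
    def n_definitions(self) -> int:
        return sum(len(v) for v in self.family_feature_names().values())


DEFAULT_TEXTURE_CONFIG = TextureBankConfig()


# ---------------------------------------------------------------------------
# shared plumbing
# ---------------------------------------------------------------------------

def _as_data(volume) -> np.ndarray:
    return volume.data if isinstance(volume, Volume) else np.asarray(volume, float)


def _bbox_crop(data: np.ndarray, mask: np.ndarray, margin: int):
    """Crop to the mask bounding box expanded by ``margin`` (clipped to grid)."""
    idx = np.nonzero(mask)
    lo = [max(int(i.min()) - margin, 0) for i in idx]
    hi = [min(int(i.max()) + margin + 1, n) for i, n in zip(idx, data.shape)]
    sl = tuple(slice(a, b) for a, b in zip(lo, hi))
    return data[sl], mask[sl]


def _require_mask(mask: np.ndarray) -> np.ndarray:
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    return mask


def _quantize(data: np.ndarray, mask: np.ndarray, cfg: TextureBankConfig) -> np.ndarray:
    """Uniform quantization of masked intensities to 0..L-1 over min-max
    (or the 1st-99th percentile range with ``robust_quantization``)."""
    vals = data[mask]
    if cfg.robust_quantization:
        lo, hi = np.percentile(vals, [1, 99])
    else:
        lo, hi = float(vals.min()), float(vals.max())
    L = cfg.n_gray_levels
    q = np.zeros(data.shape, dtype=np.int32)
    if hi > lo:
        scaled = (data - lo) / (hi - lo) * L
        q = np.clip(np.floor(scaled), 0, L - 1).astype(np.int32)
    return q


# ---------------------------------------------------------------------------
# gradient family (13 maps)
# ---------------------------------------------------------------------------

def compute_gradient_maps(volume, mask: np.ndarray) -> dict[str, np.ndarray]:
    """13 derivative/local-statistics maps sampled at mask voxels."""
    mask = _require_mask(mask)
    data, m = _bbox_crop(_as_data(volume), mask, margin=2)
    pad = np.pad(data, 1, mode="edge")
    core = (slice(1, -1),) * 3

    maps: dict[str, np.ndarray] = {}
    grads = np.gradient(pad)
    maps["dx"], maps["dy"], maps["dz"] = (g[core] for g in grads)
    maps["gradient_magnitude"] = np.sqrt(
        maps["dx"] ** 2 + maps["dy"] ** 2 + maps["dz"] ** 2
    )
    for ax, name in enumerate(("sobel_x", "sobel_y", "sobel_z")):
        maps[name] = ndimage.sobel(data, axis=ax, mode="nearest")
    maps["sobel_magnitude"] = np.sqrt(
        maps["sobel_x"] ** 2 + maps["sobel_y"] ** 2 + maps["sobel_z"] ** 2
    )
    maps["laplacian"] = ndimage.laplace(data, mode="nearest")
    maps["local_mean"] = ndimage.uniform_filter(data, size=3, mode="nearest")
    sq_mean = ndimage.uniform_filter(data**2, size=3, mode="nearest")
    maps["local_std"] = np.sqrt(np.maximum(sq_mean - maps["local_mean"] ** 2, 0.0))
    maps["local_range"] = ndimage.maximum_filter(data, size=3, mode="nearest") - \
        ndimage.minimum_filter(data, size=3, mode="nearest")

    # Kirsch-style: strongest central-difference response over 13 directions
    best = np.zeros_like(data)
    for off in _symmetric_offsets_3d():
        step = np.linalg.norm(off)
        fwd = np.roll(pad, tuple(-off), axis=(0, 1, 2))[core]
        bwd = np.roll(pad, tuple(off), axis=(0, 1, 2))[core]
        best = np.maximum(best, np.abs(fwd - bwd) / (2.0 * step))
    maps["directional_max"] = best

    return {k: v[m] for k, v in maps.items()}


# ---------------------------------------------------------------------------
# Haralick family (13 maps)
# ---------------------------------------------------------------------------

def compute_haralick_maps(volume, mask: np.ndarray,
                          cfg: TextureBankConfig = DEFAULT_TEXTURE_CONFIG
                          ) -> dict[str, np.ndarray]:
    """Per-voxel Haralick statistics of the windowed, offset-pooled 3D GLCM."""
    mask = _require_mask(mask)
    data, m = _bbox_crop(_as_data(volume), mask, margin=cfg.haralick_window // 2)
    quant = _quantize(data, m, cfg)
    coords = np.argwhere(m).astype(np.int32)
    out = per_voxel_glcm_stats_3d(
        quant, m.astype(np.uint8), coords, cfg.n_gray_levels,
        cfg.haralick_window // 2, _symmetric_offsets_3d(),
    )
    return {name: out[:, i] for i, name in enumerate(HARALICK_STAT_NAMES)}


# ---------------------------------------------------------------------------
# Laws family (125 maps)
# ---------------------------------------------------------------------------

def compute_laws_maps(volume, mask: np.ndarray,
                      cfg: TextureBankConfig = DEFAULT_TEXTURE_CONFIG
                      ) -> dict[str, np.ndarray]:
    """Laws texture energy: |response| averaged over the energy window, for
    all 5^3 separable kernel combinations (axis order x, y, z)."""
    mask = _require_mask(mask)
    margin = 2 + cfg.laws_energy_window // 2
    data, m = _bbox_crop(_as_data(volume), mask, margin=margin)

    # stage the separable convolutions to share partial results
    stage1 = {a: ndimage.convolve1d(data, k, axis=0, mode="nearest")
              for a, k in LAWS_KERNELS.items()}
    maps: dict[str, np.ndarray] = {}
    for a, r1 in stage1.items():
        for b, kb in LAWS_KERNELS.items():
            r2 = ndimage.convolve1d(r1, kb, axis=1, mode="nearest")
            for c, kc in LAWS_KERNELS.items():
                r3 = ndimage.convolve1d(r2, kc, axis=2, mode="nearest")
                energy = ndimage.uniform_filter(
                    np.abs(r3), size=cfg.laws_energy_window, mode="nearest"
                )
                maps[f"{a}{b}{c}"] = energy[m]
    return maps


# ---------------------------------------------------------------------------
# Gabor family (50 maps)
# ---------------------------------------------------------------------------

def _gabor_kernel_1d(wavelength: float, theta: float
                     ) -> tuple[np.ndarray, np.ndarray, float]:
    """Separable factors of a complex 2D Gabor kernel with ~1-octave
    bandwidth: an isotropic Gaussian envelope times exp(2i*pi*(ax + by))
    factors into two complex 1D kernels. Returns (kx, ky, dc) where ``dc``
    is the mean of the real part of the full 2D kernel (used to enforce an
    exactly zero DC response)."""
    sigma = wavelength * 0.5622  # (1/pi)*sqrt(ln2/2)*(2^b+1)/(2^b-1), b=1
    radius = int(np.ceil(3.0 * sigma))
    t = np.arange(-radius, radius + 1, dtype=float)
    env = np.exp(-(t**2) / (2.0 * sigma**2))
    env /= env.sum()  # unit-gain envelope: responses comparable across scales
    kx = env * np.exp(2j * np.pi * np.cos(theta) * t / wavelength)
    ky = env * np.exp(2j * np.pi * np.sin(theta) * t / wavelength)
    dc = float(np.outer(kx, ky).real.mean())
    return kx, ky, dc


def _complex_convolve1d(data: np.ndarray, kern: np.ndarray, axis: int
                        ) -> np.ndarray:
    out_r = ndimage.convolve1d(data.real, kern.real, axis=axis, mode="nearest") \
        - ndimage.convolve1d(data.imag, kern.imag, axis=axis, mode="nearest")
    out_i = ndimage.convolve1d(data.real, kern.imag, axis=axis, mode="nearest") \
        + ndimage.convolve1d(data.imag, kern.real, axis=axis, mode="nearest")
    return out_r + 1j * out_i


def compute_gabor_maps(volume, mask: np.ndarray,
                       cfg: TextureBankConfig = DEFAULT_TEXTURE_CONFIG
                       ) -> dict[str, np.ndarray]:
    """Magnitude of complex 2D Gabor responses per axial slice (axis 2).

    Kernels are applied as separable complex 1D convolutions; the DC
    component of the (real part of the) kernel is subtracted via a box-mean
    correction, so a constant image yields exactly zero response.
    """
    mask = _require_mask(mask)
    data, m = _bbox_crop(_as_data(volume), mask, margin=1)

    kernels = {}
    for lam in cfg.gabor_wavelengths_vox:
        for k in range(cfg.gabor_n_orientations):
            theta = k * np.pi / cfg.gabor_n_orientations
            lam_tag = int(lam) if float(lam).is_integer() else lam
            kernels[f"lam{lam_tag}_theta{k}"] = _gabor_kernel_1d(lam, theta)

    nvox = int(m.sum())
    maps = {name: np.empty(nvox) for name in kernels}
    order = np.argwhere(m)
    pos = 0
    for z in range(data.shape[2]):
        sl_mask = m[:, :, z]
        if not sl_mask.any():
            continue
        n_here = int(sl_mask.sum())
        img = data[:, :, z].astype(complex)
        box_means = {}
        for name, (kx, ky, dc) in kernels.items():
            resp = _complex_convolve1d(_complex_convolve1d(img, kx, 0), ky, 1)
            # subtract the DC term: conv with the zero-mean kernel equals
            # conv with the raw kernel minus kernel-mean * window box sum
            size = len(kx)
            if size not in box_means:
                box_means[size] = ndimage.uniform_filter(
                    data[:, :, z], size=size, mode="nearest") * size * size
            resp = resp - dc * box_means[size]
            maps[name][pos:pos + n_here] = np.abs(resp)[sl_mask]
        pos += n_here
    # reorder from slice-major to np.nonzero(mask) order
    slice_major = np.lexsort((order[:, 1], order[:, 0], order[:, 2]))
    inv = np.empty_like(slice_major)
    inv[slice_major] = np.arange(len(slice_major))
    return {k: v[inv] for k, v in maps.items()}


# ---------------------------------------------------------------------------
# COLLAGE family (13 maps)
# ---------------------------------------------------------------------------

def _dominant_orientation(img: np.ndarray, window: int) -> np.ndarray:
    """Per-pixel dominant gradient orientation in [0, pi) via the principal
    component of the gradient vectors in a window (structure tensor)."""
    gx, gy = np.gradient(img)
    sxx = ndimage.uniform_filter(gx * gx, size=window, mode="nearest")
    syy = ndimage.uniform_filter(gy * gy, size=window, mode="nearest")
    sxy = ndimage.uniform_filter(gx * gy, size=window, mode="nearest")
    theta = 0.5 * np.arctan2(2.0 * sxy, sxx - syy)
    theta = np.mod(theta, np.pi)
    flat = (sxx + syy) < 1e-12  # zero-gradient convention: orientation 0
    theta[flat] = 0.0
    return theta


def compute_collage_maps(volume, mask: np.ndarray,
                         cfg: TextureBankConfig = DEFAULT_TEXTURE_CONFIG
                         ) -> dict[str, np.ndarray]:
    """Co-occurrence statistics of quantized dominant gradient orientations
    (per axial slice); the entropy map is the canonical "gradient entropy"."""
    mask = _require_mask(mask)
    data, m = _bbox_crop(_as_data(volume), mask, margin=cfg.collage_window // 2)
    nbin = cfg.collage_orientation_bins
    offsets = np.asarray([(0, 1), (1, 0), (1, 1), (1, -1)], dtype=np.int32)

    nvox = int(m.sum())
    out_all = np.empty((nvox, 13))
    order = np.argwhere(m)
    pos = 0
    for z in range(data.shape[2]):
        sl_mask = m[:, :, z]
        if not sl_mask.any():
            continue
        theta = _dominant_orientation(data[:, :, z], cfg.collage_gradient_window)
        bins = np.minimum((theta / np.pi * nbin).astype(np.int32), nbin - 1)
        coords = np.argwhere(sl_mask).astype(np.int32)
        res = per_pixel_cooc_stats_2d(
            bins, sl_mask.astype(np.uint8), coords, nbin,
            cfg.collage_window // 2, offsets,
        )
        out_all[pos:pos + len(coords)] = res
        pos += len(coords)
    slice_major = np.lexsort((order[:, 1], order[:, 0], order[:, 2]))
    inv = np.empty_like(slice_major)
    inv[slice_major] = np.arange(len(slice_major))
    out_all = out_all[inv]
    return {name: out_all[:, i] for i, name in enumerate(HARALICK_STAT_NAMES)}


# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------

def aggregate_stats(values: np.ndarray) -> tuple[float, float, float, float, float]:
    """(mean, median, std[n-1], Fisher skewness, excess kurtosis).

    Convention: a constant sample has std = skewness = kurtosis = 0.
    """
    values = np.asarray(values, dtype=float).ravel()
    if values.size == 0:
        raise ValueError("cannot aggregate an empty sample")
    mean = float(values.mean())
    median = float(np.median(values))
    if values.size < 2 or np.ptp(values) == 0.0:
        return (mean, median, 0.0, 0.0, 0.0)
    d = values - mean
    m2 = float(np.mean(d * d))
    m3 = float(np.mean(d * d * d))
    m4 = float(np.mean(d * d * d * d))
    n = values.size
    std = float(np.sqrt(m2 * n / (n - 1)))
    skew = m3 / m2**1.5          # Fisher g1 (biased moment estimator)
    kurt = m4 / (m2 * m2) - 3.0  # excess kurtosis g2
    return (mean, median, std, skew, kurt)


_FAMILY_FUNCS = {
    "gradient": lambda v, m, c: compute_gradient_maps(v, m),
    "haralick": compute_haralick_maps,
    "laws": compute_laws_maps,
    "gabor": compute_gabor_maps,
    "collage": compute_collage_maps,
}


def extract_texture_vector(volume, mask: np.ndarray,
                           cfg: TextureBankConfig = DEFAULT_TEXTURE_CONFIG,
                           region: str | None = None) -> pd.Series:
    """The full 1070-long texture vector for one region.

    Column names are ``family__feature__stat`` (prefixed with ``region__``
    when a region name is given), in fixed family → feature → statistic
    order.
    """
    mask = _require_mask(mask)
    expected = cfg.family_feature_names()
    names: list[str] = []
    values: list[float] = []
    prefix = f"{region}__" if region else ""
    for family, feat_names in expected.items():
        maps = _FAMILY_FUNCS[family](volume, mask, cfg)
        if list(maps) != feat_names:  # contract with the config enumeration
            raise RuntimeError(f"{family} bank emitted unexpected map names")
        for feat, vals in maps.items():
            for stat, x in zip(STAT_NAMES, aggregate_stats(vals)):
                names.append(f"{prefix}{family}__{feat}__{stat}")
                values.append(x)
    return pd.Series(values, index=names, dtype=float)


__all__ = [
    "TextureBankConfig",
    "DEFAULT_TEXTURE_CONFIG",
    "STAT_NAMES",
    "LAWS_KERNELS",
    "GRADIENT_NAMES",
    "HARALICK_STAT_NAMES",
    "compute_gradient_maps",
    "compute_haralick_maps",
    "compute_laws_maps",
    "compute_gabor_maps",
    "compute_collage_maps",
    "aggregate_stats",
    "extract_texture_vector",
]
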