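"""Intensity preprocessing applied before feature extraction.

Three steps, in the order a radiomics pipeline applies them:

1. :func:`correct_bias` — multiplicative low-frequency inhomogeneity ("bias
   field") removal by a low-order polynomial fit in the log-intensity domain.
2. :func:`learn_standard_scale` / :func:`standardize_intensities` —
   histogram-landmark intensity standardization (Nyul-style): a piecewise
   linear map sends each volume's landmark percentiles onto a standard scale
   learned as the across-volume mean of those percentiles.
3. :func:`resample_isotropic` — resampling to a common isotropic voxel size
   (trilinear for intensities, nearest-neighbor for label masks).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import combinations_with_replacement
from typing import Sequence

import numpy as np
from scipy import ndimage

from .containers import RegionMaskSet, Volume
from .exceptions import DegenerateHistogramError

DEFAULT_LANDMARKS = (1.0, 10.0, 20.0, 30.0, 40.0, 50.0, 60.0, 70.0, 80.0, 90.0, 99.0)


# ---------------------------------------------------------------------------
# Bias-field correction
# ---------------------------------------------------------------------------

def _poly_design(shape: tuple[int, int, int], degree: int,
                 idx: tuple[np.ndarray, ...]) -> np.ndarray:
    """Monomial design matrix x^i y^j z^k (i+j+k <= degree) at given voxels,
    with coordinates scaled to [-1, 1] for conditioning."""
    coords = [2.0 * idx[a] / max(shape[a] - 1, 1) - 1.0 for a in range(3)]
    cols = []
    for total in range(degree + 1):
        for powers in combinations_with_replacement(range(3), total):
            col = np.ones_like(coords[0], dtype=float)
            for a in powers:
                col = col * coords[a]
            cols.append(col)
    return np.stack(cols, axis=1)


def correct_bias(volume: Volume, body_mask: np.ndarray, poly_degree: int = 3) -> Volume:
    """Remove a smooth multiplicative bias field.

    A polynomial of total degree ``poly_degree`` is least-squares fitted to
    the log intensities inside ``body_mask``; the volume is divided by the
    exponentiated fit and the gain is renormalized so the mean intensity
    inside the mask is preserved.
    """
    body_mask = np.asarray(body_mask, dtype=bool)
    if not body_mask.any():
        raise ValueError("body mask is empty")
    data = volume.data
    if np.any(data[body_mask] <= 0):
        raise ValueError("bias correction requires positive intensities in the mask")

    idx_mask = np.nonzero(body_mask)
    n_mask = idx_mask[0].size
    # a deterministic subsample is ample for a 20-coefficient smooth fit
    max_fit_voxels = 40000
    if n_mask > max_fit_voxels:
        step = int(np.ceil(n_mask / max_fit_voxels))
        idx_mask = tuple(i[::step] for i in idx_mask)
    A = _poly_design(volume.shape, poly_degree, idx_mask)
    logi = np.log(data[idx_mask])
    coef, *_ = np.linalg.lstsq(A, logi, rcond=None)

    idx_all = tuple(g.ravel() for g in np.indices(volume.shape))
    field_hat = (_poly_design(volume.shape, poly_degree, idx_all) @ coef).reshape(volume.shape)
    corrected = data / np.exp(field_hat)
    mean_before = data[body_mask].mean()
    mean_after = corrected[body_mask].mean()
    corrected = corrected * (mean_before / mean_after)
    return volume.with_data(corrected)


# ---------------------------------------------------------------------------
# Histogram-landmark standardization
# ---------------------------------------------------------------------------

@dataclass
class StandardScale:
    """Landmark percentiles and their learned standard intensities."""

    landmark_percentiles: tuple[float, ...] = DEFAULT_LANDMARKS
    standard_values: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        p = np.asarray(self.landmark_percentiles, dtype=float)
        if len(p) < 2 or np.any(np.diff(p) <= 0) or p[0] <= 0 or p[-1] >= 100:
            raise ValueError("landmark percentiles must be strictly increasing in (0, 100)")
        if self.standard_values:
            v = np.asarray(self.standard_values, dtype=float)
            if len(v) != len(p):
                raise ValueError("standard_values length must match percentiles")
            if np.any(np.diff(v) <= 0):
                raise DegenerateHistogramError("standard scale is not strictly increasing")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"landmark_percentiles": list(self.landmark_percentiles),
                       "standard_values": list(self.standard_values)}, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "StandardScale":
        with open(path) as fh:
            d = json.load(fh)
        return cls(tuple(d["landmark_percentiles"]), tuple(d["standard_values"]))


def _masked_percentiles(volume: Volume, mask: np.ndarray | None,
                        percentiles: Sequence[float]) -> np.ndarray:
    vals = volume.data[np.asarray(mask, dtype=bool)] if mask is not None else volume.data.ravel()
    if vals.size == 0:
        raise ValueError("mask selects no voxels")
    q = np.percentile(vals, percentiles)  # linear interpolation convention
    if np.any(np.diff(q) <= 0):
        raise DegenerateHistogramError(
            "landmark percentiles are not strictly increasing (constant or "
            "near-constant intensities)"
        )
    return q


def learn_standard_scale(
    training_volumes: Sequence[Volume],
    masks: Sequence[np.ndarray | None] | None = None,
    percentiles: Sequence[float] = DEFAULT_LANDMARKS,
) -> StandardScale:
    """Average each landmark percentile over the training volumes."""
    if len(training_volumes) < 2:
        raise ValueError("need at least 2 training volumes")
    if masks is None:
        masks = [None] * len(training_volumes)
    qs = np.stack([
        _masked_percentiles(v, m, percentiles)
        for v, m in zip(training_volumes, masks)
    ])
    return StandardScale(tuple(float(p) for p in percentiles),
                         tuple(qs.mean(axis=0)))


def standardize_intensities(volume: Volume, mask: np.ndarray | None,
                            scale: StandardScale) -> Volume:
    """Map the volume's landmark percentiles onto the standard scale.

    Piecewise-linear between landmarks, linear extrapolation beyond the end
    landmarks using the terminal segment slopes; strictly increasing, so
    voxel intensity ordering is preserved.
    """
    if not scale.standard_values:
        raise ValueError("scale has no learned standard values")
    src = _masked_percentiles(volume, mask, scale.landmark_percentiles)
    dst = np.asarray(scale.standard_values, dtype=float)

    x = volume.data.ravel()
    y = np.interp(x, src, dst)
    lo, hi = x < src[0], x > src[-1]
    slope_lo = (dst[1] - dst[0]) / (src[1] - src[0])
    slope_hi = (dst[-1] - dst[-2]) / (src[-1] - src[-2])
    y[lo] = dst[0] + (x[lo] - src[0]) * slope_lo
    y[hi] = dst[-1] + (x[hi] - src[-1]) * slope_hi
    return volume.with_data(y.reshape(volume.shape))


# ---------------------------------------------------------------------------
# Resampling
# ---------------------------------------------------------------------------

def resample_isotropic(obj: Volume | RegionMaskSet,
                       target_spacing_mm: float | tuple[float, float, float] = 1.0):
    """Resample to the target spacing: trilinear for volumes, nearest for masks.

    Returns the same container type with an updated grid and affine; a
    no-op (data returned unchanged) when the spacing already matches.
    """
    if np.isscalar(target_spacing_mm):
        target = (float(target_spacing_mm),) * 3
    else:
        target = tuple(float(t) for t in target_spacing_mm)
    if any(t <= 0 for t in target):
        raise ValueError("target spacing must be positive")

    if isinstance(obj, Volume):
        data, order = obj.data, 1
    elif isinstance(obj, RegionMaskSet):
        data, order = obj.labels, 0
    else:
        raise TypeError(f"cannot resample {type(obj).__name__}")

    if np.allclose(obj.spacing, target):
        return obj

    zoom = np.asarray(obj.spacing) / np.asarray(target)
    out = ndimage.zoom(data.astype(float), zoom, order=order, mode="nearest",
                       grid_mode=True)
    affine = obj.affine.copy()
    affine[:3, :3] = affine[:3, :3] @ np.diag(1.0 / zoom)
    if isinstance(obj, Volume):
        return Volume(data=out, spacing=target, affine=affine)
    return RegionMaskSet(labels=np.rint(out).astype(np.int16), spacing=target,
                         affine=affine)


def preprocess_volume(volume: Volume, body_mask: np.ndarray | None = None,
                      scale: StandardScale | None = None,
                      poly_degree: int = 3,
                      target_spacing_mm: float | None = None) -> Volume:
    """Convenience chain: bias correction → standardization → resampling."""
    if body_mask is None:
        body_mask = np.ones(volume.shape, dtype=bool)
    out = correct_bias(volume, body_mask, poly_degree=poly_degree)
    if scale is not None:
        out = standardize_intensities(out, body_mask, scale)
    if target_spacing_mm is not None:
        out = resample_isotropic(out, target_spacing_mm)
    return out


__all__ = [
    "StandardScale",
    "DEFAULT_LANDMARKS",
    "correct_bias",
    "learn_standard_scale",
    "standardize_intensities",
    "resample_isotropic",
    "preprocess_volume",
]
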