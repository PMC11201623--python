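"""Core in-memory containers shared across the pipeline.

A :class:`Volume` wraps a 3D scalar grid with its voxel spacing and affine;
a :class:`RegionMaskSet` holds the multi-label tumor-subcompartment mask
(enhancing tumor, edema, non-enhancing tumor + cystic core) and derives the
habitat (their union); a :class:`SurvivalRecord` is one subject's
right-censored outcome plus site/subgroup metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import nibabel as nib
import numpy as np

# Canonical subcompartment labels (fixed across the pipeline).
LABEL_ENHANCING = 1
LABEL_EDEMA = 2
LABEL_NONENHANCING_CYST = 3

REGION_LABELS: Mapping[str, int] = {
    "enhancing": LABEL_ENHANCING,
    "edema": LABEL_EDEMA,
    "nonenhancing_cyst": LABEL_NONENHANCING_CYST,
}
#: Region keys accepted everywhere; ``habitat`` is the union of the three.
REGION_KEYS = ("enhancing", "edema", "nonenhancing_cyst", "habitat")


def _affine_from_spacing(spacing: tuple[float, float, float]) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    return aff


@dataclass
class Volume:
    """A 3D scalar image with voxel spacing in mm.

    Parameters
    ----------
    data
        3D array of intensities (arbitrary units); must be finite.
    spacing
        Voxel edge lengths in mm along each axis, all positive.
    affine
        4x4 voxel-to-world matrix; defaults to a diagonal built from
        ``spacing``.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D array, got {self.data.ndim}D")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite values")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be a positive triple, got {self.spacing}")
        if self.affine is None:
            self.affine = _affine_from_spacing(self.spacing)
        self.affine = np.asarray(self.affine, dtype=np.float64)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def with_data(self, data: np.ndarray) -> "Volume":
        return Volume(data=data, spacing=self.spacing, affine=self.affine.copy())

    # --- NIfTI round trip -------------------------------------------------
    def to_nifti(self) -> nib.Nifti1Image:
        img = nib.Nifti1Image(self.data.astype(np.float32), self.affine)
        img.header.set_zooms(self.spacing)
        return img

    def save(self, path) -> None:
        nib.save(self.to_nifti(), str(path))

    @classmethod
    def from_nifti(cls, path_or_img) -> "Volume":
        img = path_or_img
        if not isinstance(img, nib.Nifti1Image):
            img = nib.load(str(path_or_img))
        spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
        return cls(data=np.asarray(img.dataobj, dtype=np.float64),
                   spacing=spacing, affine=np.asarray(img.affine))


@dataclass
class RegionMaskSet:
    """Multi-label subcompartment mask sharing a grid with its Volume.

    ``labels`` holds 0 (background) plus the three subcompartment labels.
    The three labels are disjoint by construction of an integer label map;
    the habitat is computed, never stored.
    """

    labels: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("label map must be 3D")
        if not np.issubdtype(self.labels.dtype, np.integer):
            self.labels = np.rint(self.labels).astype(np.int16)
        extra = set(np.unique(self.labels)) - {0, *REGION_LABELS.values()}
        if extra:
            raise ValueError(f"unknown labels present: {sorted(extra)}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if self.affine is None:
            self.affine = _affine_from_spacing(self.spacing)
        self.affine = np.asarray(self.affine, dtype=np.float64)

    def region_mask(self, region: str) -> np.ndarray:
        """Binary mask for one region key (``habitat`` = union of all)."""
        if region == "habitat":
            return self.labels > 0
        try:
            return self.labels == REGION_LABELS[region]
        except KeyError:
            raise KeyError(
                f"unknown region {region!r}; expected one of {REGION_KEYS}"
            ) from None

    def nonempty_regions(self) -> list[str]:
        return [r for r in REGION_KEYS if self.region_mask(r).any()]

    def to_nifti(self) -> nib.Nifti1Image:
        img = nib.Nifti1Image(self.labels.astype(np.int16), self.affine)
        img.header.set_zooms(self.spacing)
        return img

    def save(self, path) -> None:
        nib.save(self.to_nifti(), str(path))

    @classmethod
    def from_nifti(cls, path_or_img) -> "RegionMaskSet":
        img = path_or_img
        if not isinstance(img, nib.Nifti1Image):
            img = nib.load(str(path_or_img))
        spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
        return cls(labels=np.asarray(img.dataobj), spacing=spacing,
                   affine=np.asarray(img.affine))


@dataclass(frozen=True)
class SurvivalRecord:
    """One subject's right-censored time-to-event outcome."""

    time_days: float
    event: int  # 1 = event observed, 0 = censored
    site: str = ""
    subgroup: str = ""
    age_years: float = float("nan")

    def __post_init__(self) -> None:
        if self.time_days <= 0:
            raise ValueError("survival time must be positive")
        if self.event not in (0, 1):
            raise ValueError("event flag must be 0 or 1")


__all__ = [
    "Volume",
    "RegionMaskSet",
    "SurvivalRecord",
    "REGION_LABELS",
    "REGION_KEYS",
    "LABEL_ENHANCING",
    "LABEL_EDEMA",
    "LABEL_NONENHANCING_CYST",
]
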