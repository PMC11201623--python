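"""Synthetic phantom cohorts with known ground-truth texture and shape effects.

Every downstream stage of the pipeline (preprocessing, texture and surface
feature extraction, risk modelling, site-wise validation) is exercised on
phantoms generated here: blob-shaped "tumors" with three nested
subcompartments, a controllable intra-tumoral Gaussian random texture field,
a controllable surface irregularity, and right-censored exponential survival
whose hazard is driven by the two latent parameters.

Each subject carries two latent standard-normal scores:

* ``z_tex`` — texture disorder; the noise amplitude inside the tumor is
  ``sigma0 * exp(slope * z_tex)``, so higher ``z_tex`` means a noisier,
  higher-entropy tumor interior.
* ``z_shape`` — surface irregularity; the core blob radius is perturbed by
  random low-order spherical-harmonic modes with relative amplitude
  ``irreg0 * exp(slope * z_shape)``.

Survival is proportional-hazards exponential:
``T ~ Exp(lambda0 * exp(beta_tex*z_tex + beta_shape*z_shape))`` with uniform
censoring on ``[0, censor_horizon]``. All generators are pure functions of
(parameters, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage, special

from .containers import (
    LABEL_EDEMA,
    LABEL_ENHANCING,
    LABEL_NONENHANCING_CYST,
    RegionMaskSet,
    SurvivalRecord,
    Volume,
)
from .exceptions import DegenerateShapeError

SUBGROUPS = ("G4", "SHH")

#: Per-site subgroup composition of the default 70-subject cohort
#: (site 1: 22 subjects, site 2: 31, site 3: 17).
DEFAULT_SITE_COMPOSITION = {
    "site1": {"G4": 14, "SHH": 8},
    "site2": {"G4": 18, "SHH": 13},
    "site3": {"G4": 16, "SHH": 1},
}


# ---------------------------------------------------------------------------
# Geometry primitives
# ---------------------------------------------------------------------------

def make_sphere_mask(
    radius_mm: float,
    center: tuple[float, float, float],
    grid_shape: tuple[int, int, int],
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> np.ndarray:
    """Binary mask of lattice points within ``radius_mm`` of ``center``.

    Raises :class:`DegenerateShapeError` if the radius is below one voxel
    spacing (the discretized ball would be empty or a single point).
    """
    spacing = tuple(float(s) for s in spacing)
    if radius_mm < min(spacing):
        raise DegenerateShapeError(
            f"radius {radius_mm} mm is below one voxel spacing {min(spacing)} mm"
        )
    grids = np.ogrid[tuple(slice(0, n) for n in grid_shape)]
    d2 = sum(((g - c) * s) ** 2 for g, c, s in zip(grids, center, spacing))
    return d2 <= radius_mm**2


def _real_sph_harm(l: int, m: int, theta: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Real-valued spherical harmonic (polar angle theta, azimuth phi)."""
    y = special.sph_harm_y(l, abs(m), theta, phi)
    if m > 0:
        return math.sqrt(2.0) * y.real
    if m < 0:
        return math.sqrt(2.0) * y.imag
    return y.real


def make_perturbed_blob(
    radius_mm: float,
    irregularity: float,
    n_harmonics: int = 4,
    seed: int | np.random.Generator = 0,
    grid_shape: tuple[int, int, int] = (64, 64, 64),
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
    center: tuple[float, float, float] | None = None,
) -> np.ndarray:
    """Blob mask with radial perturbation r(θ,φ) = R·(1 + irregularity·P(θ,φ)).

    ``P`` is a random combination of real spherical harmonics of degrees
    2..n_harmonics (degree 0 would rescale the volume and degree 1 would
    translate the blob, so both are excluded), normalized to unit RMS over
    directions; ``irregularity`` is therefore the RMS relative radial
    perturbation. ``irregularity=0`` reduces exactly to
    :func:`make_sphere_mask`.
    """
    if irregularity < 0:
        raise ValueError("irregularity must be non-negative")
    if center is None:
        center = tuple((n - 1) / 2.0 for n in grid_shape)
    if irregularity == 0.0:
        return make_sphere_mask(radius_mm, center, grid_shape, spacing)
    if n_harmonics < 2:
        raise ValueError("n_harmonics must be >= 2")

    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    modes = [(l, m) for l in range(2, n_harmonics + 1) for m in range(-l, l + 1)]
    coefs = rng.standard_normal(len(modes))
    # With orthonormal harmonics the directional RMS of sum(c*Y) is
    # ||c||/sqrt(4*pi); rescale so the perturbation field has unit RMS.
    coefs *= math.sqrt(4.0 * math.pi) / np.linalg.norm(coefs)

    # Evaluate only inside a bounding box around the blob; expand the box if
    # the mask ever touches its boundary (rare, large perturbation tails).
    r_max = radius_mm * (1.0 + 4.5 * irregularity)
    while True:
        lo = [max(0, int(math.floor(c - r_max / s)) - 1) for c, s in
              zip(center, spacing)]
        hi = [min(n, int(math.ceil(c + r_max / s)) + 2) for c, s, n in
              zip(center, spacing, grid_shape)]
        grids = np.meshgrid(*[np.arange(a, b, dtype=float) for a, b in zip(lo, hi)],
                            indexing="ij")
        x = (grids[0] - center[0]) * spacing[0]
        y = (grids[1] - center[1]) * spacing[1]
        z = (grids[2] - center[2]) * spacing[2]
        r = np.sqrt(x * x + y * y + z * z)
        theta = np.arccos(np.clip(np.divide(z, np.maximum(r, 1e-12)), -1, 1))
        phi = np.arctan2(y, x)

        pert = np.zeros(r.shape)
        for (l, m), c in zip(modes, coefs):
            pert += c * _real_sph_harm(l, m, theta, phi)

        radial = 1.0 + irregularity * pert
        if radial.min() <= 0:
            raise DegenerateShapeError(
                "perturbation drives the local radius non-positive; "
                "reduce irregularity or n_harmonics"
            )
        box_mask = r <= radius_mm * radial
        can_expand = any(a > 0 or b < n for a, b, n in zip(lo, hi, grid_shape))
        if _touches_boundary(box_mask) and can_expand:
            r_max *= 1.5
            continue
        mask = np.zeros(grid_shape, dtype=bool)
        mask[tuple(slice(a, b) for a, b in zip(lo, hi))] = box_mask
        if not mask.any():
            raise DegenerateShapeError("perturbed blob contains no lattice points")
        return mask


def _touches_boundary(m: np.ndarray) -> bool:
    return bool(
        m[0].any() or m[-1].any() or m[:, 0].any() or m[:, -1].any()
        or m[:, :, 0].any() or m[:, :, -1].any()
    )


def make_textured_region(
    mask: np.ndarray,
    base_intensity: float,
    disorder: float,
    correlation_length_vox: float,
    seed: int | np.random.Generator = 0,
    background: float = 0.0,
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> Volume:
    """Fill ``mask`` with ``base + disorder * G`` over a smooth random field.

    ``G`` is white Gaussian noise convolved with an isotropic Gaussian kernel
    of width ``correlation_length_vox`` and rescaled to unit sample variance
    inside the mask; voxels outside the mask get the constant ``background``.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    if correlation_length_vox <= 0:
        raise ValueError("correlation length must be positive")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    data = np.full(mask.shape, float(background))
    if disorder == 0.0:
        data[mask] = base_intensity
        return Volume(data=data, spacing=spacing)

    noise = rng.standard_normal(mask.shape)
    smooth = ndimage.gaussian_filter(noise, sigma=correlation_length_vox)
    inside = smooth[mask]
    sd = inside.std()
    if sd == 0:  # pragma: no cover - single-voxel masks
        sd = 1.0
    data[mask] = base_intensity + disorder * (inside - inside.mean()) / sd
    return Volume(data=data, spacing=spacing)


# ---------------------------------------------------------------------------
# Survival generator
# ---------------------------------------------------------------------------

def simulate_survival(
    z_tex: float,
    z_shape: float,
    beta_tex: float,
    beta_shape: float,
    baseline_hazard: float,
    censor_horizon_days: float,
    seed: int | np.random.Generator = 0,
    site: str = "",
    subgroup: str = "",
    age_years: float = float("nan"),
) -> SurvivalRecord:
    """Exponential proportional-hazards event time with uniform censoring.

    hazard = ``baseline_hazard * exp(beta_tex*z_tex + beta_shape*z_shape)``;
    censoring time ~ Uniform(0, censor_horizon_days); the observed time is
    the minimum and the event flag marks which came first. An infinite
    horizon disables censoring.
    """
    if baseline_hazard <= 0:
        raise ValueError("baseline hazard must be positive")
    if censor_horizon_days <= 0:
        raise ValueError("censoring horizon must be positive")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    rate = baseline_hazard * math.exp(beta_tex * z_tex + beta_shape * z_shape)
    t_event = rng.exponential(1.0 / rate)
    if math.isinf(censor_horizon_days):
        t_cens = math.inf
    else:
        t_cens = rng.uniform(0.0, censor_horizon_days)
    time = min(t_event, t_cens)
    return SurvivalRecord(
        time_days=max(time, 1e-9),
        event=int(t_event <= t_cens),
        site=site,
        subgroup=subgroup,
        age_years=age_years,
    )


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

@dataclass
class PhantomParams:
    """All knobs of the phantom cohort generator.

    Defaults reproduce a 70-subject, three-site, two-subgroup cohort
    (48 Group 4 / 22 SHH; sites of 22, 31 and 17 subjects).
    """

    site_composition: dict = field(
        default_factory=lambda: {s: dict(v) for s, v in DEFAULT_SITE_COMPOSITION.items()}
    )
    grid_shape: tuple[int, int, int] = (48, 48, 48)
    voxel_spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    # tumor geometry (mm / voxels)
    core_radius_range_mm: tuple[float, float] = (4.5, 7.0)
    enhancing_thickness_vox: float = 3.0
    edema_thickness_vox: float = 4.0
    n_harmonics: int = 4
    # latent-effect scalings
    texture_sigma0: float = 12.0
    texture_log_slope: float = 0.5
    shape_irreg0: float = 0.08
    shape_log_slope: float = 0.35
    correlation_length_vox: float = 2.0
    # intensities
    base_intensity: dict = field(
        default_factory=lambda: {"enhancing": 130.0, "edema": 105.0,
                                 "nonenhancing_cyst": 85.0}
    )
    background: float = 30.0
    background_noise: float = 2.0
    # survival
    beta_tex: float = 1.0
    beta_shape: float = 0.5
    baseline_hazard: float = 5.0e-4  # per day
    censor_horizon_days: float = 3650.0
    seed: int = 0

    def __post_init__(self) -> None:
        for site, comp in self.site_composition.items():
            for sg, n in comp.items():
                if sg not in SUBGROUPS:
                    raise ValueError(f"unknown subgroup {sg!r} at {site}")
                if n < 0:
                    raise ValueError("subject counts must be >= 0")
        if any(s <= 0 for s in self.voxel_spacing_mm):
            raise ValueError("voxel spacing must be positive")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline hazard must be positive")

    @property
    def n_subjects(self) -> int:
        return sum(n for comp in self.site_composition.values() for n in comp.values())

    def subgroup_counts(self) -> dict[str, int]:
        out = {sg: 0 for sg in SUBGROUPS}
        for comp in self.site_composition.values():
            for sg, n in comp.items():
                out[sg] += n
        return out


@dataclass
class PhantomSubject:
    """One generated subject: image, masks, outcome, and the latent truth."""

    subject_id: str
    volume: Volume
    masks: RegionMaskSet
    survival: SurvivalRecord
    truth: tuple[float, float]  # (z_tex, z_shape)


_AGE_PROFILE = {"G4": (8.7, 3.8), "SHH": (5.8, 5.0)}  # mean, sd in years


def _make_subject(
    params: PhantomParams,
    subject_id: str,
    site: str,
    subgroup: str,
    rng: np.random.Generator,
) -> PhantomSubject:
    gs, sp = params.grid_shape, params.voxel_spacing_mm
    z_tex = float(rng.standard_normal())
    z_shape = float(rng.standard_normal())

    center = tuple(
        (n - 1) / 2.0 + rng.uniform(-1.5, 1.5) for n in gs
    )
    r_core = rng.uniform(*params.core_radius_range_mm)
    irreg = params.shape_irreg0 * math.exp(params.shape_log_slope * z_shape)
    for attempt in range(8):  # retry with damped modes if the radius collapses
        try:
            core = make_perturbed_blob(
                r_core, irreg, params.n_harmonics, rng, gs, sp, center
            )
            break
        except DegenerateShapeError:
            irreg *= 0.5
    else:  # pragma: no cover
        core = make_sphere_mask(r_core, center, gs, sp)

    # nested shells from the Euclidean distance to the core
    dist = ndimage.distance_transform_edt(~core, sampling=sp)
    t_enh = params.enhancing_thickness_vox * min(sp)
    t_ede = params.edema_thickness_vox * min(sp)
    enhancing = (dist <= t_enh) & ~core
    edema = (dist <= t_enh + t_ede) & ~core & ~enhancing

    labels = np.zeros(gs, dtype=np.int16)
    labels[edema] = LABEL_EDEMA
    labels[enhancing] = LABEL_ENHANCING
    labels[core] = LABEL_NONENHANCING_CYST
    masks = RegionMaskSet(labels=labels, spacing=sp)

    sigma = params.texture_sigma0 * math.exp(params.texture_log_slope * z_tex)
    habitat = labels > 0
    noise = ndimage.gaussian_filter(
        rng.standard_normal(gs), sigma=params.correlation_length_vox
    )
    inside = noise[habitat]
    field01 = (noise - inside.mean()) / max(inside.std(), 1e-12)

    data = params.background + params.background_noise * rng.standard_normal(gs)
    for region, base in params.base_intensity.items():
        from .containers import REGION_LABELS

        m = labels == REGION_LABELS[region]
        data[m] = base + sigma * field01[m]
    data = np.clip(data, 1e-3, None)  # keep log-domain bias correction valid
    volume = Volume(data=data, spacing=sp)

    age_mu, age_sd = _AGE_PROFILE[subgroup]
    age = float(np.clip(rng.normal(age_mu, age_sd), 0.5, 20.0))
    survival = simulate_survival(
        z_tex, z_shape, params.beta_tex, params.beta_shape,
        params.baseline_hazard, params.censor_horizon_days,
        seed=rng, site=site, subgroup=subgroup, age_years=age,
    )
    return PhantomSubject(subject_id, volume, masks, survival, (z_tex, z_shape))


def generate_cohort(params: PhantomParams) -> list[PhantomSubject]:
    """Generate the full phantom cohort; deterministic given ``params.seed``."""
    root = np.random.SeedSequence(params.seed)
    subjects: list[PhantomSubject] = []
    idx = 0
    slots = [
        (site, sg)
        for site, comp in sorted(params.site_composition.items())
        for sg in SUBGROUPS
        for _ in range(comp.get(sg, 0))
    ]
    for child, (site, sg) in zip(root.spawn(len(slots)), slots):
        idx += 1
        sid = f"sub-{idx:03d}"
        subjects.append(_make_subject(params, sid, site, sg, np.random.default_rng(child)))
    return subjects


def resimulate_survival_table(table: pd.DataFrame, beta_tex: float,
                              beta_shape: float, baseline_hazard: float = 5.0e-4,
                              censor_horizon_days: float = 3650.0,
                              seed: int = 0) -> pd.DataFrame:
    """Fresh survival outcomes for an existing cohort table.

    Radiomic features never depend on the hazard coefficients, so different
    hazard settings (e.g. a null with beta = 0) can share one set of
    generated images: only ``time_days`` and ``event`` are redrawn from the
    stored latent (z_tex, z_shape).
    """
    rng = np.random.default_rng(seed)
    out = table.copy()
    times, events = [], []
    for z_t, z_s in zip(out["z_tex"], out["z_shape"]):
        rec = simulate_survival(z_t, z_s, beta_tex, beta_shape,
                                baseline_hazard, censor_horizon_days, seed=rng)
        times.append(rec.time_days)
        events.append(rec.event)
    out["time_days"] = times
    out["event"] = events
    return out


def cohort_table(subjects: list[PhantomSubject]) -> pd.DataFrame:
    """Per-subject survival/metadata table (one row per subject)."""
    cols = ["subject_id", "site", "subgroup", "age_years", "time_days",
            "event", "z_tex", "z_shape"]
    rows = [
        {
            "subject_id": s.subject_id,
            "site": s.survival.site,
            "subgroup": s.survival.subgroup,
            "age_years": s.survival.age_years,
            "time_days": s.survival.time_days,
            "event": s.survival.event,
            "z_tex": s.truth[0],
            "z_shape": s.truth[1],
        }
        for s in subjects
    ]
    return pd.DataFrame(rows, columns=cols)


def write_cohort(subjects: list[PhantomSubject], out_dir) -> Path:
    """Write NIfTI volumes/masks and the cohort CSV; returns the CSV path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for s in subjects:
        s.volume.save(out / f"{s.subject_id}_T1c.nii.gz")
        s.masks.save(out / f"{s.subject_id}_mask.nii.gz")
    csv_path = out / "cohort.csv"
    cohort_table(subjects).to_csv(csv_path, index=False)
    return csv_path


__all__ = [
    "PhantomParams",
    "PhantomSubject",
    "DEFAULT_SITE_COMPOSITION",
    "SUBGROUPS",
    "make_sphere_mask",
    "make_perturbed_blob",
    "make_textured_region",
    "simulate_survival",
    "generate_cohort",
    "cohort_table",
    "resimulate_survival_table",
    "write_cohort",
]
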