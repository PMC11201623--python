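"""Surface-morphology features of tumor subcompartments.

Local features are computed on the marching-cubes isosurface of the binary
mask: per-vertex principal curvatures are estimated by fitting a quadric
patch in the local tangent frame and evaluating the first and second
fundamental forms of the fitted patch. Four Koenderink-style descriptors
follow:

* curvedness   C  = sqrt((k1^2 + k2^2)/2)
* shape index  SI = (2/pi) * arctan((k1 + k2)/(k1 - k2)),  k1 >= k2,
  with SI = sign(H) when k1 = k2 (sphere-like limit) and 0 on a plane
* sharpness    S  = (k1 - k2)^2
* total curvature T = k1^2 + k2^2

Curvature is signed with respect to the *inward* normal, so a convex
surface (sphere) has positive principal curvatures and SI = +1.

Global features are 14 contour descriptors of the voxel mask (volume,
principal-axis lengths, eccentricity, elongation, flatness, orientation,
surface area, roundness, equivalent spherical radius/diameter, elongation
shape factor, compactness, integrated intensity), using millimetre units and
the solid-ellipsoid axis-length convention (axis length = 2*sqrt(5*lambda)).

The per-region shape vector is 4 local features x 5 statistics + 14 global
features = 34 values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import trimesh
from scipy import ndimage
from scipy.spatial import cKDTree
from skimage import measure

from .containers import Volume
from .exceptions import DegenerateShapeError
from .texture_features import STAT_NAMES, aggregate_stats

LOCAL_FEATURE_NAMES = ("curvedness", "sharpness", "shape_index", "total_curvature")
GLOBAL_FEATURE_NAMES = (
    "volume",
    "major_axis_length",
    "minor_axis_length",
    "eccentricity",
    "elongation",
    "orientation",
    "perimeter",
    "roundness",
    "equivalent_spherical_radius",
    "equivalent_spherical_diameter",
    "flatness",
    "elongation_shape_factor",
    "compactness",
    "integrated_intensity",
)


@dataclass
class ShapeConfig:
    """Isosurface and curvature-estimation settings."""

    indicator_sigma_vox: float = 0.5      # Gaussian smoothing of the 0/1 mask
    smoothing_iterations: int = 10        # small-step Laplacian mesh smoothing
    smoothing_step: float = 0.1
    patch_radius_edges: float = 8.0       # patch radius, in mean edge lengths
    fit_order: int = 4                    # polynomial order of the patch fit
    min_neighbors: int = 15


DEFAULT_SHAPE_CONFIG = ShapeConfig()


# ---------------------------------------------------------------------------
# isosurface
# ---------------------------------------------------------------------------

def extract_isosurface(mask: np.ndarray,
                       spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
                       cfg: ShapeConfig = DEFAULT_SHAPE_CONFIG) -> trimesh.Trimesh:
    """Marching-cubes surface of the binary mask at level 0.5, in mm.

    The 0/1 indicator is smoothed with a small Gaussian (sigma = 0.5 voxel)
    to soften voxelization staircase before contouring, then the mesh gets a
    few small-step Laplacian smoothing iterations. Normals face outward.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise DegenerateShapeError("mask is empty")
    idx = np.nonzero(mask)
    extents = [int(i.max()) - int(i.min()) + 1 for i in idx]
    if min(extents) < 2:
        raise DegenerateShapeError("mask needs at least 2 voxels of extent per axis")

    # the mesh is translation-invariant for every consumer: crop to the
    # mask bounding box before smoothing/contouring
    sl = tuple(slice(int(i.min()), int(i.max()) + 1) for i in idx)
    padded = np.pad(mask[sl].astype(float), 2)
    smooth = ndimage.gaussian_filter(padded, sigma=cfg.indicator_sigma_vox)
    # keep the 0.5 level crossing even after heavy smoothing of thin masks
    if smooth.max() <= 0.5:
        smooth = smooth * (0.95 / smooth.max())
    verts, faces, _, _ = measure.marching_cubes(smooth, level=0.5,
                                                spacing=tuple(spacing))
    mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=True)
    if mesh.volume < 0:  # enforce outward-facing normals
        mesh.invert()
    if cfg.smoothing_iterations > 0:
        mesh = _laplacian_smooth(mesh, cfg.smoothing_iterations, cfg.smoothing_step)
    return mesh


def _laplacian_smooth(mesh: trimesh.Trimesh, iterations: int, step: float
                      ) -> trimesh.Trimesh:
    """Uniform-weight Laplacian smoothing with a small step (shrinkage is
    negligible at these settings and is covered by feature tolerances)."""
    from scipy import sparse

    v = mesh.vertices.copy()
    edges = mesh.edges_unique
    n = len(v)
    rows = np.concatenate([edges[:, 0], edges[:, 1]])
    cols = np.concatenate([edges[:, 1], edges[:, 0]])
    A = sparse.csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    deg = np.asarray(A.sum(axis=1)).ravel()
    isolated = deg == 0
    deg[isolated] = 1.0
    for _ in range(iterations):
        centroid = A @ v / deg[:, None]
        centroid[isolated] = v[isolated]
        v = v + step * (centroid - v)
    return trimesh.Trimesh(vertices=v, faces=mesh.faces, process=False)


# ---------------------------------------------------------------------------
# curvature
# ---------------------------------------------------------------------------

@dataclass
class VertexCurvature:
    """Per-vertex curvature estimates; ``valid`` flags usable vertices."""

    gaussian: np.ndarray      # K
    mean: np.ndarray          # H
    kappa1: np.ndarray        # principal curvature, kappa1 >= kappa2
    kappa2: np.ndarray
    valid: np.ndarray         # bool


def estimate_curvature(mesh: trimesh.Trimesh,
                       patch_radius: float | None = None,
                       cfg: ShapeConfig = DEFAULT_SHAPE_CONFIG) -> VertexCurvature:
    """Quadric-patch curvature at every vertex.

    Neighbors within ``patch_radius`` (default: 8 mean edge lengths) are
    expressed in the local tangent frame (z along the *inward* normal) and a
    polynomial patch z = du + ev + au^2 + buv + cv^2 + (higher-order terms
    up to ``fit_order``) is least-squares fitted; the higher-order terms
    absorb the truncation bias the quadratic alone would incur on curved
    patches. The first (E, F, G) and second (L, M, N) fundamental forms of
    the fitted patch at the origin give K = (LN - M^2)/(EG - F^2) and
    H = (EN + GL - 2FM) / (2(EG - F^2)); principal curvatures are
    H +/- sqrt(max(H^2 - K, 0)). Vertices with too few neighbors retry with
    a doubled radius and are excluded if still degenerate.
    """
    verts = np.asarray(mesh.vertices)
    normals = np.asarray(mesh.vertex_normals)
    if patch_radius is None:
        patch_radius = cfg.patch_radius_edges * float(mesh.edges_unique_length.mean())
    tree = cKDTree(verts)

    n = len(verts)
    K = np.zeros(n)
    H = np.zeros(n)
    valid = np.zeros(n, dtype=bool)
    all_neighbors = tree.query_ball_point(verts, patch_radius)

    for i in range(n):
        nrm = -normals[i]  # inward: convex surface => positive curvature
        nn = np.linalg.norm(nrm)
        if nn == 0:
            continue
        nrm = nrm / nn
        # tangent basis (manual cross products: hot loop)
        ref = (1.0, 0.0, 0.0) if abs(nrm[0]) < 0.9 else (0.0, 1.0, 0.0)
        e1 = np.array([nrm[1] * ref[2] - nrm[2] * ref[1],
                       nrm[2] * ref[0] - nrm[0] * ref[2],
                       nrm[0] * ref[1] - nrm[1] * ref[0]])
        e1 /= np.sqrt(e1 @ e1)
        e2 = np.array([nrm[1] * e1[2] - nrm[2] * e1[1],
                       nrm[2] * e1[0] - nrm[0] * e1[2],
                       nrm[0] * e1[1] - nrm[1] * e1[0]])

        idx = all_neighbors[i]
        if len(idx) <= cfg.min_neighbors:  # sparse patch: retry wider
            idx = tree.query_ball_point(verts[i], 2.0 * patch_radius)
        idx = [j for j in idx if j != i]
        if len(idx) < cfg.min_neighbors - 1:
            continue
        rel = verts[idx] - verts[i]
        u = rel @ e1
        v = rel @ e2
        w = rel @ nrm
        cols = [u, v, u * u, u * v, v * v]
        for order in range(3, cfg.fit_order + 1):
            for p in range(order + 1):
                cols.append(u ** (order - p) * v**p)
        A = np.column_stack(cols)
        try:
            AtA = A.T @ A
            AtA.flat[:: AtA.shape[0] + 1] += 1e-12  # tiny ridge for stability
            coef = np.linalg.solve(AtA, A.T @ w)
        except np.linalg.LinAlgError:  # pragma: no cover
            continue
        d, e, a, b, c = coef[:5]
        W = np.sqrt(1.0 + d * d + e * e)
        E = 1.0 + d * d
        F = d * e
        G = 1.0 + e * e
        L = 2.0 * a / W
        M = b / W
        N = 2.0 * c / W
        denom = E * G - F * F
        if denom <= 1e-12:
            continue
        K[i] = (L * N - M * M) / denom
        H[i] = (E * N + G * L - 2.0 * F * M) / (2.0 * denom)
        valid[i] = True

    disc = np.sqrt(np.maximum(H * H - K, 0.0))
    return VertexCurvature(gaussian=K, mean=H, kappa1=H + disc, kappa2=H - disc,
                           valid=valid)


def local_shape_features(curv: VertexCurvature) -> dict[str, np.ndarray]:
    """Curvedness, sharpness, shape index and total curvature per vertex
    (only valid vertices are returned)."""
    k1 = curv.kappa1[curv.valid]
    k2 = curv.kappa2[curv.valid]
    if k1.size == 0:
        raise DegenerateShapeError("no valid curvature estimates")
    curvedness = np.sqrt((k1**2 + k2**2) / 2.0)
    sharpness = (k1 - k2) ** 2
    total = k1**2 + k2**2
    diff = k1 - k2
    si = np.zeros_like(k1)
    nonumb = diff > 1e-12
    si[nonumb] = (2.0 / np.pi) * np.arctan((k1 + k2)[nonumb] / diff[nonumb])
    umb = ~nonumb
    si[umb] = np.sign((k1 + k2)[umb] / 2.0)  # sphere-like: +/-1; plane: 0
    return {
        "curvedness": curvedness,
        "sharpness": sharpness,
        "shape_index": si,
        "total_curvature": total,
    }


# ---------------------------------------------------------------------------
# global contour features
# ---------------------------------------------------------------------------

def global_shape_features(mask: np.ndarray, volume,
                          mesh: trimesh.Trimesh | None = None,
                          spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
                          cfg: ShapeConfig = DEFAULT_SHAPE_CONFIG
                          ) -> dict[str, float]:
    """The 14 global contour descriptors of one region (mm units)."""
    mask = np.asarray(mask, dtype=bool)
    nvox = int(mask.sum())
    if nvox < 4:
        raise DegenerateShapeError("need at least 4 voxels for moment features")
    data = volume.data if isinstance(volume, Volume) else np.asarray(volume, float)
    if isinstance(volume, Volume):
        spacing = volume.spacing
    if mesh is None:
        mesh = extract_isosurface(mask, spacing, cfg)

    voxel_vol = float(np.prod(spacing))
    V = nvox * voxel_vol
    area = float(mesh.area)

    coords = np.argwhere(mask) * np.asarray(spacing)
    cov = np.cov(coords, rowvar=False)
    lam, vecs = np.linalg.eigh(cov)
    order = np.argsort(lam)[::-1]
    lam = np.clip(lam[order], 1e-12, None)
    v1 = vecs[:, order[0]]

    major = 2.0 * np.sqrt(5.0 * lam[0])
    minor = 2.0 * np.sqrt(5.0 * lam[2])
    r_eq = (3.0 * V / (4.0 * np.pi)) ** (1.0 / 3.0)

    return {
        "volume": V,
        "major_axis_length": float(major),
        "minor_axis_length": float(minor),
        "eccentricity": float(np.sqrt(max(0.0, 1.0 - lam[2] / lam[0]))),
        "elongation": float(np.sqrt(lam[0] / lam[1])),
        "orientation": float(np.arccos(np.clip(abs(v1[0]), 0.0, 1.0))),
        "perimeter": area,
        # clip at 1: discretization can push a digital ball's mesh area just
        # below the analytic isoperimetric bound
        "roundness": float(min((36.0 * np.pi * V**2) ** (1.0 / 3.0) / area, 1.0)),
        "equivalent_spherical_radius": float(r_eq),
        "equivalent_spherical_diameter": float(2.0 * r_eq),
        "flatness": float(np.sqrt(lam[1] / lam[2])),
        "elongation_shape_factor": float(major / (2.0 * r_eq)),
        "compactness": float(min(36.0 * np.pi * V**2 / area**3, 1.0)),
        "integrated_intensity": float(data[mask].sum()),
    }


# ---------------------------------------------------------------------------
# per-region vector
# ---------------------------------------------------------------------------

def extract_shape_vector(mask: np.ndarray, volume,
                         cfg: ShapeConfig = DEFAULT_SHAPE_CONFIG,
                         region: str | None = None) -> pd.Series:
    """The 34-long shape vector: 4 local features x 5 statistics over mesh
    vertices, then the 14 global features. Names follow
    ``shape__{feature}__{stat}`` / ``shape__{global feature}``."""
    spacing = volume.spacing if isinstance(volume, Volume) else (1.0, 1.0, 1.0)
    mesh = extract_isosurface(mask, spacing, cfg)
    curv = estimate_curvature(mesh, cfg=cfg)
    local = local_shape_features(curv)
    glob = global_shape_features(mask, volume, mesh=mesh, spacing=spacing, cfg=cfg)

    prefix = f"{region}__" if region else ""
    names: list[str] = []
    values: list[float] = []
    for feat in LOCAL_FEATURE_NAMES:
        for stat, x in zip(STAT_NAMES, aggregate_stats(local[feat])):
            names.append(f"{prefix}shape__{feat}__{stat}")
            values.append(x)
    for feat in GLOBAL_FEATURE_NAMES:
        names.append(f"{prefix}shape__{feat}")
        values.append(glob[feat])
    return pd.Series(values, index=names, dtype=float)


__all__ = [
    "ShapeConfig",
    "DEFAULT_SHAPE_CONFIG",
    "LOCAL_FEATURE_NAMES",
    "GLOBAL_FEATURE_NAMES",
    "VertexCurvature",
    "extract_isosurface",
    "estimate_curvature",
    "local_shape_features",
    "global_shape_features",
    "extract_shape_vector",
]
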