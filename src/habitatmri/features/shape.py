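"""Morphological (shape) features of a 3-D mask, mesh-based where IBSI says so.

Shape is computed on the original image's mask only.  The surface mesh
comes from marching cubes on the zero-padded mask; volume uses the signed
tetrahedron sum over mesh faces.  A single-voxel mask has a degenerate
surface: all mesh-derived features are flagged undefined (NaN).
"""

from __future__ import annotations

import logging

import numpy as np
from scipy.spatial import ConvexHull
from scipy.spatial.distance import pdist
from skimage import measure

from ..grid import Mask3D

__all__ = ["shape_features"]

log = logging.getLogger(__name__)

_NAMES = (
    "MeshVolume", "VoxelVolume", "SurfaceArea", "SurfaceVolumeRatio",
    "Sphericity", "Maximum3DDiameter", "Maximum2DDiameterSlice",
    "Maximum2DDiameterColumn", "Maximum2DDiameterRow", "MajorAxisLength",
    "MinorAxisLength", "LeastAxisLength", "Elongation", "Flatness",
)


def _max_pairwise(points: np.ndarray) -> float:
    if len(points) < 2:
        return 0.0
    if len(points) > 400:
        try:
            points = points[ConvexHull(points).vertices]
        except Exception:  # coplanar/degenerate clouds fall back to all points
            pass
    return float(pdist(points).max())


def _max_2d_diameter(coords_mm: np.ndarray, fixed_axis: int) -> float:
    """Largest in-plane diameter over slices perpendicular to ``fixed_axis``."""
    plane_axes = [a for a in range(3) if a != fixed_axis]
    best = 0.0
    vals = coords_mm[:, fixed_axis]
    for v in np.unique(vals):
        pts = coords_mm[vals == v][:, plane_axes]
        if len(pts) >= 2:
            best = max(best, float(pdist(pts).max()))
    return best


def shape_features(mask: Mask3D, spacing=None) -> dict[str, float]:
    """The 14 IBSI shape features (mm-based)."""
    spacing = np.asarray(spacing if spacing is not None else mask.spacing, dtype=float)
    m = mask.voi
    n = int(m.sum())
    if n == 0:
        raise ValueError("empty mask")
    voxel_volume = float(np.prod(spacing))
    out = dict.fromkeys(_NAMES, float("nan"))
    out["VoxelVolume"] = n * voxel_volume
    if n == 1:
        log.warning("single-voxel mask: mesh-based shape features are undefined")
        return out

    padded = np.pad(m.astype(np.uint8), 1)
    verts, faces, *_ = measure.marching_cubes(padded, level=0.5, spacing=tuple(spacing))
    v0, v1, v2 = verts[faces[:, 0]], verts[faces[:, 1]], verts[faces[:, 2]]
    mesh_volume = float(abs(np.einsum("ij,ij->", v0, np.cross(v1, v2))) / 6.0)
    area = float(measure.mesh_surface_area(verts, faces))
    out["MeshVolume"] = mesh_volume
    out["SurfaceArea"] = area
    out["SurfaceVolumeRatio"] = area / mesh_volume if mesh_volume > 0 else float("nan")
    out["Sphericity"] = (
        float(np.pi ** (1 / 3) * (6.0 * mesh_volume) ** (2 / 3) / area) if area > 0 else float("nan")
    )

    coords_mm = np.argwhere(m) * spacing
    surf = verts  # mesh vertices trace the surface
    out["Maximum3DDiameter"] = _max_pairwise(surf)
    # slice = constant third axis; column = constant second; row = constant first
    out["Maximum2DDiameterSlice"] = _max_2d_diameter(coords_mm, fixed_axis=2)
    out["Maximum2DDiameterColumn"] = _max_2d_diameter(coords_mm, fixed_axis=1)
    out["Maximum2DDiameterRow"] = _max_2d_diameter(coords_mm, fixed_axis=0)

    cov = np.cov(coords_mm.T) if n > 1 else np.zeros((3, 3))
    eig = np.sort(np.linalg.eigvalsh(cov))[::-1]
    eig = np.clip(eig, 0.0, None)
    out["MajorAxisLength"] = float(4.0 * np.sqrt(eig[0]))
    out["MinorAxisLength"] = float(4.0 * np.sqrt(eig[1]))
    out["LeastAxisLength"] = float(4.0 * np.sqrt(eig[2]))
    out["Elongation"] = float(np.sqrt(eig[1] / eig[0])) if eig[0] > 0 else float("nan")
    out["Flatness"] = float(np.sqrt(eig[2] / eig[0])) if eig[0] > 0 else float("nan")
    return out
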