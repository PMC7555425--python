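"""3D shape descriptors of a binary mask.

Surface area and mesh volume come from a marching-cubes isosurface of the
binary mask at level 0.5 with physical spacing; axis lengths come from a
principal-component analysis of the physical coordinates of the in-mask
voxel centres (eigenvalues sorted descending; axis length = 4 sqrt(lambda)).
Maximum diameters are the largest pairwise distances between surface mesh
vertices, optionally ignoring one axis for the 2D variants. Masks too small
or too flat for a mesh fall back to voxel-face surface area; degenerate
eigenvalues yield axis lengths of 0.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import ConvexHull
from scipy.spatial.distance import pdist
from skimage import measure

FEATURE_NAMES = (
    "Elongation",
    "Flatness",
    "LeastAxisLength",
    "MajorAxisLength",
    "Maximum2DDiameterColumn",
    "Maximum2DDiameterRow",
    "Maximum2DDiameterSlice",
    "Maximum3DDiameter",
    "MeshVolume",
    "MinorAxisLength",
    "Sphericity",
    "SurfaceArea",
    "SurfaceVolumeRatio",
    "VoxelVolume",
)


def _mesh(mask: np.ndarray, spacing) -> tuple[np.ndarray, np.ndarray] | None:
    padded = np.pad(mask, 1).astype(np.float64)
    try:
        verts, faces, _, _ = measure.marching_cubes(
            padded, level=0.5, spacing=tuple(spacing)
        )
    except (ValueError, RuntimeError):
        return None
    return verts, faces


def _mesh_volume(verts: np.ndarray, faces: np.ndarray) -> float:
    tri = verts[faces]
    return float(abs(np.einsum("ij,ij->i", tri[:, 0], np.cross(tri[:, 1], tri[:, 2])).sum()) / 6.0)


def _voxel_face_area(mask: np.ndarray, spacing) -> float:
    """Total area of exposed voxel faces (fallback surface measure)."""
    sx, sy, sz = spacing
    areas = (sy * sz, sx * sz, sx * sy)
    total = 0.0
    for axis, a in enumerate(areas):
        padded = np.pad(mask, [(1, 1) if i == axis else (0, 0) for i in range(3)])
        diff = np.abs(np.diff(padded.astype(np.int8), axis=axis))
        total += a * diff.sum()
    return float(total)


def _max_pairwise(points: np.ndarray) -> float:
    if len(points) < 2:
        return 0.0
    if len(points) > 1000:
        try:
            points = points[ConvexHull(points).vertices]
        except Exception:
            pass
    if len(points) > 4000:  # extremely non-convex fallback; subsample
        idx = np.linspace(0, len(points) - 1, 4000).astype(int)
        points = points[idx]
    return float(pdist(points).max())


def _max_pairwise_2d(points: np.ndarray) -> float:
    if len(points) < 2:
        return 0.0
    if len(points) > 500:
        try:
            points = points[ConvexHull(points, qhull_options="QJ").vertices]
        except Exception:
            pass
    return float(pdist(points).max())


def compute(mask: np.ndarray, spacing) -> dict[str, float]:
    spacing = np.asarray(spacing, dtype=float)
    n = int(mask.sum())
    voxel_volume = n * float(np.prod(spacing))

    mesh = _mesh(mask, spacing)
    if mesh is not None:
        verts, faces = mesh
        surface_area = float(measure.mesh_surface_area(verts, faces))
        mesh_volume = _mesh_volume(verts, faces)
        pts = verts
    else:
        surface_area = _voxel_face_area(mask, spacing)
        mesh_volume = voxel_volume
        pts = np.argwhere(mask) * spacing
    if mesh_volume <= 0:
        mesh_volume = max(voxel_volume, 1e-12)

    sphericity = (36.0 * np.pi * mesh_volume**2) ** (1.0 / 3.0) / surface_area if surface_area > 0 else 0.0
    sv_ratio = surface_area / mesh_volume

    coords = np.argwhere(mask) * spacing
    if n >= 2:
        eig = np.linalg.eigvalsh(np.cov(coords.T))
        eig = np.clip(np.sort(eig)[::-1], 0.0, None)
    else:
        eig = np.zeros(3)
    major, minor, least = (4.0 * np.sqrt(eig)).tolist()
    elongation = float(np.sqrt(eig[1] / eig[0])) if eig[0] > 0 else 0.0
    flatness = float(np.sqrt(eig[2] / eig[0])) if eig[0] > 0 else 0.0

    return {
        "Elongation": elongation,
        "Flatness": flatness,
        "LeastAxisLength": least,
        "MajorAxisLength": major,
        "Maximum2DDiameterColumn": _max_pairwise_2d(pts[:, [1, 2]]),
        "Maximum2DDiameterRow": _max_pairwise_2d(pts[:, [0, 2]]),
        "Maximum2DDiameterSlice": _max_pairwise_2d(pts[:, [0, 1]]),
        "Maximum3DDiameter": _max_pairwise(pts),
        "MeshVolume": mesh_volume,
        "MinorAxisLength": minor,
        "Sphericity": float(sphericity),
        "SurfaceArea": surface_area,
        "SurfaceVolumeRatio": float(sv_ratio),
        "VoxelVolume": voxel_volume,
    }
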