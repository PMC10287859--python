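"""Shape descriptors of a binary region in physical units.

Surface quantities come from a marching-cubes mesh of the (zero-padded)
mask; axis lengths from the principal components of the voxel-centre
coordinates (reported as 4 standard deviations, the full-axis convention).
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import ConvexHull
from skimage import measure

SHAPE_NAMES = (
    "MeshVolume", "VoxelVolume", "SurfaceArea", "SurfaceVolumeRatio",
    "Sphericity", "Maximum3DDiameter", "Maximum2DDiameterSlice",
    "Maximum2DDiameterColumn", "Maximum2DDiameterRow", "MajorAxisLength",
    "MinorAxisLength", "LeastAxisLength", "Elongation", "Flatness",
)


def _mesh_volume(verts: np.ndarray, faces: np.ndarray) -> float:
    v0 = verts[faces[:, 0]]
    v1 = verts[faces[:, 1]]
    v2 = verts[faces[:, 2]]
    return float(abs(np.einsum("ij,ij->i", v0, np.cross(v1, v2)).sum()) / 6.0)


def _max_pairwise(points: np.ndarray) -> float:
    if len(points) < 2:
        return 0.0
    if len(points) > 3:
        try:
            points = points[ConvexHull(points).vertices]
        except Exception:  # degenerate (coplanar/collinear) point sets
            pass
    diff = points[:, None, :] - points[None, :, :]
    return float(np.sqrt((diff**2).sum(axis=-1)).max())


def shape_features(mask: np.ndarray, spacing) -> dict[str, float]:
    spacing = np.asarray(spacing, dtype=float)
    n_vox = int(mask.sum())
    voxel_volume = float(np.prod(spacing))

    padded = np.pad(mask.astype(np.uint8), 1)
    verts, faces, _, _ = measure.marching_cubes(padded, level=0.5, spacing=tuple(spacing))
    surface_area = float(measure.mesh_surface_area(verts, faces))
    mesh_volume = _mesh_volume(verts, faces)

    coords = np.argwhere(mask) * spacing
    centered = coords - coords.mean(axis=0)
    cov = centered.T @ centered / n_vox
    eig = np.sort(np.linalg.eigvalsh(cov))[::-1]
    eig = np.clip(eig, 0.0, None)
    major, minor, least = (4.0 * np.sqrt(eig)).tolist()

    out = {
        "MeshVolume": mesh_volume,
        "VoxelVolume": n_vox * voxel_volume,
        "SurfaceArea": surface_area,
        "SurfaceVolumeRatio": surface_area / mesh_volume if mesh_volume > 0 else 0.0,
        "Sphericity": float((36 * np.pi * mesh_volume**2) ** (1 / 3) / surface_area)
        if surface_area > 0 else 0.0,
        "Maximum3DDiameter": _max_pairwise(verts),
        # 2-D diameters: largest vertex distance in each coordinate plane
        "Maximum2DDiameterSlice": _max_pairwise(verts[:, :2]),
        "Maximum2DDiameterColumn": _max_pairwise(verts[:, [0, 2]]),
        "Maximum2DDiameterRow": _max_pairwise(verts[:, 1:]),
        "MajorAxisLength": major,
        "MinorAxisLength": minor,
        "LeastAxisLength": least,
        "Elongation": float(np.sqrt(eig[1] / eig[0])) if eig[0] > 0 else 0.0,
        "Flatness": float(np.sqrt(eig[2] / eig[0])) if eig[0] > 0 else 0.0,
    }
    return out
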