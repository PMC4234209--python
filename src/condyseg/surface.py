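"""Volume measurement and triangle-mesh surface extraction from binary masks.

The mesh is the iso-surface at level 0.5 of the 0/1 voxel grid (marching
cubes), with vertices in millimetres (``index * spacing + origin``). Masks are
padded by one background voxel on every side before extraction so surfaces
close at VOI borders. Optional Taubin smoothing (a low-shrinkage two-pass
Laplacian) stands in for the proprietary smoothing of clinical rendering
software; comparisons are only meaningful between meshes produced with
identical smoothing settings.
"""

from __future__ import annotations

import numpy as np
import trimesh
from skimage import measure

from .volume_io import BinaryMask

__all__ = ["mask_volume_mm3", "extract_surface"]


def mask_volume_mm3(mask: BinaryMask) -> float:
    """Segmented volume in mm^3: true-voxel count times the voxel volume."""
    return mask.count() * float(np.prod(mask.spacing))


def extract_surface(mask: BinaryMask, smooth_iterations: int = 10) -> trimesh.Trimesh:
    """Extract the mm-coordinate triangle mesh bounding a binary mask.

    Parameters
    ----------
    mask
        Non-empty binary mask with spacing/origin metadata.
    smooth_iterations
        Taubin smoothing passes applied after extraction; 0 leaves the raw
        marching-cubes surface. The default (10) changes enclosed volume by
        well under a percent on condyle-sized shapes.
    """
    if not mask.data.any():
        raise ValueError("cannot extract a surface from an empty mask")
    padded = np.pad(mask.data.astype(np.float32), 1)
    verts, faces, _, _ = measure.marching_cubes(padded, level=0.5, spacing=mask.spacing)
    # undo the one-voxel pad, then move into the mask's mm frame
    verts = verts - np.asarray(mask.spacing) + np.asarray(mask.origin)
    mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=True)
    if mesh.is_watertight:
        mesh.fix_normals()  # consistent outward winding so enclosed volume is positive
    if smooth_iterations > 0:
        trimesh.smoothing.filter_taubin(
            mesh, lamb=0.5, nu=0.53, iterations=int(smooth_iterations)
        )
    return mesh
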