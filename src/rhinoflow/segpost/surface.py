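"""Surface extraction: label volumes to simulation-ready triangle meshes.

Marching cubes at iso-level 0.5 on the binary mask of the selected
classes, with vertices mapped to mm via the volume's spacing and origin.
Masks are zero-padded by one voxel so closed regions yield watertight
surfaces.  Optional Laplacian smoothing.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import trimesh
from skimage import measure

from .labels import LabelVolume


def extract_surface(
    lv: LabelVolume,
    class_ids: list[int] | tuple[int, ...],
    smoothing: int = 0,
) -> trimesh.Trimesh:
    """Extract the surface of the union of the given classes.

    Parameters
    ----------
    lv : LabelVolume
    class_ids : class ids forming the region of interest
    smoothing : number of Laplacian smoothing passes (0 = none)
    """
    mask = np.isin(lv.voxels, class_ids)
    if not mask.any():
        raise ValueError("selected classes form an empty region")
    padded = np.pad(mask.astype(np.float32), 1)
    verts, faces, _, _ = measure.marching_cubes(
        padded, level=0.5, spacing=lv.spacing
    )
    # un-pad and shift to physical origin; axes are (z, y, x) in mm
    verts = verts - np.asarray(lv.spacing) + np.asarray(lv.origin)
    mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=True)
    if mesh.volume < 0:  # enforce outward-facing normals
        mesh.invert()
    if smoothing > 0:
        trimesh.smoothing.filter_laplacian(mesh, iterations=smoothing)
    return mesh


def save_surface(mesh: trimesh.Trimesh, path: str | Path) -> None:
    """Write STL (binary) or PLY depending on the file suffix."""
    mesh.export(str(path))


def load_surface(path: str | Path) -> trimesh.Trimesh:
    m = trimesh.load(str(path), force="mesh")
    return m
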