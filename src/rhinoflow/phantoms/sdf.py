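"""Implicit-function (signed distance) surface generation.

Phantom surfaces are built by sampling a signed distance function on a
fine grid and extracting the zero level set with marching cubes, which
guarantees watertight meshes for bounded solids.
"""

from __future__ import annotations

import numpy as np
import trimesh
from skimage import measure

from ..meshgen.surface import SurfaceGeometry


def mesh_from_sdf(
    sdf, lo, hi, resolution: float, pad: int = 2
) -> SurfaceGeometry:
    """Extract the zero level set of ``sdf`` (negative inside) in mm.

    Parameters
    ----------
    sdf : callable (N, 3) -> (N,)
        Signed distance (or any sign-consistent implicit function).
    lo, hi : (3,) mm bounds of the solid
    resolution : sampling step in mm
    """
    lo = np.asarray(lo, float) - pad * resolution
    hi = np.asarray(hi, float) + pad * resolution
    ns = np.maximum(((hi - lo) / resolution).astype(int) + 1, 2)
    axes = [np.linspace(lo[k], hi[k], ns[k]) for k in range(3)]
    grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1)
    values = sdf(grid.reshape(-1, 3)).reshape(grid.shape[:-1])
    spacing = [(axes[k][1] - axes[k][0]) for k in range(3)]
    # extract at a tiny offset level: samples lying exactly on the zero
    # level set otherwise produce degenerate (non-manifold) triangles
    level = 1e-6 * resolution
    verts, faces, _, _ = measure.marching_cubes(values, level=level, spacing=spacing)
    verts = verts + lo
    mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=True)
    parts = mesh.split(only_watertight=False)
    if len(parts) > 1:  # drop sliver components from implicit-function creases
        mesh = max(parts, key=lambda c: abs(c.volume))
    if mesh.volume < 0:
        mesh.invert()
    return SurfaceGeometry(mesh)
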