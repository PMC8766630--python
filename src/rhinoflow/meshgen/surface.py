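"""Surface geometry handling for mesh generation."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import trimesh


@dataclass
class SurfaceGeometry:
    """A triangle surface (mm) with cached watertightness.

    Inside/outside tests require a watertight (edge-manifold, closed)
    surface; non-manifold input is accepted for I/O but inside tests are
    refused.
    """

    mesh: trimesh.Trimesh

    @property
    def watertight(self) -> bool:
        return bool(self.mesh.is_watertight)

    @property
    def bounds(self) -> np.ndarray:
        return np.asarray(self.mesh.bounds)  # (2, 3) min/max, mm

    @property
    def vertices(self) -> np.ndarray:
        return np.asarray(self.mesh.vertices)

    @property
    def faces(self) -> np.ndarray:
        return np.asarray(self.mesh.faces)

    @property
    def triangles(self) -> np.ndarray:
        return self.vertices[self.faces]  # (M, 3, 3)


def read_surface(path: str | Path) -> SurfaceGeometry:
    """Load an STL/PLY surface; watertightness is checked, not required."""
    mesh = trimesh.load(str(path), force="mesh")
    if not isinstance(mesh, trimesh.Trimesh) or len(mesh.faces) == 0:
        raise ValueError(f"no triangles found in {path}")
    return SurfaceGeometry(mesh)


def write_surface(geom: SurfaceGeometry | trimesh.Trimesh, path: str | Path) -> None:
    mesh = geom.mesh if isinstance(geom, SurfaceGeometry) else geom
    mesh.export(str(path))
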