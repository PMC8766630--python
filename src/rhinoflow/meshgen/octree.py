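"""Hierarchical unstructured Cartesian (octree) mesh generation.

Starting from an initial cube surrounding the whole geometry (level 0),
every cell of the current level is subdivided into 8 equally sized child
cells; children located outside the geometry are deleted.  This continues
to a uniform refinement level; afterwards only cells cut by the boundary
and/or cells inside refinement patches are subdivided further until the
final level.  A 2:1 level balance is enforced across cell faces.

Cell classification:

* a cell is *cut* when at least one surface triangle overlaps its box
  (separating-axis test against the parent's candidate triangles);
* a non-cut cell contains no part of the surface, so a single
  inside-test of its center decides the whole cell.  This is the robust
  variant of deleting "cells located outside"; a center-only deletion
  criterion is available via ``deletion="center"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .inside import points_inside
from .surface import SurfaceGeometry

FACE_DIRS = np.array(
    [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]]
)


@dataclass
class Cell:
    cut: bool
    tri_candidates: np.ndarray | None = None  # triangle indices, cut cells only


@dataclass
class CartesianMesh:
    """Octree mesh: leaves keyed by (level, i, j, k) integer coordinates."""

    root_origin: np.ndarray  # (3,) mm, min corner of the level-0 cube
    root_size: float  # mm, level-0 edge length
    l_uniform: int
    l_final: int
    leaves: dict = field(default_factory=dict)

    def spacing(self, level: int) -> float:
        """Cell edge length delta_x at a refinement level."""
        return self.root_size / 2**level

    def center(self, key) -> np.ndarray:
        level, i, j, k = key
        dx = self.spacing(level)
        return self.root_origin + (np.array([i, j, k]) + 0.5) * dx

    def centers(self, keys) -> np.ndarray:
        return np.array([self.center(k) for k in keys])

    @property
    def n_leaves(self) -> int:
        return len(self.leaves)

    def leaf_levels(self) -> np.ndarray:
        return np.array([k[0] for k in self.leaves])

    @staticmethod
    def parent_of(key):
        level, i, j, k = key
        if level == 0:
            return None
        return (level - 1, i // 2, j // 2, k // 2)

    @staticmethod
    def children_of(key):
        level, i, j, k = key
        return [
            (level + 1, 2 * i + a, 2 * j + b, 2 * k + c)
            for a in (0, 1)
            for b in (0, 1)
            for c in (0, 1)
        ]

    # -- persistence --------------------------------------------------------
    def save_h5(self, path: str | Path) -> None:
        import h5py

        keys = np.array(sorted(self.leaves), dtype=np.int64)
        cut = np.array([self.leaves[tuple(k)].cut for k in keys], dtype=bool)
        with h5py.File(path, "w") as f:
            f.attrs["root_origin"] = self.root_origin
            f.attrs["root_size"] = self.root_size
            f.attrs["l_uniform"] = self.l_uniform
            f.attrs["l_final"] = self.l_final
            f.create_dataset("leaf_keys", data=keys)
            f.create_dataset("leaf_cut", data=cut)

    def export_vtk(self, path: str | Path) -> None:
        """Legacy-ASCII VTK unstructured grid of the leaf cells (inspection)."""
        keys = sorted(self.leaves)
        lines = [
            "# vtk DataFile Version 3.0",
            "octree leaf cells",
            "ASCII",
            "DATASET UNSTRUCTURED_GRID",
            f"POINTS {8 * len(keys)} float",
        ]
        for key in keys:
            c = self.center(key)
            h = self.spacing(key[0]) / 2
            for dz in (-h, h):
                for dy in (-h, h):
                    for dx in (-h, h):
                        lines.append(f"{c[0]+dx:.6g} {c[1]+dy:.6g} {c[2]+dz:.6g}")
        lines.append(f"CELLS {len(keys)} {9 * len(keys)}")
        for n in range(len(keys)):
            base = 8 * n
            lines.append("8 " + " ".join(str(base + k) for k in range(8)))
        lines.append(f"CELL_TYPES {len(keys)}")
        lines.extend(["11"] * len(keys))  # VTK_VOXEL
        lines.append(f"CELL_DATA {len(keys)}")
        lines.append("SCALARS level int 1")
        lines.append("LOOKUP_TABLE default")
        lines.extend(str(k[0]) for k in keys)
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def load_h5(cls, path: str | Path) -> "CartesianMesh":
        import h5py

        with h5py.File(path, "r") as f:
            mesh = cls(
                root_origin=np.array(f.attrs["root_origin"]),
                root_size=float(f.attrs["root_size"]),
                l_uniform=int(f.attrs["l_uniform"]),
                l_final=int(f.attrs["l_final"]),
            )
            for key, cut in zip(f["leaf_keys"][...], f["leaf_cut"][...]):
                mesh.leaves[tuple(int(v) for v in key)] = Cell(cut=bool(cut))
        return mesh


# ---------------------------------------------------------------------------
# triangle / box overlap (separating axis theorem)
# ---------------------------------------------------------------------------

def tri_box_overlap(tris: np.ndarray, center: np.ndarray, half: float) -> np.ndarray:
    """Vectorized triangle vs axis-aligned cube overlap test.

    tris: (M, 3, 3); returns bool (M,).  Touching counts as overlap.
    """
    v = tris - center  # (M, 3, 3)
    # axis tests: box axes
    lo, hi = v.min(axis=1), v.max(axis=1)
    ok = ~np.any((lo > half) | (hi < -half), axis=1)
    if not ok.any():
        return ok
    # plane of triangle
    e0 = v[:, 1] - v[:, 0]
    e1 = v[:, 2] - v[:, 1]
    e2 = v[:, 0] - v[:, 2]
    n = np.cross(e0, e1)
    r = half * np.abs(n).sum(axis=1)
    s = np.einsum("mk,mk->m", n, v[:, 0])
    ok &= np.abs(s) <= r + 1e-12
    if not ok.any():
        return ok
    # 9 cross-axis tests
    for e in (e0, e1, e2):
        for axis in range(3):
            a = np.zeros_like(e)
            a[:, axis] = 1.0
            ax = np.cross(a, e)  # (M, 3)
            p = np.einsum("mk,mvk->mv", ax, v)  # (M, 3) projections
            rad = half * np.abs(ax).sum(axis=1)
            ok &= ~(
                (p.min(axis=1) > rad + 1e-12) | (p.max(axis=1) < -rad - 1e-12)
            )
    return ok


def _initial_cube(geom: SurfaceGeometry, inflate: float) -> tuple[np.ndarray, float]:
    lo, hi = geom.bounds
    center = (lo + hi) / 2
    size = float((hi - lo).max()) * (1.0 + inflate)
    return center - size / 2, size


def generate_mesh(
    geom: SurfaceGeometry,
    l_uniform: int,
    l_final: int | None = None,
    patches: list[tuple[np.ndarray, np.ndarray]] | None = None,
    boundary_refine: bool = False,
    deletion: str = "robust",
    inflate: float = 0.05,
) -> CartesianMesh:
    """Generate the octree mesh for a watertight surface.

    Parameters
    ----------
    geom : SurfaceGeometry
        Watertight input surface (mm).
    l_uniform : int
        Uniform refinement level (>= 1); the spacing there is
        root_size / 2**l_uniform.
    l_final : int, optional
        Final level for boundary/patch refinement (defaults to l_uniform).
    patches : list of (lo, hi) boxes in mm, optional
        Axis-aligned refinement patches.
    boundary_refine : bool
        Refine cells cut by the surface up to l_final.
    deletion : {"robust", "center"}
        "robust": delete only cells that contain no surface triangle and
        whose center is outside.  "center": delete every cell with an
        outside center.
    """
    if not geom.watertight:
        raise ValueError("mesh generation requires a watertight geometry")
    l_final = l_uniform if l_final is None else l_final
    if not 1 <= l_uniform <= l_final:
        raise ValueError("need 1 <= l_uniform <= l_final")
    origin, size = _initial_cube(geom, inflate)
    mesh = CartesianMesh(origin, size, l_uniform, l_final)
    tris = geom.triangles
    current = {(0, 0, 0, 0): Cell(cut=True, tri_candidates=np.arange(len(tris)))}
    for level in range(1, l_final + 1):
        nxt: dict = {}
        for key, cell in current.items():
            refine = key[0] < l_uniform
            if key[0] >= l_uniform:
                refine = (boundary_refine and cell.cut) or _in_patch(
                    mesh, key, patches
                )
            if not refine:
                nxt[key] = cell
                continue
            for child, ccell in _classify_children(
                mesh, key, cell, tris, geom, deletion
            ):
                nxt[child] = ccell
        current = nxt
    mesh.leaves = current
    _balance_2to1(mesh, tris, geom, deletion)
    return mesh


def _in_patch(mesh, key, patches) -> bool:
    if not patches:
        return False
    c = mesh.center(key)
    h = mesh.spacing(key[0]) / 2
    for lo, hi in patches:
        if np.all(c + h >= lo) and np.all(c - h <= hi):
            return True
    return False


def _classify_children(mesh, key, cell, tris, geom, deletion):
    children = CartesianMesh.children_of(key)
    if not cell.cut:
        # no surface inside the parent: children inherit interior status
        return [(ck, Cell(cut=False)) for ck in children]
    out = []
    pending_interior = []
    cand = cell.tri_candidates
    for ck in children:
        center = mesh.center(ck)
        half = mesh.spacing(ck[0]) / 2
        sub = cand[tri_box_overlap(tris[cand], center, half)]
        if len(sub):
            if deletion == "center" and not points_inside(geom, center[None])[0]:
                continue
            out.append((ck, Cell(cut=True, tri_candidates=sub)))
        else:
            pending_interior.append(ck)
    if pending_interior:
        centers = mesh.centers(pending_interior)
        inside = points_inside(geom, centers)
        for ck, ok in zip(pending_interior, inside):
            if ok:
                out.append((ck, Cell(cut=False)))
    return out


def _covering_leaf(mesh, level, ijk):
    i, j, k = ijk
    for l in range(level, -1, -1):
        key = (l, i, j, k)
        if key in mesh.leaves:
            return key
        i, j, k = i // 2, j // 2, k // 2
    return None


def _balance_2to1(mesh, tris, geom, deletion) -> None:
    changed = True
    while changed:
        changed = False
        for key in list(mesh.leaves):
            if key not in mesh.leaves:
                continue
            level, i, j, k = key
            n_side = 2**level
            for d in FACE_DIRS:
                ni, nj, nk = i + d[0], j + d[1], k + d[2]
                if not (0 <= ni < n_side and 0 <= nj < n_side and 0 <= nk < n_side):
                    continue
                nb = _covering_leaf(mesh, level, (ni, nj, nk))
                if nb is None or nb[0] >= level - 1:
                    continue
                cell = mesh.leaves.pop(nb)
                if cell.cut and cell.tri_candidates is None:
                    cell.tri_candidates = np.arange(len(tris))
                for ck, ccell in _classify_children(
                    mesh, nb, cell, tris, geom, deletion
                ):
                    mesh.leaves[ck] = ccell
                changed = True
    return
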