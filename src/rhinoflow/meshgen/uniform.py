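"""Extraction of a uniform-level grid from an octree mesh for the solver.

The flow solver operates on the finest uniform refinement level.  This
module rasterizes the octree leaves onto that level (coarser leaves are
expanded into their constituent fine cells), trims the grid to the fluid
bounding box with one layer of padding, and computes per-direction wall
distance fractions q in (0, 1] for the cut links needed by interpolated
bounce-back.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..tlb.lattice import XI
from .inside import segment_first_hit
from .octree import CartesianMesh
from .surface import SurfaceGeometry


@dataclass
class UniformGrid:
    """Dense uniform grid: fluid mask plus geometry metadata.

    ``origin`` is the mm coordinate of the *center* of cell (0, 0, 0);
    ``dx`` the cell edge length in mm.  ``wall_q[i]`` holds, for fluid
    cells whose neighbor in lattice direction i is solid, the fraction of
    the link length at which the wall is crossed (NaN elsewhere).
    """

    mask: np.ndarray  # (nx, ny, nz) bool, True = fluid
    origin: np.ndarray  # (3,) mm, center of cell (0,0,0)
    dx: float  # mm
    wall_q: np.ndarray | None = None  # (27, nx, ny, nz) float32 or None
    labels: dict = field(default_factory=dict)  # name -> bool mask (openings)

    @property
    def shape(self):
        return self.mask.shape

    def cell_centers(self, idx: np.ndarray) -> np.ndarray:
        """(N, 3) mm centers for an (N, 3) integer index array."""
        return self.origin + np.asarray(idx, float) * self.dx

    def mark_region(self, name: str, lo, hi) -> None:
        """Label fluid cells whose centers fall in an axis-aligned mm box."""
        nx, ny, nz = self.mask.shape
        idx = np.argwhere(self.mask)
        centers = self.cell_centers(idx)
        sel = np.all((centers >= np.asarray(lo)) & (centers <= np.asarray(hi)), axis=1)
        m = np.zeros_like(self.mask)
        m[tuple(idx[sel].T)] = True
        self.labels[name] = m

    def mark_opening(self, name: str, lo, hi, normal) -> None:
        """Label an opening: the single outermost fluid layer in a box.

        Cells qualify when their center lies in the (lo, hi) mm box and
        their neighbor one cell along the outward ``normal`` is non-fluid
        (or outside the grid), so the opening is exactly one layer thick.
        """
        self.mark_region(name, lo, hi)
        m = self.labels[name]
        idx = np.argwhere(m)
        n = np.asarray(normal, int)
        nb = idx + n
        shape = np.asarray(self.mask.shape)
        inside = np.all((nb >= 0) & (nb < shape), axis=1)
        outermost = ~inside.copy()
        nb_in = nb[inside]
        outermost[inside] = ~self.mask[tuple(nb_in.T)]
        out = np.zeros_like(m)
        out[tuple(idx[outermost].T)] = True
        self.labels[name] = out


def wall_links(mask: np.ndarray):
    """Yield (i_dir, cell_index_array) for links from fluid into solid.

    Domain borders count as solid.
    """
    for i, xi in enumerate(XI):
        if not xi.any():
            continue
        shifted = np.zeros_like(mask)
        src = [slice(None)] * 3
        dst = [slice(None)] * 3
        for ax in range(3):
            if xi[ax] == 1:
                dst[ax], src[ax] = slice(0, -1), slice(1, None)
            elif xi[ax] == -1:
                dst[ax], src[ax] = slice(1, None), slice(0, -1)
        shifted[tuple(dst)] = mask[tuple(src)]
        cut = mask & ~shifted
        yield i, np.argwhere(cut)


def to_uniform_grid(
    mesh: CartesianMesh,
    geom: SurfaceGeometry | None = None,
    level: int | None = None,
    wall_distances: str = "exact",
) -> UniformGrid:
    """Rasterize octree leaves at a uniform level and attach wall data.

    Parameters
    ----------
    wall_distances : {"exact", "halfway", "none"}
        "exact" casts a ray along every cut link against the leaf's
        candidate triangles (q fractions for Bouzidi); "halfway" sets all
        q to 0.5; "none" skips the computation.
    """
    level = mesh.l_uniform if level is None else level
    n = 2**level
    full = np.zeros((n, n, n), dtype=bool)
    cand_map: dict[tuple, np.ndarray] = {}
    cut_keys: list[tuple] = []
    for (l, i, j, k), cell in mesh.leaves.items():
        if l > level:
            continue
        f = 2 ** (level - l)
        if not cell.cut:
            full[
                i * f : (i + 1) * f, j * f : (j + 1) * f, k * f : (k + 1) * f
            ] = True
            continue
        for key in np.ndindex(f, f, f):
            fine = (i * f + key[0], j * f + key[1], k * f + key[2])
            cut_keys.append(fine)
            if cell.tri_candidates is not None:
                cand_map[fine] = cell.tri_candidates
    if cut_keys and geom is not None:
        # fluid cells are the cells whose centers lie inside the geometry;
        # cut cells with outside centers only contribute their wall links
        dx_lvl = mesh.spacing(level)
        centers = mesh.root_origin + (np.asarray(cut_keys) + 0.5) * dx_lvl
        from .inside import points_inside

        inside = points_inside(geom, centers)
        for key, ok in zip(cut_keys, inside):
            if ok:
                full[key] = True
    else:
        for key in cut_keys:
            full[key] = True
    # leaves finer than `level` mark their ancestor cell
    for (l, i, j, k), cell in mesh.leaves.items():
        if l <= level:
            continue
        f = 2 ** (l - level)
        full[i // f, j // f, k // f] = True
    if not full.any():
        raise ValueError("no leaves at or below the requested level")
    # trim to fluid bounding box with 1-cell pad
    idx = np.argwhere(full)
    lo = np.maximum(idx.min(axis=0) - 1, 0)
    hi = np.minimum(idx.max(axis=0) + 2, n)
    mask = full[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]].copy()
    dx = mesh.spacing(level)
    origin = mesh.root_origin + (lo + 0.5) * dx
    grid = UniformGrid(mask=mask, origin=origin, dx=dx)
    if wall_distances == "none":
        return grid
    q = np.full((27,) + mask.shape, np.nan, dtype=np.float32)
    tris = geom.triangles if geom is not None else None
    for i, cells in wall_links(mask):
        if len(cells) == 0:
            continue
        xi = XI[i].astype(float)
        length = float(np.linalg.norm(xi)) * dx
        qi = np.full(len(cells), 0.5, dtype=np.float32)
        if wall_distances == "exact" and tris is not None:
            starts = grid.cell_centers(cells)
            for k, cell in enumerate(cells):
                key = tuple(int(v) for v in cell + lo)
                cand = cand_map.get(key)
                if cand is None or len(cand) == 0:
                    continue
                hit = segment_first_hit(
                    tris[cand], starts[k : k + 1], xi, length
                )[0]
                if np.isfinite(hit):
                    qi[k] = hit
        q[(i,) + tuple(cells.T)] = qi
    grid.wall_q = q
    return grid
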