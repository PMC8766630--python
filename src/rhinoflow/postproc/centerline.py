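"""Naive geometric centerlines for phantom geometries.

Production centerlines come from external tooling and are accepted as
polyline input.  For synthetic phantoms this module provides:

* the analytic axis polyline when the phantom carries one;
* a distance-transform ridge path for voxel masks: Dijkstra's shortest
  path between two endpoints on the fluid voxel graph with edge costs
  that penalize wall proximity, which pulls the path onto the medial
  axis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, sparse
from scipy.sparse.csgraph import dijkstra


@dataclass
class Centerline:
    points: np.ndarray  # (N, 3) mm, ordered
    side: str = ""

    @property
    def tangents(self) -> np.ndarray:
        t = np.gradient(self.points, axis=0)
        return t / np.linalg.norm(t, axis=1, keepdims=True)

    @property
    def arclength(self) -> float:
        return float(np.linalg.norm(np.diff(self.points, axis=0), axis=1).sum())


def naive_centerline(phantom=None, mask: np.ndarray | None = None,
                     origin=(0.0, 0.0, 0.0), dx: float = 1.0,
                     endpoints=None, side: str = "") -> Centerline:
    """Centerline for a phantom or a voxel mask.

    With ``phantom`` given (an object carrying ``centerline`` or
    ``centerlines``), the analytic axis polyline is returned.  With a
    voxel ``mask`` and two mm ``endpoints``, a distance-transform ridge
    path is extracted.
    """
    if phantom is not None:
        if hasattr(phantom, "centerline"):
            return Centerline(np.asarray(phantom.centerline, float), side=side)
        if hasattr(phantom, "centerlines"):
            if not side:
                raise ValueError("side required for multi-passage phantoms")
            return Centerline(np.asarray(phantom.centerlines[side], float), side=side)
        raise ValueError("phantom carries no centerline")
    if mask is None or endpoints is None:
        raise ValueError("need a phantom, or a mask with endpoints")
    return _ridge_path(mask, np.asarray(origin, float), dx, endpoints, side)


def _ridge_path(mask, origin, dx, endpoints, side) -> Centerline:
    mask = np.asarray(mask, bool)
    idx = np.argwhere(mask)
    flat = {tuple(c): n for n, c in enumerate(idx)}
    ends = []
    for p in endpoints:
        cell = np.round((np.asarray(p, float) - origin) / dx).astype(int)
        if tuple(cell) not in flat:
            raise ValueError(f"endpoint {p} not inside the mask")
        ends.append(flat[tuple(cell)])
    dt = ndimage.distance_transform_edt(mask)
    # edge cost: step length penalized by inverse wall distance at the
    # target voxel; the cheapest path rides the distance-transform ridge
    rows, cols, costs = [], [], []
    offs = np.array(
        [(a, b, c) for a in (-1, 0, 1) for b in (-1, 0, 1) for c in (-1, 0, 1)
         if (a, b, c) != (0, 0, 0)]
    )
    for off in offs:
        nb = idx + off
        ok = np.all((nb >= 0) & (nb < np.asarray(mask.shape)), axis=1)
        ok[ok] &= mask[tuple(nb[ok].T)]
        src = np.flatnonzero(ok)
        dst = np.array([flat[tuple(c)] for c in nb[ok]])
        step = np.linalg.norm(off)
        w = step / (1.0 + dt[tuple(nb[ok].T)] ** 2)
        rows.extend(src)
        cols.extend(dst)
        costs.extend(w)
    n = len(idx)
    graph = sparse.csr_matrix((costs, (rows, cols)), shape=(n, n))
    _, pred = dijkstra(
        graph, indices=ends[0], return_predecessors=True, directed=True
    )
    path = []
    cur = ends[1]
    while cur != ends[0] and cur >= 0:
        path.append(cur)
        cur = pred[cur]
    if cur < 0:
        raise ValueError("endpoints are not connected inside the mask")
    path.append(ends[0])
    pts = origin + idx[path[::-1]] * dx
    return Centerline(np.asarray(pts, float), side=side)
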