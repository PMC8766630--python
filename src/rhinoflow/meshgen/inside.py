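"""Point-in-solid tests and segment/surface intersections.

Inside/outside classification uses a ray-casting parity test with
vectorized Moller-Trumbore ray/triangle intersection.  Several jittered
ray directions vote per point, which makes the parity test robust against
rays grazing edges or vertices; points lying exactly on the surface are
resolved toward inside by the majority vote with a small negative
t-threshold.
"""

from __future__ import annotations

import numpy as np

from .surface import SurfaceGeometry

_EPS = 1e-12


def _ray_hits(triangles: np.ndarray, origins: np.ndarray, direction: np.ndarray,
              t_min: float = 1e-9) -> np.ndarray:
    """Count ray/triangle crossings with t > t_min for each origin.

    triangles: (M, 3, 3); origins: (N, 3); direction: (3,) shared.
    Returns integer crossing counts, shape (N,).
    """
    v0 = triangles[:, 0]
    e1 = triangles[:, 1] - v0
    e2 = triangles[:, 2] - v0
    d = direction / np.linalg.norm(direction)
    p = np.cross(d, e2)  # (M, 3)
    det = np.einsum("mk,mk->m", e1, p)
    ok = np.abs(det) > _EPS
    counts = np.zeros(len(origins), dtype=np.int64)
    if not ok.any():
        return counts
    v0, e1, e2, p, det = v0[ok], e1[ok], e2[ok], p[ok], det[ok]
    inv = 1.0 / det
    # chunk origins to bound memory at N*M
    chunk = max(1, int(2_000_000 // max(len(v0), 1)))
    for s in range(0, len(origins), chunk):
        o = origins[s : s + chunk]  # (n, 3)
        tvec = o[:, None, :] - v0[None]  # (n, M, 3)
        u = np.einsum("nmk,mk->nm", tvec, p) * inv[None]
        q = np.cross(tvec, e1[None])
        v = np.einsum("nmk,mk->nm", q, d[None]) * inv[None]
        t = np.einsum("nmk,mk->nm", q, e2) * inv[None]
        hit = (u >= 0) & (v >= 0) & (u + v <= 1) & (t > t_min)
        counts[s : s + chunk] = hit.sum(axis=1)
    return counts


def points_inside(
    geom: SurfaceGeometry, points: np.ndarray, n_rays: int = 3, seed: int = 0
) -> np.ndarray:
    """Parity ray-cast inside test for an array of points (N, 3) -> bool (N,)."""
    if not geom.watertight:
        raise ValueError("inside tests require a watertight surface")
    points = np.atleast_2d(np.asarray(points, float))
    rng = np.random.default_rng(seed)
    votes = np.zeros(len(points), dtype=np.int64)
    tris = geom.triangles
    for _ in range(n_rays):
        direction = rng.standard_normal(3)
        counts = _ray_hits(tris, points, direction)
        votes += counts % 2
    return votes * 2 > n_rays


def point_inside(geom: SurfaceGeometry, p) -> bool:
    """Scalar convenience wrapper around :func:`points_inside`."""
    return bool(points_inside(geom, np.asarray(p, float)[None])[0])


def segment_first_hit(
    triangles: np.ndarray, starts: np.ndarray, direction: np.ndarray, length: float
) -> np.ndarray:
    """First intersection parameter q in (0, 1] along segments, NaN if none.

    All segments share one direction and length; ``triangles`` may be a
    per-call candidate subset.  Used for Bouzidi wall-distance fractions.
    """
    v0 = triangles[:, 0]
    e1 = triangles[:, 1] - v0
    e2 = triangles[:, 2] - v0
    d = np.asarray(direction, float)
    d = d / np.linalg.norm(d)
    p = np.cross(d, e2)
    det = np.einsum("mk,mk->m", e1, p)
    ok = np.abs(det) > _EPS
    out = np.full(len(starts), np.nan)
    if not ok.any():
        return out
    v0, e1, e2, p, det = v0[ok], e1[ok], e2[ok], p[ok], det[ok]
    inv = 1.0 / det
    tvec = starts[:, None, :] - v0[None]
    u = np.einsum("nmk,mk->nm", tvec, p) * inv[None]
    q = np.cross(tvec, e1[None])
    v = np.einsum("nmk,mk->nm", q, d[None]) * inv[None]
    t = np.einsum("nmk,mk->nm", q, e2) * inv[None]
    frac = t / length
    hit = (u >= -1e-9) & (v >= -1e-9) & (u + v <= 1 + 1e-9) & (frac > 1e-9) & (frac <= 1 + 1e-9)
    frac = np.where(hit, frac, np.inf)
    best = frac.min(axis=1)
    out = np.where(np.isfinite(best), np.minimum(best, 1.0), np.nan)
    return out
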