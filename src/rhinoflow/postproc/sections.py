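"""Centerline cross sections by slab-constrained region growing.

A cross section at centerline station C with unit tangent n collects the
grid cells whose centers x satisfy the slab test

    |(x - C) . n| < (sqrt(3)/2) dx,

restricted to the cells reachable from the seed cell (the cell containing
C) through 26-neighbor connectivity inside the slab.  The connectivity
constraint separates the two nasal sides and excludes sinus cells that
the slab happens to cut but that are not connected to the main cavity at
this station.
"""

from __future__ import annotations

import warnings
from collections import deque
from dataclasses import dataclass

import numpy as np
import pandas as pd

SLAB_HALF_FACTOR = np.sqrt(3.0) / 2.0

_NEIGHBORS = np.array(
    [
        (a, b, c)
        for a in (-1, 0, 1)
        for b in (-1, 0, 1)
        for c in (-1, 0, 1)
        if (a, b, c) != (0, 0, 0)
    ]
)


@dataclass
class CrossSection:
    cells: np.ndarray  # (H_cs, 3) integer grid indices
    station: np.ndarray  # (3,) mm
    normal: np.ndarray  # (3,) unit
    arclength: float  # mm along the centerline

    @property
    def H_cs(self) -> int:
        return len(self.cells)


def slab_mask(
    mask: np.ndarray, origin: np.ndarray, dx: float, point, normal
) -> np.ndarray:
    """Boolean mask of fluid cells inside the slab of thickness sqrt(3) dx."""
    n = np.asarray(normal, float)
    n = n / np.linalg.norm(n)
    idx = np.indices(mask.shape).reshape(3, -1).T
    centers = origin + idx * dx
    d = (centers - np.asarray(point, float)) @ n
    inside = np.abs(d) < SLAB_HALF_FACTOR * dx
    out = np.zeros(mask.shape, bool)
    out[tuple(idx[inside].T)] = True
    return out & mask


def cross_section_cells(
    mask: np.ndarray,
    origin: np.ndarray,
    dx: float,
    point,
    normal,
    arclength: float = 0.0,
) -> CrossSection:
    """Region-grow the cross section connected to the seed at ``point``."""
    point = np.asarray(point, float)
    seed = np.round((point - np.asarray(origin, float)) / dx).astype(int)
    shape = np.asarray(mask.shape)
    if np.any(seed < 0) or np.any(seed >= shape) or not mask[tuple(seed)]:
        raise ValueError("seed point is outside the fluid mesh")
    slab = slab_mask(mask, origin, dx, point, normal)
    if not slab[tuple(seed)]:
        # the seed cell center may fall just outside the slab; admit it
        slab[tuple(seed)] = True
    visited = np.zeros(mask.shape, bool)
    visited[tuple(seed)] = True
    queue = deque([tuple(seed)])
    members = []
    while queue:
        cur = queue.popleft()
        members.append(cur)
        for d in _NEIGHBORS:
            nb = (cur[0] + d[0], cur[1] + d[1], cur[2] + d[2])
            if any(c < 0 or c >= s for c, s in zip(nb, shape)):
                continue
            if slab[nb] and not visited[nb]:
                visited[nb] = True
                queue.append(nb)
    n = np.asarray(normal, float)
    return CrossSection(
        cells=np.array(members),
        station=point,
        normal=n / np.linalg.norm(n),
        arclength=arclength,
    )


def section_average(cs: CrossSection, fld: np.ndarray) -> float:
    """Arithmetic mean of a cell field over the cross-section members."""
    if cs.H_cs < 1:
        raise ValueError("empty cross section")
    return float(fld[tuple(cs.cells.T)].mean())


def _arclength_param(points: np.ndarray) -> np.ndarray:
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    return np.concatenate([[0.0], np.cumsum(seg)])


def centerline_stations(points: np.ndarray, n_stations: int):
    """Equidistant stations (point, unit tangent, arclength) along a polyline."""
    s = _arclength_param(points)
    total = s[-1]
    targets = np.linspace(0.0, total, n_stations)
    out = []
    for t in targets:
        k = min(np.searchsorted(s, t), len(points) - 1)
        k0 = max(k - 1, 0)
        p = np.interp(t, s, points[:, 0]), np.interp(t, s, points[:, 1]), np.interp(
            t, s, points[:, 2]
        )
        tang = points[min(k0 + 1, len(points) - 1)] - points[k0]
        nrm = np.linalg.norm(tang)
        if nrm == 0:
            continue
        out.append((np.array(p), tang / nrm, t))
    return out, total


def centerline_profiles(
    fields: dict,
    mask: np.ndarray,
    origin,
    dx: float,
    centerlines: dict,
    n_stations: int = 50,
) -> pd.DataFrame:
    """Total pressure and temperature along per-side centerlines.

    Parameters
    ----------
    fields : dict with "p_tot" (and optionally "T") cell arrays
    centerlines : dict side -> (N, 3) mm polyline (nostril end first)

    Returns a DataFrame with columns side, station, arclength_pct,
    p_tot, T, n_cells; stations whose seed leaves the mesh are skipped
    with a warning.
    """
    rows = []
    for side, pts in centerlines.items():
        stations, total = centerline_stations(np.asarray(pts, float), n_stations)
        for i, (p, tang, s) in enumerate(stations):
            try:
                cs = cross_section_cells(mask, np.asarray(origin), dx, p, tang, s)
            except ValueError:
                warnings.warn(
                    f"station {i} on side {side!r} lies outside the mesh; skipped"
                )
                continue
            row = {
                "side": side,
                "station": i,
                "arclength_pct": 100.0 * s / total if total > 0 else 0.0,
                "p_tot": section_average(cs, fields["p_tot"]),
                "n_cells": cs.H_cs,
            }
            if "T" in fields and fields["T"] is not None:
                row["T"] = section_average(cs, fields["T"])
            rows.append(row)
    return pd.DataFrame(rows)


def total_pressure(rho: np.ndarray, v: np.ndarray) -> np.ndarray:
    """p_tot = rho c_s^2 + 1/2 rho v^2 (lattice units)."""
    from ..tlb.lattice import CS2

    v2 = np.einsum("k...,k...->...", v, v)
    return rho * CS2 + 0.5 * rho * v2
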