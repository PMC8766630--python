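"""Analytic flow-geometry phantoms: ducts, spheres, bends.

Each phantom pairs a watertight surface with its analytic reference
solution (laminar profile and pressure gradient for a prescribed flux),
inlet/outlet patch locations, and the geometric centerline — everything
the meshing/solver/post-processing chain needs for verification.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh

from ..meshgen.surface import SurfaceGeometry
from .sdf import mesh_from_sdf


@dataclass
class DuctPhantom:
    """Rectangular duct along z with analytic laminar reference."""

    geometry: SurfaceGeometry
    width: float  # x extent, mm
    height: float  # y extent, mm
    length: float  # z extent, mm
    flux: float  # prescribed volume flux, mm^3/s
    inlet_box: tuple  # (lo, hi) mm region of the inlet patch
    outlet_box: tuple
    centerline: np.ndarray  # (N, 3) mm points along the axis

    @property
    def pressure_gradient(self) -> float:
        """dp/dz (Pa/mm per unit dynamic viscosity) for the given flux.

        From the rectangular-duct series solution: Q = c(a, b)/mu * (-dp/dz)
        with c evaluated by :func:`rect_duct_flux_coefficient`.
        """
        c = rect_duct_flux_coefficient(self.width / 2, self.height / 2)
        return -self.flux / c

    def velocity_profile(self, x, y, mu: float = 1.0) -> np.ndarray:
        """Analytic w(x, y) for the stored flux (series solution)."""
        G = -self.pressure_gradient / mu
        return rect_duct_velocity(
            np.asarray(x), np.asarray(y), self.width / 2, self.height / 2, G
        )


def rect_duct_velocity(x, y, a, b, G, n_terms: int = 51) -> np.ndarray:
    """Laminar velocity in a rectangular duct |x|<=a, |y|<=b.

    w(x, y) = (G/2) [ b^2 - y^2 - 4 b^2 sum_k (-1)^k cosh(l_k x / b)
              cos(l_k y / b) / (l_k^3 cosh(l_k a / b)) ],  l_k = (2k+1) pi/2
    with G = (-dp/dz)/mu.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    w = b**2 - y**2
    for k in range(n_terms):
        lk = (2 * k + 1) * np.pi / 2
        # overflow-safe cosh ratio: cosh(u)/cosh(U) for |u| <= U
        u = lk * x / b
        U = lk * a / b
        ratio = (
            np.exp(np.abs(u) - U)
            * (1 + np.exp(-2 * np.abs(u)))
            / (1 + np.exp(-2 * U))
        )
        w = w - 4 * b**2 * (-1) ** k * ratio * np.cos(lk * y / b) / lk**3
    return 0.5 * G * w


def rect_duct_flux_coefficient(a, b, n_terms: int = 51) -> float:
    """Q / G for the rectangular duct (G = (-dp/dz)/mu), mm^4.

    Q = G [ (4/3) a b^3 - 8 b^4 sum_k tanh(l_k a / b) / l_k^5 ].
    """
    s = 0.0
    for k in range(n_terms):
        lk = (2 * k + 1) * np.pi / 2
        s += np.tanh(lk * a / b) / lk**5
    return float((4 / 3) * a * b**3 - 8 * b**4 * s)


def make_duct(
    width: float = 10.0,
    height: float = 10.0,
    length: float = 100.0,
    flux: float = 250e3,
    patch_depth: float | None = None,
) -> DuctPhantom:
    """Rectangular duct phantom (mm); flux in mm^3/s (250 ml/s default).

    The duct is watertight (capped ends); the caps carry the labeled
    inlet (z = 0) and outlet (z = length) patches.
    """
    if min(width, height, length) <= 0:
        raise ValueError("degenerate duct dimensions")
    box = trimesh.creation.box(extents=(width, height, length))
    box.apply_translation((0, 0, length / 2))
    geom = SurfaceGeometry(box)
    pd = patch_depth if patch_depth is not None else 0.05 * length
    big = max(width, height)
    inlet = ((-big, -big, -1e-6), (big, big, pd))
    outlet = ((-big, -big, length - pd), (big, big, length + 1e-6))
    n = max(int(length), 2)
    cl = np.stack(
        [np.zeros(n), np.zeros(n), np.linspace(0, length, n)], axis=1
    )
    return DuctPhantom(
        geometry=geom, width=width, height=height, length=length, flux=flux,
        inlet_box=inlet, outlet_box=outlet, centerline=cl,
    )


def make_sphere(radius: float = 10.0, subdivisions: int = 3) -> SurfaceGeometry:
    """Watertight icosphere phantom (mm)."""
    return SurfaceGeometry(trimesh.creation.icosphere(subdivisions, radius))


@dataclass
class LBendPhantom:
    geometry: SurfaceGeometry
    centerline: np.ndarray  # (N, 3) analytic medial axis
    radius: float


def make_l_bend(
    arm: float = 20.0, radius: float = 3.0, resolution: float = 0.5
) -> LBendPhantom:
    """L-shaped tube: one arm along +z, one along +x, joined at the origin."""

    def sdf(p):
        # capsule along z from 0 to arm
        dz = np.sqrt(p[:, 0] ** 2 + p[:, 1] ** 2)
        az = np.clip(p[:, 2], 0, arm)
        d1 = np.sqrt(p[:, 0] ** 2 + p[:, 1] ** 2 + (p[:, 2] - az) ** 2) - radius
        ax = np.clip(p[:, 0], 0, arm)
        d2 = np.sqrt((p[:, 0] - ax) ** 2 + p[:, 1] ** 2 + p[:, 2] ** 2) - radius
        return np.minimum(d1, d2)

    geom = mesh_from_sdf(
        sdf, (-radius, -radius, -radius), (arm + radius, radius, arm + radius),
        resolution,
    )
    n = int(arm)
    leg1 = np.stack([np.zeros(n), np.zeros(n), np.linspace(arm, 0, n)], axis=1)
    leg2 = np.stack([np.linspace(0, arm, n), np.zeros(n), np.zeros(n)], axis=1)
    cl = np.vstack([leg1, leg2[1:]])
    return LBendPhantom(geometry=geom, centerline=cl, radius=radius)


@dataclass
class TorusSegmentPhantom:
    geometry: SurfaceGeometry
    centerline: np.ndarray
    arc_length: float


def make_torus_segment(
    ring_radius: float = 15.0,
    tube_radius: float = 3.0,
    angle: float = np.pi / 2,
    resolution: float = 0.5,
) -> TorusSegmentPhantom:
    """Curved tube along a circular arc in the xz-plane."""

    def sdf(p):
        phi = np.clip(np.arctan2(p[:, 2], p[:, 0]), 0, angle)
        cx = ring_radius * np.cos(phi)
        cz = ring_radius * np.sin(phi)
        return (
            np.sqrt((p[:, 0] - cx) ** 2 + p[:, 1] ** 2 + (p[:, 2] - cz) ** 2)
            - tube_radius
        )

    m = ring_radius + 2 * tube_radius
    geom = mesh_from_sdf(sdf, (-m, -tube_radius, -m), (m, tube_radius, m), resolution)
    phis = np.linspace(0, angle, 64)
    cl = np.stack(
        [ring_radius * np.cos(phis), np.zeros_like(phis), ring_radius * np.sin(phis)],
        axis=1,
    )
    return TorusSegmentPhantom(
        geometry=geom, centerline=cl, arc_length=ring_radius * angle
    )
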