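"""D3Q27 lattice model: directions, weights, equilibria, moments.

The spatial discretization uses 27 discrete molecule velocities
(all sign combinations of {-1, 0, 1}^3), the isothermal speed of sound
c_s^2 = 1/3, and the standard weights 8/27, 2/27, 1/54, 1/216 by squared
speed.  Two distribution sets live on the lattice: the particle
probability distribution function (PPDF) f_i for mass and momentum, and
the total energy distribution function (TEDF) h_i, whose zeroth moment is
rho * E with E = (D/2) R T + v^2/2 (D = 3).

Field array layout throughout: distributions (27, nx, ny, nz), density
(nx, ny, nz), velocity (3, nx, ny, nz).
"""

from __future__ import annotations

import numpy as np

D = 3
CS2 = 1.0 / 3.0

#: Discrete molecule velocities, shape (27, 3).
XI = np.array(
    [[x, y, z] for x in (-1, 0, 1) for y in (-1, 0, 1) for z in (-1, 0, 1)],
    dtype=np.int64,
)

_W_BY_SPEED = {0: 8.0 / 27.0, 1: 2.0 / 27.0, 2: 1.0 / 54.0, 3: 1.0 / 216.0}
#: Direction weights t_p, shape (27,).
W = np.array([_W_BY_SPEED[int(np.sum(xi * xi))] for xi in XI])

#: Index of the opposite direction: XI[OPP[i]] == -XI[i].
OPP = np.array(
    [int(np.flatnonzero(np.all(XI == -xi, axis=1))[0]) for xi in XI]
)

XI_F = XI.astype(float)
XI_SQ = np.einsum("ik,ik->i", XI_F, XI_F)


def equilibrium_f(rho: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Maxwell equilibrium F_i for density rho and velocity v.

    rho: (...,); v: (3, ...).  Returns (27, ...).
    """
    rho = np.asarray(rho, float)
    v = np.asarray(v, float)
    xv = np.tensordot(XI_F, v, axes=(1, 0))  # (27, ...)
    v2 = np.einsum("k...,k...->...", v, v)
    shape = (27,) + (1,) * rho.ndim
    w = W.reshape(shape)
    return rho * w * (1.0 + xv / CS2 + xv**2 / (2 * CS2**2) - v2 / (2 * CS2))


def total_energy(v: np.ndarray, T: np.ndarray, R: float) -> np.ndarray:
    """E = (D/2) R T + v^2 / 2."""
    v2 = np.einsum("k...,k...->...", np.asarray(v, float), np.asarray(v, float))
    return 0.5 * D * R * np.asarray(T, float) + 0.5 * v2


def equilibrium_h(
    rho: np.ndarray, v: np.ndarray, T: np.ndarray, R: float,
    Feq: np.ndarray | None = None,
) -> np.ndarray:
    """Total-energy equilibrium H_i for (rho, v, T).

    H_i = rho c_s^2 t_p [ xi.v/c_s^2 + ((xi.v)^2/c_s^4 - v^2/c_s^2)
          + (|xi|^2/c_s^2 - D)/2 ] + E F_i
    """
    rho = np.asarray(rho, float)
    v = np.asarray(v, float)
    if Feq is None:
        Feq = equilibrium_f(rho, v)
    xv = np.tensordot(XI_F, v, axes=(1, 0))
    v2 = np.einsum("k...,k...->...", v, v)
    shape = (27,) + (1,) * rho.ndim
    w = W.reshape(shape)
    xi_sq = XI_SQ.reshape(shape)
    bracket = xv / CS2 + (xv**2 / CS2**2 - v2 / CS2) + 0.5 * (xi_sq / CS2 - D)
    E = total_energy(v, T, R)
    return rho * CS2 * w * bracket + E * Feq


def macroscopic(
    f: np.ndarray, h: np.ndarray | None = None, R: float = 1.0
) -> dict:
    """Conservative moments: rho, v, and (with h) T, E, p.

    rho = sum_i f_i;  rho v = sum_i xi_i f_i;
    rho ((D R / 2) T + v^2/2) = sum_i h_i;  p = rho c_s^2.
    """
    rho = f.sum(axis=0)
    if np.any(rho <= 0):
        raise ValueError("non-positive density encountered")
    mom = np.tensordot(XI_F.T, f, axes=(1, 0))  # (3, ...)
    v = mom / rho
    out = {"rho": rho, "v": v, "p": rho * CS2}
    if h is not None:
        rhoE = h.sum(axis=0)
        v2 = np.einsum("k...,k...->...", v, v)
        out["E"] = rhoE / rho
        out["T"] = (out["E"] - 0.5 * v2) / (0.5 * D * R)
    return out
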