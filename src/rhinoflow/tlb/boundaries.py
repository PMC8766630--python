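"""Boundary-condition specifications for the thermal LB solver.

Three boundary families model the nasal-cavity setting:

* isothermal no-slip walls at body temperature T_B (interpolated
  bounce-back for the PPDF, an anti-bounce-back Dirichlet rule for the
  TEDF);
* the pharynx outlet, driven either by a prescribed volume flux (a
  proportional controller adapts the outlet pressure each step until the
  target Reynolds number is met) or by a fixed pressure difference;
* the nostril inlets, where the density follows the modified
  Saint-Venant/Wantzel relation and the temperature is the ambient air
  temperature T_N.
"""

from __future__ import annotations

from dataclasses import dataclass

from .units import GAMMA_AIR, T_AMBIENT, T_BODY


@dataclass(frozen=True)
class WallSpec:
    """Isothermal no-slip wall (temperatures in K)."""

    T_wall: float = T_BODY
    scheme: str = "bouzidi+abb"


@dataclass(frozen=True)
class OpeningSpec:
    """Geometric opening: labeled fluid cells with an outward normal."""

    label: str
    normal: tuple[int, int, int]  # outward lattice direction (unit axis)


@dataclass(frozen=True)
class PharynxSpec(OpeningSpec):
    """Pharynx outlet boundary.

    volume_flux mode needs a target Reynolds number Re_P = (Vdot/A) d/nu
    (or equivalently a lattice volume flux from which the solver computes
    Re_P); pressure mode needs the prescribed pressure difference in
    lattice rho*c_s^2 units.
    """

    mode: str = "volume_flux"  # or "pressure"
    target_re: float | None = None
    vdot_lattice: float | None = None
    delta_p_lattice: float = 0.0
    gain: float = 1e-6  # lattice pressure per unit Reynolds-number error
    hydraulic_diameter: float | None = None  # lattice units; default from area

    def __post_init__(self) -> None:
        if self.mode not in ("volume_flux", "pressure"):
            raise ValueError(f"unknown pharynx mode {self.mode!r}")
        if self.mode == "volume_flux" and (
            self.target_re is None and self.vdot_lattice is None
        ):
            raise ValueError("volume_flux mode needs target_re or vdot_lattice")


@dataclass(frozen=True)
class NostrilSpec(OpeningSpec):
    """Nostril boundary: Saint-Venant/Wantzel density, ambient temperature."""

    T_inlet: float = T_AMBIENT
    gamma: float = GAMMA_AIR


def saint_venant_wantzel_density(
    rho_prev, mom_prev_sq, gamma: float = GAMMA_AIR
):
    """Updated boundary density from the previous-step momentum.

    rho = (1 - (gamma-1)/(2 gamma) * (3 / rho_prev^2) * |rho_prev v_prev|^2
          )^(gamma/(gamma-1))

    with the factor 3 = 1/c_s^2 in lattice units and the ambient density
    normalized to 1.  ``mom_prev_sq`` is |rho_prev v_prev|^2.
    """
    import numpy as np

    bracket = 1.0 - (gamma - 1.0) / (2.0 * gamma) * 3.0 * mom_prev_sq / rho_prev**2
    if np.any(bracket <= 0):
        raise ValueError("supersonic boundary state in Saint-Venant/Wantzel update")
    return bracket ** (gamma / (gamma - 1.0))
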