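"""Physical <-> lattice unit bridge and fluid properties.

Lattice units use delta_x = delta_t = 1 and an ambient density of 1.  A
:class:`UnitBridge` fixes the physical cell size (m), time step (s), and
reference density (kg/m^3); all conversions follow from those three
scales.  The BGK collision frequencies derive from the lattice kinematic
viscosity and thermal diffusivity:

    omega   = 1 / (nu_lattice / c_s^2 + 1/2)
    omega_t = 1 / (alpha_lattice / c_s^2 + 1/2),   alpha = nu / Pr

with the Prandtl number of air Pr = 0.72.
"""

from __future__ import annotations

from dataclasses import dataclass

from .lattice import CS2

#: Kinematic viscosity of air at the average ambient temperature, m^2/s.
NU_AIR = 1.63e-5
#: Prandtl number of air.
PR_AIR = 0.72
#: Default physical temperatures, K.
T_BODY = 309.15
T_AMBIENT = 293.15
T_AVG = 303.15
#: Isentropic exponent of air.
GAMMA_AIR = 1.4


def omega_from_nu(nu_lattice: float) -> float:
    return 1.0 / (nu_lattice / CS2 + 0.5)


def nu_from_omega(omega: float) -> float:
    return CS2 * (1.0 / omega - 0.5)


@dataclass(frozen=True)
class FluidProps:
    """Lattice-unit fluid properties of the working gas."""

    nu: float = 0.05  # lattice kinematic viscosity
    Pr: float = PR_AIR
    R: float = 1.0  # lattice specific gas constant
    rho0: float = 1.0  # ambient lattice density
    gamma: float = GAMMA_AIR

    def __post_init__(self) -> None:
        if not 0 < self.omega < 2:
            raise ValueError("omega outside (0, 2); adjust nu")
        if not 0 < self.omega_t < 2:
            raise ValueError("omega_t outside (0, 2); adjust nu or Pr")
        if self.rho0 <= 0:
            raise ValueError("rho0 must be positive")

    @property
    def omega(self) -> float:
        return omega_from_nu(self.nu)

    @property
    def alpha(self) -> float:
        """Lattice thermal diffusivity nu / Pr."""
        return self.nu / self.Pr

    @property
    def omega_t(self) -> float:
        return omega_from_nu(self.alpha)


@dataclass(frozen=True)
class UnitBridge:
    """Conversions between physical SI and lattice units."""

    dx: float  # m per cell
    dt: float  # s per step
    rho0: float = 1.204  # kg/m^3 ambient air density

    @classmethod
    def from_viscosity(
        cls, dx: float, nu_phys: float = NU_AIR, nu_lattice: float = 0.05,
        rho0: float = 1.204,
    ) -> "UnitBridge":
        """Fix dt so that the physical viscosity maps to nu_lattice."""
        return cls(dx=dx, dt=nu_lattice * dx**2 / nu_phys, rho0=rho0)

    def nu_to_lattice(self, nu_phys: float) -> float:
        return nu_phys * self.dt / self.dx**2

    def velocity_to_lattice(self, u: float) -> float:
        return u * self.dt / self.dx

    def velocity_to_physical(self, u_lattice: float) -> float:
        return u_lattice * self.dx / self.dt

    def pressure_to_physical(self, delta_rho_cs2: float) -> float:
        """Lattice pressure difference (rho*c_s^2 units) -> Pa."""
        return delta_rho_cs2 * self.rho0 * self.dx**2 / self.dt**2

    def volume_flux_to_lattice(self, vdot_m3s: float) -> float:
        """m^3/s -> lattice cells^3 per step."""
        return vdot_m3s * self.dt / self.dx**3

    def mass_flux_to_physical(self, mdot_lattice: float) -> float:
        """Lattice rho0*v*cells^2 -> kg/s."""
        return mdot_lattice * self.rho0 * self.dx**4 / self.dt / self.dx
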