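"""D3Q27 thermal lattice-Boltzmann solver (BGK + total-energy distribution).

One time step performs, on the finest uniform grid level:

1. moment evaluation (density, velocity, temperature);
2. BGK collision of the PPDF toward the Maxwell equilibrium and of the
   TEDF toward the total-energy equilibrium, including the cross-coupling
   term (omega_t - omega_f)(xi.v - v^2/2)(f_i - F_i); an optional Guo
   body force supports channel-flow validation cases;
3. streaming along the 27 directions (periodic axes via array roll);
4. wall handling: interpolated (Bouzidi) bounce-back for the PPDF using
   the stored link-wise wall distances q, and an anti-bounce-back rule
   pinning the wall temperature for the TEDF;
5. open boundaries: equilibrium reconstruction at nostril cells
   (Saint-Venant/Wantzel density, ambient temperature, extrapolated
   velocity) and at pharynx cells (controlled or prescribed pressure,
   extrapolated velocity and temperature).

The solver is deterministic: identical grid/configuration give bitwise
identical fields.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .boundaries import (
    NostrilSpec,
    PharynxSpec,
    WallSpec,
    saint_venant_wantzel_density,
)
from .lattice import (
    CS2,
    OPP,
    W,
    XI,
    XI_F,
    XI_SQ,
    D,
    equilibrium_f,
    equilibrium_h,
    macroscopic,
)
from .units import FluidProps, T_AMBIENT


def _shift(a: np.ndarray, xi, periodic) -> np.ndarray:
    """Stream array contents one cell along +xi (wraps; walls fix later)."""
    out = a
    for ax in range(3):
        if xi[ax]:
            out = np.roll(out, xi[ax], axis=ax)
    return out


@dataclass
class Monitor:
    """Per-interval scalar series recorded during a run."""

    name: str
    func: object  # callable(solver) -> float
    interval: int = 50
    steps: list = field(default_factory=list)
    values: list = field(default_factory=list)


@dataclass
class SimulationResult:
    rho: np.ndarray
    v: np.ndarray
    T: np.ndarray | None
    mask: np.ndarray
    n_steps: int
    monitors: dict
    avg: dict | None = None  # time-averaged fields
    grid: object = None


class ThermalLatticeSolver:
    """BGK D3Q27 solver on a dense masked uniform grid."""

    def __init__(
        self,
        mask: np.ndarray,
        props: FluidProps,
        wall: WallSpec | None = None,
        wall_q: np.ndarray | None = None,
        openings: list | None = None,
        labels: dict | None = None,
        periodic: tuple[bool, bool, bool] = (False, False, False),
        force: tuple[float, float, float] | None = None,
        thermal: bool = True,
        T_init: float = T_AMBIENT,
        T_wall_field: np.ndarray | None = None,
        grid: object = None,
    ):
        self.mask = np.asarray(mask, bool)
        self.props = props
        self.wall = wall or WallSpec()
        self.openings = openings or []
        self.labels = labels or {}
        self.periodic = periodic
        self.force = None if force is None else np.asarray(force, float)
        self.thermal = thermal
        self.T_init = T_init
        # per-cell wall temperature seen by adjacent cut links (K);
        # scalar walls use the WallSpec temperature everywhere
        self.T_wall_field = T_wall_field
        self.grid = grid
        self.step_count = 0

        shape = self.mask.shape
        rho0 = props.rho0
        v0 = np.zeros((3,) + shape)
        self.f = equilibrium_f(np.full(shape, rho0), v0)
        self.f[:, ~self.mask] = 0.0
        if thermal:
            self.h = equilibrium_h(
                np.full(shape, rho0), v0, np.full(shape, T_init), props.R
            )
            self.h[:, ~self.mask] = 0.0
        else:
            self.h = None

        self._open_masks = {}
        self._inner_idx = {}
        bc_cells = np.zeros(shape, bool)
        for spec in self.openings:
            m = self.labels[spec.label]
            self._open_masks[spec.label] = m
            bc_cells |= m
            # inner cells one step inward (against the outward normal)
            n = np.asarray(spec.normal, int)
            idx = np.argwhere(m)
            inner = idx - n
            inner = np.clip(inner, 0, np.asarray(shape) - 1)
            self._inner_idx[spec.label] = (idx, inner)
        self._bc_cells = bc_cells
        self._build_wall_links(wall_q)
        self._pharynx_rho = rho0
        self._mom_prev = {}
        self._avg_accum = None
        self._avg_count = 0

    # ------------------------------------------------------------------
    def _build_wall_links(self, wall_q) -> None:
        """Index arrays for links from fluid cells into solid cells."""
        mask = self.mask
        links = []
        for i, xi in enumerate(XI):
            if not xi.any():
                continue
            nb = _shift(mask.astype(np.int8), -xi, self.periodic)
            # neighbor in +xi direction: roll by -xi brings neighbor here
            nb = nb.astype(bool)
            if not all(self.periodic):
                # non-periodic axes: out-of-domain neighbors are solid
                border = np.zeros_like(mask)
                for ax in range(3):
                    if self.periodic[ax] or xi[ax] == 0:
                        continue
                    sl = [slice(None)] * 3
                    sl[ax] = -1 if xi[ax] == 1 else 0
                    border[tuple(sl)] = True
                nb = nb & ~border
            cut = mask & ~nb & ~self._bc_cells
            if not cut.any():
                continue
            cells = np.argwhere(cut)
            if wall_q is not None:
                q = wall_q[(i,) + tuple(cells.T)].astype(float)
                q = np.where(np.isfinite(q) & (q > 0), q, 0.5)
            else:
                q = np.full(len(cells), 0.5)
            # upstream fluid neighbor (cell - xi), for the q < 1/2 branch
            up = cells - xi
            shape_arr = np.asarray(mask.shape)
            ok_up = np.all((up >= 0) & (up < shape_arr), axis=1)
            up_safe = np.clip(up, 0, shape_arr - 1)
            ok_up &= mask[tuple(up_safe.T)]
            links.append((i, cells, q, up_safe, ok_up))
        self._wall_links = links

    # ------------------------------------------------------------------
    def moments(self) -> dict:
        m = macroscopic(
            np.where(self.mask[None], self.f, W[:, None, None, None] * self.props.rho0),
            self.h if self.thermal else None,
            self.props.R,
        )
        if self.force is not None:
            m["v"] = m["v"] + 0.5 * self.force[:, None, None, None] / m["rho"]
        return m

    def step(self) -> None:
        props = self.props
        om, omt = props.omega, props.omega_t
        mom = self.moments()
        rho, v = mom["rho"], mom["v"]
        Feq = equilibrium_f(rho, v)
        f_pc = self.f + om * (Feq - self.f)
        if self.force is not None:
            # Guo forcing: F_i = (1-om/2) w_i [ (xi-v).G/cs2 + (xi.v)(xi.G)/cs2^2 ]
            G = self.force
            xiG = XI_F @ G  # (27,)
            vG = np.einsum("k...,k->...", v, G)
            xv = np.tensordot(XI_F, v, axes=(1, 0))
            Fi = (1 - om / 2) * W[:, None, None, None] * (
                (xiG[:, None, None, None] - vG[None]) / CS2
                + xv * xiG[:, None, None, None] / CS2**2
            )
            f_pc = f_pc + Fi
        if self.thermal:
            T = mom["T"]
            Heq = equilibrium_h(rho, v, T, props.R, Feq=Feq)
            xv = np.tensordot(XI_F, v, axes=(1, 0))
            v2 = np.einsum("k...,k...->...", v, v)
            h_pc = (
                self.h
                + omt * (Heq - self.h)
                + (omt - om) * (xv - 0.5 * v2) * (self.f - Feq)
            )
        # streaming
        f_new = np.empty_like(self.f)
        for i, xi in enumerate(XI):
            f_new[i] = _shift(f_pc[i], xi, self.periodic)
        if self.thermal:
            h_new = np.empty_like(self.h)
            for i, xi in enumerate(XI):
                h_new[i] = _shift(h_pc[i], xi, self.periodic)
        # wall bounce-back (Bouzidi two-branch interpolation)
        for i, cells, q, up, ok_up in self._wall_links:
            io = OPP[i]
            idx = tuple(cells.T)
            fi = f_pc[(i,) + idx]
            fio = f_pc[(io,) + idx]
            f_up = np.where(
                ok_up, f_pc[(i,) + tuple(np.clip(up, 0, None).T)], fi
            )
            lo = q < 0.5
            val = np.where(
                lo,
                2.0 * q * fi + (1.0 - 2.0 * q) * f_up,
                fi / (2.0 * q) + (2.0 * q - 1.0) / (2.0 * q) * fio,
            )
            f_new[(io,) + idx] = val
            if self.thermal:
                # anti-bounce-back: pin the wall total energy at T_wall
                rho_c = rho[idx]
                if self.T_wall_field is not None:
                    Tw = self.T_wall_field[idx]
                else:
                    Tw = self.wall.T_wall
                Ew = 0.5 * D * props.R * Tw
                Hw = (
                    rho_c * CS2 * W[i] * 0.5 * (XI_SQ[i] / CS2 - D)
                    + Ew * rho_c * W[i]
                )
                h_new[(io,) + idx] = -h_pc[(i,) + idx] + 2.0 * Hw
        self.f = f_new
        if self.thermal:
            self.h = h_new
        self._apply_openings(rho, v, mom.get("T"))
        self.f[:, ~self.mask] = 0.0
        if self.thermal:
            self.h[:, ~self.mask] = 0.0
        if np.any(self.f[:, self.mask] < -1e-6):
            raise FloatingPointError(
                f"negative distribution at step {self.step_count}: "
                "solver unstable (reduce velocity or increase viscosity)"
            )
        self.step_count += 1

    # ------------------------------------------------------------------
    def _apply_openings(self, rho, v, T) -> None:
        props = self.props
        for spec in self.openings:
            idx, inner = self._inner_idx[spec.label]
            ii = tuple(inner.T)
            oi = tuple(idx.T)
            v_in = v[(slice(None),) + ii]  # (3, n)
            if isinstance(spec, NostrilSpec):
                mom_prev = self._mom_prev.get(spec.label)
                if mom_prev is None:
                    rho_b = np.full(idx.shape[0], props.rho0)
                else:
                    rho_prev, v_prev = mom_prev
                    msq = np.einsum("kn,kn->n", rho_prev * v_prev, rho_prev * v_prev)
                    rho_b = saint_venant_wantzel_density(
                        rho_prev, msq, spec.gamma
                    ) * props.rho0
                T_b = np.full(idx.shape[0], spec.T_inlet)
                self._mom_prev[spec.label] = (rho[ii], v_in)
            elif isinstance(spec, PharynxSpec):
                if spec.mode == "pressure":
                    rho_b = np.full(
                        idx.shape[0], props.rho0 + spec.delta_p_lattice / CS2
                    )
                else:
                    re_t = self._pharynx_target_re(spec, idx)
                    n = np.asarray(spec.normal, float)
                    u_n = np.einsum("kn,k->n", v_in, n).mean()
                    d_h = self._pharynx_dh(spec, idx)
                    re_c = abs(u_n) * d_h / props.nu
                    # too little flux -> lower the outlet pressure further
                    self._pharynx_rho -= spec.gain / CS2 * (re_t - re_c)
                    self._pharynx_rho = float(
                        np.clip(self._pharynx_rho, 0.8 * props.rho0, 1.2 * props.rho0)
                    )
                    rho_b = np.full(idx.shape[0], self._pharynx_rho)
                T_b = T[ii] if (self.thermal and T is not None) else None
            else:
                continue
            fb = equilibrium_f(rho_b, v_in)
            self.f[(slice(None),) + oi] = fb
            if self.thermal and T_b is not None:
                self.h[(slice(None),) + oi] = equilibrium_h(
                    rho_b, v_in, T_b, props.R, Feq=fb
                )
            elif self.thermal and isinstance(spec, PharynxSpec):
                self.h[(slice(None),) + oi] = equilibrium_h(
                    rho_b, v_in, np.full(idx.shape[0], self.T_init), props.R, Feq=fb
                )

    def _pharynx_dh(self, spec, idx) -> float:
        if spec.hydraulic_diameter is not None:
            return spec.hydraulic_diameter
        area = float(idx.shape[0])  # cells^2 (dx = 1)
        return 2.0 * np.sqrt(area / np.pi)

    def _pharynx_target_re(self, spec, idx) -> float:
        if spec.target_re is not None:
            return spec.target_re
        area = float(idx.shape[0])
        return (spec.vdot_lattice / area) * self._pharynx_dh(spec, idx) / self.props.nu

    # ------------------------------------------------------------------
    def run(
        self,
        n_iter: int,
        avg_iter: int = 0,
        monitors: list[Monitor] | None = None,
    ) -> SimulationResult:
        """Run n_iter steps, then accumulate time averages over avg_iter."""
        monitors = monitors or []
        for _ in range(n_iter):
            self.step()
            self._record(monitors)
        if avg_iter > 0:
            self._avg_accum = None
            self._avg_count = 0
            for _ in range(avg_iter):
                self.step()
                self._record(monitors)
                self._accumulate()
        mom = self.moments()
        avg = None
        if self._avg_count:
            avg = {
                k: a / self._avg_count for k, a in self._avg_accum.items()
            }
        return SimulationResult(
            rho=mom["rho"],
            v=mom["v"],
            T=mom.get("T"),
            mask=self.mask,
            n_steps=self.step_count,
            monitors={m.name: (m.steps, m.values) for m in monitors},
            avg=avg,
            grid=self.grid,
        )

    def _record(self, monitors) -> None:
        for m in monitors:
            if self.step_count % m.interval == 0:
                m.steps.append(self.step_count)
                m.values.append(float(m.func(self)))

    def _accumulate(self) -> None:
        mom = self.moments()
        fields = {"rho": mom["rho"], "v": mom["v"]}
        if self.thermal:
            fields["T"] = mom["T"]
        if self._avg_accum is None:
            self._avg_accum = {k: np.array(a, dtype=float) for k, a in fields.items()}
        else:
            for k, a in fields.items():
                self._avg_accum[k] += a
        self._avg_count += 1
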