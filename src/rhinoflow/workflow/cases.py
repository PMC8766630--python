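"""Ready-made simulation cases on phantom geometries.

These functions wire the full chain — phantom surface, octree mesh,
uniform solver grid, thermal LB solver, boundary summary — for the duct
benchmark and the two-passage airway.  They are both the workhorses of
the verification suite and worked examples of pipeline assembly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..meshgen import generate_mesh, to_uniform_grid
from ..phantoms import AirwayPhantom, DuctPhantom, make_duct, make_two_passage_airway
from ..postproc import FlowSummary, boundary_summary, total_pressure
from ..tlb import (
    FluidProps,
    NostrilSpec,
    PharynxSpec,
    ThermalLatticeSolver,
    WallSpec,
)


@dataclass
class CaseResult:
    grid: object
    solver: ThermalLatticeSolver
    result: object
    summary: FlowSummary
    phantom: object


def duct_flow_case(
    duct: DuctPhantom | None = None,
    level: int = 5,
    target_re: float = 10.0,
    nu: float = 0.05,
    n_iter: int = 4000,
    gain: float = 1e-5,
    thermal: bool = False,
) -> CaseResult:
    """Flux-controlled laminar flow through a square duct.

    The duct's z=0 cap acts as the controlled outlet ("pharynx"), the
    z=L cap as the inlet ("nostril"); flow is drawn through at the target
    Reynolds number (based on the outlet hydraulic diameter).
    """
    duct = duct or make_duct(width=8, height=8, length=24)
    mesh = generate_mesh(duct.geometry, l_uniform=level)
    grid = to_uniform_grid(mesh, duct.geometry)
    grid.mark_opening("pharynx", *duct.inlet_box, normal=(0, 0, -1))
    grid.mark_opening("nostril_left", *duct.outlet_box, normal=(0, 0, 1))
    props = FluidProps(nu=nu)
    openings = [
        PharynxSpec(
            label="pharynx", normal=(0, 0, -1), mode="volume_flux",
            target_re=target_re, gain=gain,
        ),
        NostrilSpec(label="nostril_left", normal=(0, 0, 1)),
    ]
    solver = ThermalLatticeSolver(
        grid.mask, props, wall=WallSpec(), wall_q=grid.wall_q,
        openings=openings, labels=grid.labels, thermal=thermal, grid=grid,
    )
    result = solver.run(n_iter)
    summary = _summarize(grid, result, thermal)
    return CaseResult(grid, solver, result, summary, duct)


def airway_flow_case(
    asymmetry: float = 1.0,
    level: int = 5,
    vdot_lattice: float = 0.35,
    nu: float = 0.05,
    n_iter: int = 7000,
    avg_iter: int = 0,
    gain: float = 1e-5,
    thermal: bool = False,
    phantom: AirwayPhantom | None = None,
) -> CaseResult:
    """Flux-controlled inspiration through the two-passage airway.

    The prescribed lattice volume flux is held fixed by the pharynx
    controller, so runs at different asymmetries are directly comparable
    operating points on the flux-pressure curve.
    """
    phantom = phantom or make_two_passage_airway(asymmetry=asymmetry)
    mesh = generate_mesh(phantom.geometry, l_uniform=level)
    grid = to_uniform_grid(mesh, phantom.geometry)
    grid.mark_opening("pharynx", *phantom.pharynx_box, normal=(0, 0, -1))
    for side, box in phantom.nostril_boxes.items():
        grid.mark_opening(f"nostril_{side}", *box, normal=(0, 0, 1))
    props = FluidProps(nu=nu)
    openings = [
        PharynxSpec(
            label="pharynx", normal=(0, 0, -1), mode="volume_flux",
            vdot_lattice=vdot_lattice, gain=gain,
        )
    ] + [
        NostrilSpec(label=f"nostril_{side}", normal=(0, 0, 1))
        for side in phantom.nostril_boxes
    ]
    solver = ThermalLatticeSolver(
        grid.mask, props, wall=WallSpec(), wall_q=grid.wall_q,
        openings=openings, labels=grid.labels, thermal=thermal, grid=grid,
    )
    result = solver.run(n_iter, avg_iter=avg_iter)
    summary = _summarize(grid, result, thermal)
    return CaseResult(grid, solver, result, summary, phantom)


def _summarize(grid, result, thermal) -> FlowSummary:
    openings = {}
    for name, m in grid.labels.items():
        normal = (0, 0, -1) if name == "pharynx" else (0, 0, 1)
        openings[name] = {"mask": m, "normal": normal}
    return boundary_summary(
        result.rho, result.v, result.T if thermal else None, openings
    )


def fields_for_profiles(result) -> dict:
    """Cell fields consumed by centerline profiling."""
    out = {"p_tot": total_pressure(result.rho, result.v)}
    if result.T is not None:
        out["T"] = result.T
    return out
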