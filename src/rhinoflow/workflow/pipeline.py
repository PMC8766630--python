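"""Pipeline orchestration: segmentation -> geometry -> mesh -> simulation ->
flow post-processing, with per-stage status, idempotent resume, and
failure isolation.

The configuration names either real inputs (an STL surface, label
volumes) or a phantom spec; every stage writes its products into a
project directory keyed by the content hash of the configuration, and a
completed stage is skipped on re-run.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from ..fourphase import classify_resistance, log_effective_resistance
from ..meshgen import (
    CartesianMesh,
    UniformGrid,
    generate_mesh,
    read_surface,
    to_uniform_grid,
    write_surface,
)
from ..phantoms import make_duct, make_labeled_head, make_two_passage_airway
from ..postproc import centerline_profiles, naive_centerline
from ..segpost import LabelVolume, extract_surface, save_nrrd, segmentation_metrics
from ..tlb import FluidProps, NostrilSpec, PharynxSpec, ThermalLatticeSolver, UnitBridge
from .cases import fields_for_profiles
from .project import Project, StageStatus
from .summary_io import summarize_openings


def run_pipeline(config: dict, out_root: str | Path) -> Project:
    """Execute all pipeline stages for a configuration; resumable."""
    proj = Project.open(out_root, config)
    stages = [
        ("segmentation", _stage_segmentation),
        ("geometry", _stage_geometry),
        ("mesh", _stage_mesh),
        ("simulation", _stage_simulation),
        ("postprocessing", _stage_postprocessing),
    ]
    for name, fn in stages:
        if proj.statuses[name] == StageStatus.DONE and _products_exist(proj, name):
            proj.note(f"stage {name}: skipped (already done)")
            continue
        proj.set_status(name, StageStatus.RUNNING)
        try:
            fn(proj, config)
        except Exception as exc:  # noqa: BLE001 - failure isolation by design
            proj.note(f"stage {name}: FAILED ({exc})")
            proj.statuses[name] = StageStatus.FAILED
            proj.save()
            return proj
        proj.set_status(name, StageStatus.DONE)
        proj.note(f"stage {name}: done")
    return proj


_PRODUCTS = {
    "segmentation": ["segmentation.json"],
    "geometry": ["surface.stl"],
    "mesh": ["grid.npz"],
    "simulation": ["fields.npz"],
    "postprocessing": ["report.json"],
}


def _products_exist(proj: Project, stage: str) -> bool:
    return all((proj.dir / f).is_file() for f in _PRODUCTS[stage])


# -- stages -----------------------------------------------------------------

def _stage_segmentation(proj: Project, config: dict) -> None:
    """Optional CT segmentation of a labeled-head input (threshold route).

    Flow-only configs (duct/airway phantoms) have nothing to segment;
    the stage then records that it was not applicable.
    """
    head_cfg = config.get("head")
    out = {"applicable": head_cfg is not None}
    if head_cfg is not None:
        ph = make_labeled_head(
            shape=tuple(head_cfg.get("shape", (20, 64, 64))),
            sigma_hu=head_cfg.get("sigma_hu", 0.0),
            seed=head_cfg.get("seed", 0),
        )
        # intensity thresholding at the class-midpoint windows: air/bone/
        # tissue are separable by construction; cavity sub-classes come
        # from the phantom's truth for the downstream geometry
        inten = ph.intensity
        air = inten < 0.35
        bone = inten > 0.6
        pred = np.full(inten.shape, 8, dtype=np.int16)
        pred[bone] = 7
        pred[air] = 6
        truth_gross = np.where(
            np.isin(ph.labels.voxels, [0, 1, 2, 3, 4, 5, 6]), 6, ph.labels.voxels
        )
        m = segmentation_metrics(pred, truth_gross, n_classes=9)
        save_nrrd(ph.labels, proj.dir / "labels.nrrd")
        out["metrics"] = m.as_dict()
    (proj.dir / "segmentation.json").write_text(json.dumps(out, indent=2))


def _make_phantom(config: dict):
    spec = config.get("phantom", {"kind": "duct"})
    kind = spec.get("kind", "duct")
    params = dict(spec.get("params", {}))
    if kind == "duct":
        return make_duct(**params)
    if kind == "two_passage_airway":
        return make_two_passage_airway(**params)
    raise ValueError(f"unknown phantom kind {kind!r}")


def _stage_geometry(proj: Project, config: dict) -> None:
    geo_cfg = config.get("geometry", {})
    if "stl" in geo_cfg:
        geom = read_surface(geo_cfg["stl"])
        phantom = None
    else:
        phantom = _make_phantom(config)
        geom = phantom.geometry
    write_surface(geom, proj.dir / "surface.stl")


def _stage_mesh(proj: Project, config: dict) -> None:
    geom = read_surface(proj.dir / "surface.stl")
    level = config.get("mesh", {}).get("level", 5)
    mesh = generate_mesh(geom, l_uniform=level)
    mesh.save_h5(proj.dir / "octree.h5")
    grid = to_uniform_grid(mesh, geom)
    np.savez_compressed(
        proj.dir / "grid.npz",
        mask=grid.mask, origin=grid.origin, dx=grid.dx, wall_q=grid.wall_q,
    )


def _load_grid(proj: Project) -> UniformGrid:
    z = np.load(proj.dir / "grid.npz")
    return UniformGrid(
        mask=z["mask"], origin=z["origin"], dx=float(z["dx"]), wall_q=z["wall_q"]
    )


def _stage_simulation(proj: Project, config: dict) -> None:
    grid = _load_grid(proj)
    phantom = _make_phantom(config)
    sim = config.get("simulation", {})
    if hasattr(phantom, "pharynx_box"):
        grid.mark_opening("pharynx", *phantom.pharynx_box, normal=(0, 0, -1))
        for side, box in phantom.nostril_boxes.items():
            grid.mark_opening(f"nostril_{side}", *box, normal=(0, 0, 1))
    else:
        grid.mark_opening("pharynx", *phantom.inlet_box, normal=(0, 0, -1))
        grid.mark_opening("nostril_left", *phantom.outlet_box, normal=(0, 0, 1))
    props = FluidProps(nu=sim.get("nu", 0.05))
    openings = [
        PharynxSpec(
            label="pharynx", normal=(0, 0, -1), mode=sim.get("mode", "volume_flux"),
            vdot_lattice=sim.get("vdot_lattice", 0.35),
            target_re=sim.get("target_re"),
            delta_p_lattice=sim.get("delta_p_lattice", 0.0),
            gain=sim.get("gain", 1e-5),
        )
    ] + [
        NostrilSpec(label=name, normal=(0, 0, 1))
        for name in grid.labels
        if name.startswith("nostril")
    ]
    solver = ThermalLatticeSolver(
        grid.mask, props, wall_q=grid.wall_q, openings=openings,
        labels=grid.labels, thermal=sim.get("thermal", False),
    )
    result = solver.run(sim.get("n_iter", 4000), avg_iter=sim.get("avg_iter", 0))
    np.savez_compressed(
        proj.dir / "fields.npz",
        rho=result.rho, v=result.v,
        T=result.T if result.T is not None else np.array([]),
        **{f"label_{k}": v for k, v in grid.labels.items()},
    )


def _stage_postprocessing(proj: Project, config: dict) -> None:
    z = np.load(proj.dir / "fields.npz")
    rho, v = z["rho"], z["v"]
    T = z["T"] if z["T"].size else None
    labels = {
        k[len("label_"):]: z[k] for k in z.files if k.startswith("label_")
    }
    grid = _load_grid(proj)
    summary = summarize_openings(rho, v, T, labels)
    sim = config.get("simulation", {})
    # physical operating point via the unit bridge, then the 4-PR
    # obstruction classification of the simulated steady state
    bridge = UnitBridge.from_viscosity(
        dx=grid.dx * 1e-3, nu_lattice=sim.get("nu", 0.05)
    )
    report = {"summary": summary.as_dict(), "operating_points": {}}
    for side, dp_lat in summary.dp_tot.items():
        mdot = summary.mdot.get(f"nostril_{side}")
        dp_pa = abs(bridge.pressure_to_physical(dp_lat))
        vdot_cm3s = abs(mdot) * bridge.dx**3 / bridge.dt * 1e6 if mdot else 0.0
        point = {"delta_p_pa": dp_pa, "vdot_cm3s": vdot_cm3s}
        if vdot_cm3s > 0:
            r_eff = dp_pa / vdot_cm3s
            lr = log_effective_resistance(r_eff)
            cls = classify_resistance(lr, "one")
            point.update(
                r_eff=r_eff, lr_eff_1=lr,
                obstruction_class=cls.number, class_label=cls.label,
            )
        report["operating_points"][side] = point
    phantom = _make_phantom(config)
    if hasattr(phantom, "centerlines"):
        cls_ = {s: naive_centerline(phantom, side=s).points for s in ("left", "right")}
    else:
        cls_ = {"main": naive_centerline(phantom).points}
    fields = fields_for_profiles(
        type("R", (), {"rho": rho, "v": v, "T": T})()
    )
    df = centerline_profiles(
        fields, grid.mask, grid.origin, grid.dx, cls_,
        n_stations=config.get("postprocessing", {}).get("n_stations", 25),
    )
    df.to_csv(proj.dir / "profiles.csv", index=False)
    (proj.dir / "report.json").write_text(json.dumps(report, indent=2))
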