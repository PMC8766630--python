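"""Two-passage airway phantom.

A topological stand-in for a nasal cavity: two curved passages
("left"/"right") run from separate nostril openings, merge into a single
outlet tube (the "pharynx"), and optionally carry side pockets
("sinuses") connected through narrow ostia.  A configurable asymmetry
factor narrows the minimum cross-section of one passage to emulate
unilateral obstruction: with asymmetry a, the narrowed side's minimal
area is a times the other side's (radius scaled by sqrt(a)).

Geometry (mm), z is the streamwise axis:
pharynx tube from z=0..z_merge at x=0, then the passages separate in x
following a smooth cosine offset up to the nostril plane z=length.
Analytic centerlines per side are returned alongside the surface.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..meshgen.surface import SurfaceGeometry
from .sdf import mesh_from_sdf


@dataclass
class AirwayPhantom:
    geometry: SurfaceGeometry
    asymmetry: float
    length: float
    z_merge: float
    passage_radius: float
    pharynx_radius: float
    offset: float
    narrowed_side: str
    centerlines: dict  # side -> (N, 3) mm polyline, nostril -> pharynx
    nostril_boxes: dict  # side -> (lo, hi) mm patch at the nostril plane
    pharynx_box: tuple  # (lo, hi) mm patch at the pharynx plane
    sinus_pockets: bool = False


def _passage_offset(z, z_merge, length, offset):
    """Lateral center offset of a passage: 0 at merge, `offset` at nostrils."""
    t = np.clip((z - z_merge) / (length - z_merge), 0.0, 1.0)
    return offset * 0.5 * (1 - np.cos(np.pi * t))


def _radius_profile(z, z_merge, length, r, scale):
    """Passage radius with a smooth constriction dip at mid-passage."""
    t = np.clip((z - z_merge) / (length - z_merge), 0.0, 1.0)
    dip = np.exp(-(((t - 0.5) / 0.18) ** 2))
    return r * (1.0 - (1.0 - scale) * dip)


def make_two_passage_airway(
    asymmetry: float = 1.0,
    length: float = 36.0,
    z_merge: float = 12.0,
    passage_radius: float = 3.0,
    pharynx_radius: float = 4.0,
    offset: float = 7.0,
    narrowed_side: str = "left",
    sinus_pockets: bool = False,
    resolution: float = 0.45,
) -> AirwayPhantom:
    """Build the airway surface and its analytic centerlines.

    asymmetry in (0, 1]: ratio of the narrowed side's minimum section
    area to the open side's.
    """
    if not 0 < asymmetry <= 1:
        raise ValueError("asymmetry must be in (0, 1]")
    r_scale = {"left": 1.0, "right": 1.0}
    r_scale[narrowed_side] = float(np.sqrt(asymmetry))
    signs = {"left": -1.0, "right": 1.0}

    def sdf(p):
        x, y, z = p[:, 0], p[:, 1], p[:, 2]
        # pharynx tube (capped at z=0, open into the merge region)
        d_ph = np.sqrt(x**2 + y**2) - pharynx_radius
        d_ph = np.maximum(d_ph, np.maximum(-z, z - (z_merge + 2.0)))
        ds = [d_ph]
        for side, sgn in signs.items():
            xc = sgn * _passage_offset(z, z_merge, length, offset)
            rr = _radius_profile(
                z, z_merge, length, passage_radius, r_scale[side]
            )
            d = np.sqrt((x - xc) ** 2 + y**2) - rr
            d = np.maximum(d, np.maximum(z_merge - 2.0 - z, z - length))
            ds.append(d)
            if sinus_pockets:
                # spherical pocket connected by a narrow ostium
                zc = (z_merge + length) / 2
                cx = sgn * (offset + 2.5)
                pocket = (
                    np.sqrt((x - cx) ** 2 + y**2 + (z - zc) ** 2) - 2.0
                )
                ax = np.clip((x - sgn * offset * 0.5) * sgn, 0, 2.8)
                ost = (
                    np.sqrt(
                        (x - sgn * (offset * 0.5 + ax)) ** 2
                        + y**2
                        + (z - zc) ** 2
                    )
                    - 0.8
                )
                ds.extend([pocket, ost])
        return np.minimum.reduce(ds)

    m = offset + passage_radius + 4
    geom = mesh_from_sdf(
        sdf, (-m, -passage_radius - 3, 0.0), (m, passage_radius + 3, length),
        resolution,
    )
    centerlines = {}
    for side, sgn in signs.items():
        zs = np.linspace(length, 0.0, 73)
        xs = sgn * _passage_offset(zs, z_merge, length, offset)
        centerlines[side] = np.stack([xs, np.zeros_like(zs), zs], axis=1)
    pd = 1.2  # patch depth, mm
    nostril_boxes = {
        side: (
            (sgn * offset - passage_radius, -passage_radius, length - pd),
            (sgn * offset + passage_radius, passage_radius, length + 1e-6),
        )
        for side, sgn in signs.items()
    }
    pharynx_box = (
        (-pharynx_radius, -pharynx_radius, -1e-6),
        (pharynx_radius, pharynx_radius, pd),
    )
    return AirwayPhantom(
        geometry=geom,
        asymmetry=asymmetry,
        length=length,
        z_merge=z_merge,
        passage_radius=passage_radius,
        pharynx_radius=pharynx_radius,
        offset=offset,
        narrowed_side=narrowed_side,
        centerlines=centerlines,
        nostril_boxes=nostril_boxes,
        pharynx_box=pharynx_box,
        sinus_pockets=sinus_pockets,
    )
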