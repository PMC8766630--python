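"""Flux-versus-pressure overlay of 4-PR measurements and simulation points.

Rhinologists read 4-PR results from an xy-plot of volume flux (cm^3/s) over
pressure loss (Pa), one loop per phase.  Steady simulations correspond to a
respiration frequency of zero, i.e. Strouhal number Sr = 0, and are placed
as individual points onto the measured loops.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .recording import FourPhaseRecording


@dataclass(frozen=True)
class OverlayPoint:
    """A single (pressure loss, volume flux) operating point."""

    delta_p: float  # Pa
    vdot: float  # cm^3/s
    sr: float = 0.0  # Strouhal number; steady simulations carry 0
    source: str = "simulation"


def overlay_data(
    rec_insp: FourPhaseRecording,
    rec_exp: FourPhaseRecording,
    sim_points: list[OverlayPoint] | None = None,
) -> pd.DataFrame:
    """Merge measurement loops and steady simulation points into one table.

    Returns a DataFrame with columns ``delta_p_pa, vdot_cm3s, sr, source,
    series`` ready for CSV export or plotting (flux over pressure loss).
    """
    sim_points = sim_points or []
    for p in sim_points:
        if p.source == "simulation" and p.sr != 0.0:
            raise ValueError("steady simulation points must carry Sr == 0")
    frames = []
    for rec, series in ((rec_insp, "inspiration"), (rec_exp, "expiration")):
        frames.append(
            pd.DataFrame(
                {
                    "delta_p_pa": rec.delta_p,
                    "vdot_cm3s": rec.vdot,
                    "sr": float("nan"),
                    "source": "measurement",
                    "series": series,
                }
            )
        )
    if sim_points:
        frames.append(
            pd.DataFrame(
                {
                    "delta_p_pa": [p.delta_p for p in sim_points],
                    "vdot_cm3s": [p.vdot for p in sim_points],
                    "sr": [p.sr for p in sim_points],
                    "source": [p.source for p in sim_points],
                    "series": "simulation",
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
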