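"""Recordings of 4-phase rhinomanometry (4-PR) measurements.

A recording holds one full respiration cycle of differential pressure
``delta_p`` (Pa, nasopharynx vs. mask) and signed volume flux ``vdot``
(cm^3/s, positive at inspiration) sampled over time ``t`` (s).
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

#: Mandatory CSV column names for waveform files.
CSV_COLUMNS = ("time_s", "delta_p_pa", "vdot_cm3s")


class Side(str, enum.Enum):
    LEFT = "left"
    RIGHT = "right"
    TOTAL = "total"


class Phase(str, enum.Enum):
    INSPIRATION = "inspiration"
    EXPIRATION = "expiration"


@dataclass(frozen=True)
class FourPhaseRecording:
    """One sampled respiration cycle for a single nasal side.

    Attributes
    ----------
    side : Side
        Measured side (``left``, ``right``) or ``total`` nose.
    t : ndarray
        Sample times in seconds, strictly increasing.
    delta_p : ndarray
        Differential pressure in Pa.
    vdot : ndarray
        Signed volume flux in cm^3/s (+ inspiration, - expiration).
    """

    side: Side
    t: np.ndarray
    delta_p: np.ndarray
    vdot: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        dp = np.asarray(self.delta_p, dtype=float)
        vd = np.asarray(self.vdot, dtype=float)
        if not (len(t) == len(dp) == len(vd)):
            raise ValueError("t, delta_p, vdot must have equal length")
        if len(t) < 4:
            raise ValueError("a recording needs at least 4 samples")
        if not np.all(np.diff(t) > 0):
            raise ValueError("non-monotone time")
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "delta_p", dp)
        object.__setattr__(self, "vdot", vd)

    @property
    def T(self) -> float:
        """Duration of the recorded cycle in seconds."""
        return float(self.t[-1] - self.t[0])

    def phase_mask(self, phase: Phase) -> np.ndarray:
        """Boolean mask of the samples belonging to one respiration phase."""
        phase = Phase(phase)
        if phase is Phase.INSPIRATION:
            return self.vdot > 0
        return self.vdot < 0


def load_recording(path: str | Path, side: Side | str) -> FourPhaseRecording:
    """Read a waveform CSV (columns ``time_s, delta_p_pa, vdot_cm3s``)."""
    df = pd.read_csv(path)
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing column(s) in waveform file: {missing}")
    return FourPhaseRecording(
        side=Side(side),
        t=df["time_s"].to_numpy(float),
        delta_p=df["delta_p_pa"].to_numpy(float),
        vdot=df["vdot_cm3s"].to_numpy(float),
    )


def save_recording(rec: FourPhaseRecording, path: str | Path) -> None:
    """Write a recording back to the waveform CSV layout."""
    pd.DataFrame(
        {"time_s": rec.t, "delta_p_pa": rec.delta_p, "vdot_cm3s": rec.vdot}
    ).to_csv(path, index=False)


@dataclass
class ResistanceResult:
    """Effective-resistance analysis of one measurement.

    ``r_eff`` is in Pa*s/cm^3; the log quantities are the dimensionless
    rhinomanometric classification scales; ``obstruction_class`` is 1..5.
    """

    r_eff: float
    lr_eff_1: float
    obstruction_class: int
    class_label: str
    lr_eff_2: Optional[float] = None
    vr_insp: Optional[float] = None
    vr_exp: Optional[float] = None
    side: Optional[str] = None
    method: Optional[str] = None
    extras: dict = field(default_factory=dict)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "side": self.side,
            "method": self.method,
            "r_eff_pa_s_cm3": self.r_eff,
            "lr_eff_1": self.lr_eff_1,
            "lr_eff_2": self.lr_eff_2,
            "vr_insp_pa_s_cm3": self.vr_insp,
            "vr_exp_pa_s_cm3": self.vr_exp,
            "obstruction_class": self.obstruction_class,
            "class_label": self.class_label,
            **self.extras,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text
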