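"""4-phase rhinomanometry: recordings, resistances, classification, overlay."""

from .recording import (
    CSV_COLUMNS,
    FourPhaseRecording,
    Phase,
    ResistanceResult,
    Side,
    load_recording,
    save_recording,
)
from .resistance import FLUX_FLOOR_FRACTION, effective_resistance, vertex_resistance
from .classify import (
    CLASS_LABELS,
    ONE_SIDED_UPPER_BOUNDS,
    TWO_SIDED_UPPER_BOUNDS,
    ObstructionClass,
    classify_resistance,
    combined_log_resistance,
    log_effective_resistance,
)
from .overlay import OverlayPoint, overlay_data


def analyze(rec: FourPhaseRecording, method: str = "rms_ratio") -> ResistanceResult:
    """Full single-recording analysis: R_eff, LR_eff^1, VR, and class."""
    r = effective_resistance(rec, method=method)
    lr1 = log_effective_resistance(r)
    cls = classify_resistance(lr1, sided="one")

    def _vr(phase):
        try:
            return vertex_resistance(rec, phase)
        except ValueError:
            return None

    return ResistanceResult(
        r_eff=r,
        lr_eff_1=lr1,
        obstruction_class=cls.number,
        class_label=cls.label,
        vr_insp=_vr(Phase.INSPIRATION),
        vr_exp=_vr(Phase.EXPIRATION),
        side=rec.side.value,
        method=method,
    )


__all__ = [
    "CSV_COLUMNS",
    "CLASS_LABELS",
    "FLUX_FLOOR_FRACTION",
    "ONE_SIDED_UPPER_BOUNDS",
    "TWO_SIDED_UPPER_BOUNDS",
    "FourPhaseRecording",
    "ObstructionClass",
    "OverlayPoint",
    "Phase",
    "ResistanceResult",
    "Side",
    "analyze",
    "classify_resistance",
    "combined_log_resistance",
    "effective_resistance",
    "load_recording",
    "log_effective_resistance",
    "overlay_data",
    "save_recording",
    "vertex_resistance",
]
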