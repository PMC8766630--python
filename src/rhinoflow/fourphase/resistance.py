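"""Effective and vertex resistance of a respiration cycle.

The effective resistance R_eff is defined as the ratio of the effective
(RMS) differential pressure and the effective volume flux over one cycle,

    R_eff = dp_eff / vdot_eff .

The rhinomanometric literature also prints this as the square root of the
cycle mean of the instantaneous ratio,

    R_eff = sqrt( (1/T) * int_0^T (dp / vdot) dt ),

which only coincides with the RMS ratio when dp/vdot is constant in time.
Both conventions are provided; the RMS ratio is the default because it is
the defining equality.  See :func:`effective_resistance`.
"""

from __future__ import annotations

import numpy as np

from .recording import FourPhaseRecording, Phase

#: Fraction of the cycle's peak |vdot| below which samples are excluded
#: from the integral-form quadrature (guards against division blow-up at
#: flow reversal).
FLUX_FLOOR_FRACTION = 0.01


def _trapz_mean(y: np.ndarray, t: np.ndarray) -> float:
    """Time-average of y(t) by trapezoidal quadrature."""
    T = t[-1] - t[0]
    return float(np.trapezoid(y, t) / T)


def effective_resistance(
    rec: FourPhaseRecording, method: str = "rms_ratio"
) -> float:
    """Effective resistance R_eff in Pa*s/cm^3.

    Parameters
    ----------
    rec : FourPhaseRecording
        One full respiration cycle.
    method : {"rms_ratio", "printed_integral"}
        ``rms_ratio`` returns RMS(dp)/RMS(vdot) (the defining equality).
        ``printed_integral`` returns sqrt((1/T) int dp/vdot dt) with
        samples below the flux floor excluded from the integrand.
    """
    vd = rec.vdot
    dp = rec.delta_p
    if not np.any(vd != 0.0):
        raise ValueError("degenerate recording: volume flux identically zero")
    if method == "rms_ratio":
        rms_dp = np.sqrt(_trapz_mean(dp**2, rec.t))
        rms_vd = np.sqrt(_trapz_mean(vd**2, rec.t))
        return float(rms_dp / rms_vd)
    if method == "printed_integral":
        floor = FLUX_FLOOR_FRACTION * np.max(np.abs(vd))
        keep = np.abs(vd) >= floor
        if keep.sum() < 2:
            raise ValueError("degenerate recording: all samples below flux floor")
        ratio = dp[keep] / vd[keep]
        if np.any(ratio < 0):
            raise ValueError(
                "printed_integral requires dp/vdot >= 0 above the flux floor"
            )
        mean_ratio = _trapz_mean(ratio, rec.t[keep])
        return float(np.sqrt(mean_ratio))
    raise ValueError(f"unknown method {method!r}")


def vertex_resistance(rec: FourPhaseRecording, phase: Phase | str) -> float:
    """Resistance dp/vdot at the highest point of the respiration wave.

    The vertex resistance VR is evaluated at the sample of maximum |vdot|
    within the requested phase (inspiration: vdot > 0; expiration: vdot < 0).
    """
    mask = rec.phase_mask(Phase(phase))
    if not np.any(mask):
        raise ValueError(f"phase {Phase(phase).value!r} absent from recording")
    idx = np.flatnonzero(mask)
    k = idx[np.argmax(np.abs(rec.vdot[idx]))]
    return float(rec.delta_p[k] / rec.vdot[k])
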