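"""Synthetic 4-PR respiration waveforms with known ground-truth resistance.

The generator produces a sinusoidal volume flux over one full respiration
cycle and a differential pressure consistent with a prescribed resistance
``r_true``:

* ``convention="rms"``:     dp = r_true * vdot, so the RMS-ratio estimator
  recovers r_true exactly.
* ``convention="printed"``: dp = r_true**2 * vdot, so the integral-form
  estimator sqrt((1/T) int dp/vdot dt) recovers r_true exactly.

Optional multiplicative Gaussian noise (seeded) perturbs the pressure.
"""

from __future__ import annotations

import numpy as np

from ..fourphase.recording import FourPhaseRecording, Side


def make_4pr_waveform(
    r_true: float,
    cycle_s: float = 4.0,
    peak_flux: float = 400.0,
    noise: float = 0.0,
    seed: int | None = None,
    n_samples: int = 401,
    side: Side | str = Side.TOTAL,
    convention: str = "rms",
) -> tuple[FourPhaseRecording, FourPhaseRecording]:
    """Generate one respiration cycle split into inspiration/expiration.

    Parameters
    ----------
    r_true : float
        Ground-truth resistance in Pa*s/cm^3 (> 0).
    cycle_s : float
        Duration of the full cycle in seconds (quiet breathing ~4 s).
    peak_flux : float
        Peak volume flux in cm^3/s (quiet breathing ~400 cm^3/s).
    noise : float
        Relative sigma of multiplicative Gaussian noise on the pressure.
    seed : int, optional
        Seed for the noise generator; generation is deterministic per seed.
    convention : {"rms", "printed"}
        Which effective-resistance convention the pressure obeys.

    Returns
    -------
    (full_cycle, full_cycle_expiration_view)
        Two recordings: the full cycle (inspiration half first) and the
        same cycle with the expiration half leading, mirroring how the two
        loops of a 4-PR plot are recorded.  Both carry the whole cycle so
        that either can be analyzed stand-alone.
    """
    if not r_true > 0:
        raise ValueError("r_true must be positive")
    t = np.linspace(0.0, cycle_s, n_samples)
    vdot = peak_flux * np.sin(2.0 * np.pi * t / cycle_s)
    if convention == "rms":
        dp = r_true * vdot
    elif convention == "printed":
        dp = r_true**2 * vdot
    else:
        raise ValueError(f"unknown convention {convention!r}")
    if noise > 0:
        rng = np.random.default_rng(seed)
        dp = dp * (1.0 + noise * rng.standard_normal(dp.shape))
    rec = FourPhaseRecording(side=Side(side), t=t, delta_p=dp, vdot=vdot)
    # Expiration-led view: shift the cycle by half a period.
    half = n_samples // 2
    dp2 = np.concatenate([dp[half:-1], dp[: half + 1]])
    vd2 = np.concatenate([vdot[half:-1], vdot[: half + 1]])
    rec_exp = FourPhaseRecording(side=Side(side), t=t, delta_p=dp2, vdot=vd2)
    return rec, rec_exp
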