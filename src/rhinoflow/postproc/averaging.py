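"""Temporal moving average of monitor series.

a_bar(t) = 1/(dt+1) * sum_{k=-dt/2}^{dt/2} a(t+k)  with an even window
parameter dt (so the window of dt+1 samples is symmetric).  At the series
edges the window is truncated to the available samples and the count
renormalized.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class AveragedSeries:
    values: np.ndarray
    window: int  # dt (even); the window holds dt+1 samples
    stride: int = 1


def moving_average(series, dt: int) -> AveragedSeries:
    """Centered moving average with truncate-and-renormalize edges."""
    if dt % 2 != 0:
        raise ValueError(
            f"averaging interval must be even (got {dt}); try {dt - 1} or {dt + 1}"
        )
    a = np.asarray(series, float)
    if a.ndim != 1:
        raise ValueError("series must be 1-D")
    if len(a) <= dt:
        raise ValueError("series must be longer than the window")
    kernel = np.ones(dt + 1)
    s = np.convolve(a, kernel, mode="same")
    n = np.convolve(np.ones_like(a), kernel, mode="same")
    return AveragedSeries(values=s / n, window=dt)
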