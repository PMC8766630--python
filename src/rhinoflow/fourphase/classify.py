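"""Obstruction classification from logarithmic effective resistances.

Classification uses the one-sided logarithmic effective resistance

    LR_eff^1 = log10(10 * R_eff)

and, for the total nose measured on both sides, the two-sided quantity

    LR_eff^2 = log10(10 * R_left * R_right / (R_left + R_right)),

i.e. the parallel-resistor combination of the per-side effective
resistances.  Five obstruction classes (very low .. very high) are defined
by published upper bounds on these scales.

The published two-sided column is internally non-monotone (class 3's range
lies below class 2's); both tables are therefore shipped verbatim as
configuration and evaluated through a single ordered-threshold engine that
takes the running maximum of the printed upper bounds and resolves values
in overlap regions to the LOWER class.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

CLASS_LABELS = ("very low", "low", "moderate", "high", "very high")

#: Printed per-class upper bounds (classes 1..4; class 5 is open-ended).
ONE_SIDED_UPPER_BOUNDS = (0.755, 0.960, 1.135, 1.365)
TWO_SIDED_UPPER_BOUNDS = (0.423, 0.703, 0.592, 0.755)


@dataclass(frozen=True)
class ObstructionClass:
    number: int  # 1..5
    label: str

    def __int__(self) -> int:
        return self.number


def log_effective_resistance(r_eff: float) -> float:
    """LR_eff^1 = log10(10 * R_eff); requires R_eff > 0."""
    if not r_eff > 0:
        raise ValueError("r_eff must be positive")
    return math.log10(10.0 * r_eff)


def combined_log_resistance(r_left: float, r_right: float) -> float:
    """LR_eff^2 from the per-side effective resistances (parallel combination)."""
    if not (r_left > 0 and r_right > 0):
        raise ValueError("both resistances must be positive")
    return math.log10(10.0 * (r_left * r_right) / (r_left + r_right))


def _ordered_thresholds(bounds: Sequence[float]) -> list[float]:
    # Running maximum turns the printed per-class upper bounds into ordered
    # thresholds; with `value <= threshold -> first matching class` this
    # resolves printed overlaps to the lower class.
    out, cur = [], -math.inf
    for b in bounds:
        cur = max(cur, b)
        out.append(cur)
    return out


def classify_resistance(
    lr_eff: float,
    sided: str = "one",
    upper_bounds: Sequence[float] | None = None,
) -> ObstructionClass:
    """Map a logarithmic effective resistance to an obstruction class 1..5.

    Parameters
    ----------
    lr_eff : float
        LR_eff^1 (``sided="one"``) or LR_eff^2 (``sided="two"``).
    sided : {"one", "two"}
        Which published table to use.
    upper_bounds : sequence of 4 floats, optional
        Override the per-class upper bounds (thresholds are configuration,
        not code).
    """
    if math.isnan(lr_eff):
        raise ValueError("lr_eff is NaN")
    if upper_bounds is None:
        if sided == "one":
            upper_bounds = ONE_SIDED_UPPER_BOUNDS
        elif sided == "two":
            upper_bounds = TWO_SIDED_UPPER_BOUNDS
        else:
            raise ValueError(f"unknown sided {sided!r}")
    for k, thr in enumerate(_ordered_thresholds(upper_bounds), start=1):
        if lr_eff <= thr:
            return ObstructionClass(k, CLASS_LABELS[k - 1])
    return ObstructionClass(5, CLASS_LABELS[4])
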