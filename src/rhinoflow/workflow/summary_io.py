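"""Small helper shared by pipeline and cases: summary from label arrays."""

from __future__ import annotations

import numpy as np

from ..postproc import FlowSummary, boundary_summary


def summarize_openings(
    rho: np.ndarray, v: np.ndarray, T, labels: dict, **kwargs
) -> FlowSummary:
    openings = {
        name: {
            "mask": np.asarray(mask, bool),
            "normal": (0, 0, -1) if name == "pharynx" else (0, 0, 1),
        }
        for name, mask in labels.items()
    }
    return boundary_summary(rho, v, T, openings, **kwargs)
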