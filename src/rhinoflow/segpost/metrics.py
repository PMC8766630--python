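"""Segmentation quality metrics: accuracy, Jaccard, segment and component match.

All metrics are reported in percent.  Per-slice quantities are averaged
over the classes of a slice and then over slices:

* accuracy — % of voxels with equal labels;
* mean Jaccard J — intersection-over-union per class per slice (a class
  empty in both volumes contributes 100%), averaged over classes, then
  slices;
* segment match S — per slice, % of classes whose presence/absence agrees;
* component match C — per slice and class the absolute difference in
  2-D connected-component count (8-connectivity), mapped to a % match by
  ``100/(1 + |delta|)`` (zero difference = 100%), averaged.  The mapping
  is configurable; any monotone map with 0 -> 100% is admissible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy import ndimage

from .labels import LabelVolume

STRUCT_8 = np.ones((3, 3), dtype=bool)


@dataclass(frozen=True)
class SegMetrics:
    accuracy: float  # %
    mean_jaccard: float  # %
    segment_match: float  # %
    component_match: float  # %

    def as_dict(self) -> dict:
        return {
            "accuracy_pct": self.accuracy,
            "mean_jaccard_pct": self.mean_jaccard,
            "segment_match_pct": self.segment_match,
            "component_match_pct": self.component_match,
        }


def default_component_map(delta: int) -> float:
    return 100.0 / (1.0 + abs(delta))


def segmentation_metrics(
    pred: LabelVolume | np.ndarray,
    truth: LabelVolume | np.ndarray,
    n_classes: int | None = None,
    component_map: Callable[[int], float] = default_component_map,
) -> SegMetrics:
    """Compare a predicted label volume against a reference, slice-wise."""
    p = pred.voxels if isinstance(pred, LabelVolume) else np.asarray(pred)
    t = truth.voxels if isinstance(truth, LabelVolume) else np.asarray(truth)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {t.shape}")
    if n_classes is None:
        n_classes = int(max(p.max(), t.max())) + 1
    accuracy = 100.0 * float((p == t).mean())
    j_slices, s_slices, c_slices = [], [], []
    for ps, ts in zip(p, t):
        j_cls, s_cls, c_cls = [], [], []
        for s in range(n_classes):
            a, b = ps == s, ts == s
            inter = np.logical_and(a, b).sum()
            union = np.logical_or(a, b).sum()
            j_cls.append(100.0 if union == 0 else 100.0 * inter / union)
            s_cls.append(a.any() == b.any())
            _, na = ndimage.label(a, structure=STRUCT_8)
            _, nb = ndimage.label(b, structure=STRUCT_8)
            c_cls.append(component_map(na - nb))
        j_slices.append(np.mean(j_cls))
        s_slices.append(100.0 * np.mean(s_cls))
        c_slices.append(np.mean(c_cls))
    return SegMetrics(
        accuracy=accuracy,
        mean_jaccard=float(np.mean(j_slices)),
        segment_match=float(np.mean(s_slices)),
        component_match=float(np.mean(c_slices)),
    )
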