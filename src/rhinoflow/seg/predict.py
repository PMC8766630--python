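"""Inference: slice-wise segmentation of CT-like intensity volumes."""

from __future__ import annotations

import numpy as np

from .network import SegmentationCNN


def roi_window(
    slice_shape: tuple[int, int], roi: int, offset: tuple[int, int] = (0, 0)
) -> tuple[slice, slice]:
    """Centered ROI crop window with a configurable offset.

    The ROI emulates restricting full-resolution slices to the nasal
    cavity region before segmentation.
    """
    h, w = slice_shape
    oy, ox = offset
    y0 = (h - roi) // 2 + oy
    x0 = (w - roi) // 2 + ox
    if y0 < 0 or x0 < 0 or y0 + roi > h or x0 + roi > w:
        raise ValueError(
            f"ROI {roi} px with offset {offset} exceeds slice extent {slice_shape}"
        )
    return slice(y0, y0 + roi), slice(x0, x0 + roi)


def predict_slice(model: SegmentationCNN, image: np.ndarray) -> np.ndarray:
    """Per-pixel class ids for one ROI-sized slice.

    Binary mode thresholds the sigmoid map at 0.5; multi-class mode takes
    the argmax over the class probabilities (ties resolve to the lowest
    class index).
    """
    P = model.forward(image)
    if model.spec.n_classes == 2:
        return (P > 0.5).astype(np.int16)
    return np.argmax(P, axis=0).astype(np.int16)


def predict_segmentation(
    model: SegmentationCNN,
    volume: np.ndarray,
    roi_offset: tuple[int, int] = (0, 0),
) -> np.ndarray:
    """Segment a (Z, H, W) intensity volume slice by slice.

    Each axial slice is cropped to the model's ROI window and classified;
    the per-slice label maps are stacked into a (Z, roi, roi) volume.
    """
    volume = np.asarray(volume, float)
    if volume.ndim != 3:
        raise ValueError("expected a (Z, H, W) volume")
    roi = model.spec.roi_size
    ys, xs = roi_window(volume.shape[1:], roi, roi_offset)
    return np.stack([predict_slice(model, sl[ys, xs]) for sl in volume])
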