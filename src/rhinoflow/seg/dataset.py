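"""Slice datasets for CNN segmentation training.

A dataset holds axial CT-like intensity slices (values scaled to [0,1])
and per-slice one-hot label stacks over S classes (S=2 for the binary
air/non-air task, S=9 for the multi-class task).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class SliceDataset:
    """Images and one-hot labels for per-pixel segmentation.

    Attributes
    ----------
    images : list of (H, W) float arrays in [0, 1]
    labels : list of (S, H, W) one-hot stacks (exactly one 1 per pixel)
    """

    images: list = field(default_factory=list)
    labels: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.images) != len(self.labels):
            raise ValueError("images and labels must pair up")
        for img, lab in zip(self.images, self.labels):
            img = np.asarray(img)
            lab = np.asarray(lab)
            if img.shape != lab.shape[1:]:
                raise ValueError("label stack must match image shape")
            if not np.all(lab.sum(axis=0) == 1):
                raise ValueError("labels must be one-hot per pixel")

    @property
    def N(self) -> int:
        return len(self.images)

    @property
    def n_classes(self) -> int:
        return int(self.labels[0].shape[0]) if self.labels else 0

    def class_pixel_counts(self) -> np.ndarray:
        """Total pixel count per class over the whole dataset."""
        counts = np.zeros(self.n_classes, dtype=np.int64)
        for lab in self.labels:
            counts += lab.reshape(lab.shape[0], -1).sum(axis=1).astype(np.int64)
        return counts

    def copy_shallow(self) -> "SliceDataset":
        return SliceDataset(list(self.images), list(self.labels))


def labels_from_classmap(classmap: np.ndarray, n_classes: int) -> np.ndarray:
    """(H, W) integer class map -> (S, H, W) one-hot stack."""
    classmap = np.asarray(classmap)
    if classmap.min() < 0 or classmap.max() >= n_classes:
        raise ValueError("class ids out of range")
    return (np.arange(n_classes)[:, None, None] == classmap[None]).astype(np.uint8)
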