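"""Labeled head-like CT phantom for segmentation training.

Generates an axial-slice volume emulating the 9-class anatomy: an
ellipsoidal "head" of tissue holding seven air spaces (paired frontal and
sphenoid sinus pockets, the combined maxillary pockets, and a central
nasal/oral cavity), thin bone shells around the cavities plus an outer
skull shell, and air outside the head.  Class intensities follow nominal
Hounsfield-unit values (air -1000, tissue +40, bone +700) with Gaussian
noise, then rescale to [0, 1] over the window [-1000, 1000].

The class layout mirrors the multi-class label table of
:mod:`rhinoflow.segpost.labels` and reproduces the severe class imbalance
of real data (the five sinus segments together stay below ~5% of pixels).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from ..segpost.labels import CLASS_NAMES_9, LabelVolume

HU_AIR, HU_TISSUE, HU_BONE = -1000.0, 40.0, 700.0
HU_WINDOW = (-1000.0, 1000.0)


@dataclass
class HeadPhantom:
    intensity: np.ndarray  # (Z, H, W) floats in [0, 1]
    labels: LabelVolume  # ground-truth 9-class map
    seed: int
    sigma_hu: float


def _ellipsoid(shape, center, radii):
    zz, yy, xx = np.mgrid[: shape[0], : shape[1], : shape[2]]
    return (
        ((zz - center[0]) / radii[0]) ** 2
        + ((yy - center[1]) / radii[1]) ** 2
        + ((xx - center[2]) / radii[2]) ** 2
    ) <= 1.0


def make_labeled_head(
    shape: tuple[int, int, int] = (20, 64, 64),
    sigma_hu: float = 30.0,
    seed: int = 0,
) -> HeadPhantom:
    """Build one labeled head volume (axial slices along axis 0)."""
    Z, H, W = shape
    cz, cy, cx = Z / 2, H / 2, W / 2
    head = _ellipsoid(shape, (cz, cy, cx), (0.95 * Z / 2, 0.42 * H, 0.36 * W))

    scale = H / 64.0
    zs = Z / 20.0

    def pocket(center_zyx, radii_zyx):
        return _ellipsoid(shape, center_zyx, radii_zyx) & head

    cavities = {}
    # central nasal/oral cavity: tall narrow midline region
    cavities[5] = pocket((cz, cy + 4 * scale, cx), (7 * zs, 13 * scale, 4.5 * scale))
    # frontal sinuses: upper front, small, left/right of midline
    cavities[0] = pocket((cz + 4 * zs, cy - 17 * scale, cx - 4 * scale),
                         (2.5 * zs, 3 * scale, 3 * scale))
    cavities[1] = pocket((cz + 4 * zs, cy - 17 * scale, cx + 4 * scale),
                         (2.5 * zs, 3 * scale, 3 * scale))
    # maxillary sinuses (combined class): lateral mid-face pockets
    cavities[2] = pocket((cz, cy + 6 * scale, cx - 13 * scale),
                         (4 * zs, 5 * scale, 4 * scale)) | pocket(
        (cz, cy + 6 * scale, cx + 13 * scale), (4 * zs, 5 * scale, 4 * scale)
    )
    # sphenoid sinuses: deep central pockets, left/right
    cavities[3] = pocket((cz - 4 * zs, cy - 6 * scale, cx - 3.5 * scale),
                         (2.5 * zs, 2.5 * scale, 2.5 * scale))
    cavities[4] = pocket((cz - 4 * zs, cy - 6 * scale, cx + 3.5 * scale),
                         (2.5 * zs, 2.5 * scale, 2.5 * scale))

    labels = np.full(shape, 8, dtype=np.int16)  # tissue
    labels[~head] = 6  # air outside
    # bone: outer skull shell + shells around all cavities
    skull = head & ~ndimage.binary_erosion(head, iterations=2)
    all_cav = np.zeros(shape, bool)
    for m in cavities.values():
        all_cav |= m
    shells = ndimage.binary_dilation(all_cav, iterations=2) & ~all_cav & head
    labels[skull] = 7
    labels[shells & (labels == 8)] = 7
    for cid, m in cavities.items():
        labels[m] = cid

    hu = np.empty(shape, float)
    hu[np.isin(labels, [0, 1, 2, 3, 4, 5, 6])] = HU_AIR
    hu[labels == 7] = HU_BONE
    hu[labels == 8] = HU_TISSUE
    rng = np.random.default_rng(seed)
    if sigma_hu > 0:
        hu = hu + sigma_hu * rng.standard_normal(shape)
    lo, hi = HU_WINDOW
    intensity = np.clip((hu - lo) / (hi - lo), 0.0, 1.0)
    return HeadPhantom(
        intensity=intensity,
        labels=LabelVolume(labels, class_names=dict(CLASS_NAMES_9)),
        seed=seed,
        sigma_hu=sigma_hu,
    )


def head_slice_dataset(
    n_heads: int = 2,
    shape: tuple[int, int, int] = (20, 64, 64),
    sigma_hu: float = 30.0,
    seed: int = 0,
):
    """SliceDataset of axial slices pooled from several head phantoms."""
    from ..seg.dataset import SliceDataset, labels_from_classmap

    images, labels = [], []
    for k in range(n_heads):
        ph = make_labeled_head(shape, sigma_hu=sigma_hu, seed=seed + k)
        for z in range(shape[0]):
            images.append(ph.intensity[z])
            labels.append(labels_from_classmap(ph.labels.voxels[z], 9))
    return SliceDataset(images, labels)
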