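"""Greedy oversampling balancer for the sinus classes.

The five paranasal-sinus segments occupy only a few percent of the pixels
of a typical training set, so a CNN tends to ignore them.  The balancer
repeatedly finds the least-dominant sinus segment, picks a training slice
containing it, applies a random translation or a horizontal flip (the
flip swaps left/right sinus labels, assuming bilateral symmetry), and
appends the transformed copy.  It stops when the mean absolute pairwise
difference of the sinus pixel counts stops decreasing, or when the
dataset has grown to a size cap.

Original slices are never altered; only transformed copies are appended.
"""

from __future__ import annotations

import warnings

import numpy as np

from .dataset import SliceDataset

#: Maximum oversampled size as a multiple of the original dataset.
MAX_OVERSAMPLE_FACTOR = 10
#: Maximum random translation as a fraction of the ROI side length.
MAX_SHIFT_FRACTION = 0.10


def horizontal_flip(
    image: np.ndarray, label: np.ndarray, mirror_pairs: dict[int, int]
) -> tuple[np.ndarray, np.ndarray]:
    """Flip left-right and exchange mirrored class channels."""
    img = image[:, ::-1].copy()
    lab = label[:, :, ::-1].copy()
    out = lab.copy()
    for a, b in mirror_pairs.items():
        out[b] = lab[a]
        out[a] = lab[b]
    return img, out


def translate(
    image: np.ndarray, label: np.ndarray, shift: tuple[int, int]
) -> tuple[np.ndarray, np.ndarray]:
    """Integer translation with zero fill; labels shift identically.

    Pixels shifted in from outside get intensity 0 and the background
    class (channel 0 in binary mode; the 'outside air' convention is the
    caller's choice of channel order in multi-class mode — exposed via
    ``fill_class`` in :func:`balance_training_set`).
    """
    dy, dx = shift
    img = np.zeros_like(image)
    lab = np.zeros_like(label)
    h, w = image.shape
    ys_src = slice(max(0, -dy), min(h, h - dy))
    xs_src = slice(max(0, -dx), min(w, w - dx))
    ys_dst = slice(max(0, dy), min(h, h + dy))
    xs_dst = slice(max(0, dx), min(w, w + dx))
    img[ys_dst, xs_dst] = image[ys_src, xs_src]
    lab[:, ys_dst, xs_dst] = label[:, ys_src, xs_src]
    return img, lab


def _sinus_counts(ds: SliceDataset, sinus_ids: list[int]) -> np.ndarray:
    return ds.class_pixel_counts()[sinus_ids]


def mean_abs_pairwise_diff(counts: np.ndarray) -> float:
    c = np.asarray(counts, dtype=float)
    if len(c) < 2:
        return 0.0
    diffs = np.abs(c[:, None] - c[None, :])
    n = len(c)
    return float(diffs.sum() / (n * (n - 1)))


def balance_training_set(
    ds: SliceDataset,
    sinus_class_ids: list[int],
    rng_seed: int = 0,
    mirror_pairs: dict[int, int] | None = None,
    fill_class: int = 0,
    max_factor: int = MAX_OVERSAMPLE_FACTOR,
) -> SliceDataset:
    """Oversample slices until the sinus pixel counts are balanced.

    Parameters
    ----------
    ds : SliceDataset
        Input dataset; returned unchanged (same lists copied) if already
        balanced.
    sinus_class_ids : list of int
        Label-channel indices of the sinus segments to balance.
    mirror_pairs : dict, optional
        Mapping of left<->right class channels exchanged by a horizontal
        flip (each pair listed once, e.g. ``{0: 1, 3: 4}``).
    fill_class : int
        Class channel assigned to pixels translated in from outside.
    """
    mirror_pairs = mirror_pairs or {}
    rng = np.random.default_rng(rng_seed)
    out = ds.copy_shallow()

    counts0 = ds.class_pixel_counts()
    present = [
        cid for cid in sinus_class_ids if cid < len(counts0) and counts0[cid] > 0
    ]
    absent = sorted(set(sinus_class_ids) - set(present))
    if absent:
        warnings.warn(
            f"sinus class(es) {absent} absent from every slice; "
            "excluded from balancing"
        )
    if len(present) < 2:
        return out

    cap = max_factor * ds.N
    score = mean_abs_pairwise_diff(_sinus_counts(out, present))
    max_shift = max(1, int(MAX_SHIFT_FRACTION * ds.images[0].shape[0]))
    while out.N < cap:
        counts = _sinus_counts(out, present)
        least = present[int(np.argmin(counts))]
        candidates = [
            k for k in range(out.N) if out.labels[k][least].any()
        ]
        if not candidates:
            break
        k = int(rng.choice(candidates))
        img, lab = out.images[k], out.labels[k]
        if mirror_pairs and rng.random() < 0.5:
            img2, lab2 = horizontal_flip(img, lab, mirror_pairs)
        else:
            dy = int(rng.integers(-max_shift, max_shift + 1))
            dx = int(rng.integers(-max_shift, max_shift + 1))
            img2, lab2 = translate(img, lab, (dy, dx))
            # re-establish one-hot for zero-filled pixels
            empty = lab2.sum(axis=0) == 0
            lab2[fill_class][empty] = 1
        out.images.append(img2)
        out.labels.append(lab2)
        new_score = mean_abs_pairwise_diff(_sinus_counts(out, present))
        if new_score >= score:
            out.images.pop()
            out.labels.pop()
            break
        score = new_score
    return out
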