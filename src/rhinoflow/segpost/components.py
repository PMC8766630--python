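"""Connected-component post-processing of multi-class label volumes.

Three steps clean a raw CNN segmentation:

1. :func:`split_maxillary` — separate the combined maxillary-sinus class
   into left and right components by centroid position relative to the
   mid-sagittal plane (10-class output).
2. :func:`dissolve_small_components` — voxels of tiny connected
   components (< 10 voxels by default) take the dominant label of their
   3x3x3 neighborhood.
3. :func:`enforce_plausibility` — for healthy anatomy each cavity is one
   connected component; smaller satellite components lying inside another
   cavity's convex region are recolored to the enclosing cavity's class.

Connectivity is 26-neighborhood in 3-D (8-neighborhood within slices).
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
from scipy import ndimage
from scipy.spatial import Delaunay, QhullError

from .labels import (
    MAXILLARY_COMBINED,
    MAXILLARY_LEFT,
    MAXILLARY_RIGHT,
    SINUS_CLASS_IDS,
    LabelVolume,
)

log = logging.getLogger(__name__)

STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


def split_maxillary(
    lv: LabelVolume,
    combined_id: int = MAXILLARY_COMBINED,
    mid_sagittal_x: float | None = None,
) -> LabelVolume:
    """Split the combined maxillary class into left/right by centroid side.

    The mid-sagittal plane defaults to the volume's x midplane.  Components
    whose centroid has x below the plane become left (keep ``combined_id``),
    the rest become the new right id.  More than two sizable components
    only triggers a warning; assignment stays centroid-based.
    """
    out = lv.copy()
    mask = out.voxels == combined_id
    out.class_names[MAXILLARY_LEFT] = "maxillary sinus left"
    out.class_names[MAXILLARY_RIGHT] = "maxillary sinus right"
    if not mask.any():
        return out
    labels, n = ndimage.label(mask, structure=STRUCT_26)
    if mid_sagittal_x is None:
        mid_sagittal_x = (lv.voxels.shape[2] - 1) / 2.0
    big = sum(
        1 for s in ndimage.sum_labels(mask, labels, range(1, n + 1)) if s > 10
    )
    if big > 2:
        warnings.warn(
            f"maxillary class has {big} sizable components; "
            "assigning left/right by centroid anyway"
        )
    centroids = ndimage.center_of_mass(mask, labels, range(1, n + 1))
    for comp_id, (cz, cy, cx) in enumerate(centroids, start=1):
        target = MAXILLARY_LEFT if cx < mid_sagittal_x else MAXILLARY_RIGHT
        out.voxels[labels == comp_id] = target
    return out


def dissolve_small_components(
    lv: LabelVolume, min_voxels: int = 10, to_fixpoint: bool = False
) -> LabelVolume:
    """Dissolve connected components with fewer than ``min_voxels`` voxels.

    Each voxel of a small component takes the most frequent label of its
    3x3x3 neighborhood, with the voxel's own current label excluded from
    the count.  Components of exactly ``min_voxels`` voxels are untouched
    (strict less-than).  With ``to_fixpoint=True`` the pass repeats until
    nothing changes.
    """
    out = lv.copy()
    while True:
        changed = _dissolve_pass(out.voxels, min_voxels)
        if not to_fixpoint or not changed:
            break
    return out


def _dissolve_pass(vox: np.ndarray, min_voxels: int) -> bool:
    targets = []
    for cid in np.unique(vox):
        labels, n = ndimage.label(vox == cid, structure=STRUCT_26)
        if n == 0:
            continue
        sizes = ndimage.sum_labels(np.ones_like(vox), labels, range(1, n + 1))
        for comp_id, size in enumerate(sizes, start=1):
            if size < min_voxels:
                targets.append(np.argwhere(labels == comp_id))
    if not targets:
        return False
    snapshot = vox.copy()  # neighborhood modes read the pre-pass state
    changed = False
    for coords in targets:
        for z, y, x in coords:
            own = snapshot[z, y, x]
            zlo, ylo, xlo = max(z - 1, 0), max(y - 1, 0), max(x - 1, 0)
            nb = snapshot[zlo : z + 2, ylo : y + 2, xlo : x + 2]
            vals, counts = np.unique(nb[nb != own], return_counts=True)
            if len(vals) == 0:
                continue
            vox[z, y, x] = vals[np.argmax(counts)]
            changed = True
    return changed


def enforce_plausibility(
    lv: LabelVolume,
    healthy: bool,
    cavity_ids: tuple[int, ...] | None = None,
) -> LabelVolume:
    """Recolor anatomically implausible satellite sinus components.

    Only applicable to healthy anatomy, where each cavity is a single
    connected component: per sinus class, the largest component keeps the
    label; every smaller component whose centroid lies inside the convex
    region spanned by another cavity's main component is recolored to that
    cavity's class.  With ``healthy=False`` this is a no-op.
    """
    if not healthy:
        log.info("geometry not flagged healthy; plausibility pass skipped")
        return lv.copy()
    if cavity_ids is None:
        cavity_ids = tuple(
            set(SINUS_CLASS_IDS) | {MAXILLARY_LEFT, MAXILLARY_RIGHT}
        )
    out = lv.copy()
    main_components: dict[int, np.ndarray] = {}
    satellites: list[tuple[int, np.ndarray]] = []
    for cid in cavity_ids:
        mask = out.voxels == cid
        if not mask.any():
            continue
        labels, n = ndimage.label(mask, structure=STRUCT_26)
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, range(1, n + 1))
        keep = int(np.argmax(sizes)) + 1
        main_components[cid] = np.argwhere(labels == keep)
        for comp_id in range(1, n + 1):
            if comp_id != keep:
                satellites.append((cid, np.argwhere(labels == comp_id)))
    hulls = {}
    for cid, pts in main_components.items():
        if len(pts) >= 4:
            try:
                hulls[cid] = Delaunay(pts)
            except QhullError:
                pass
    for cid, coords in satellites:
        centroid = coords.mean(axis=0)
        for other, hull in hulls.items():
            if other == cid:
                continue
            if hull.find_simplex(centroid) >= 0:
                out.voxels[tuple(coords.T)] = other
                break
    return out
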