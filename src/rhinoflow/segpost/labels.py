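"""Label volumes: 3-D integer class maps aligned to CT-like volumes.

The 9 anatomical classes of the multi-class segmentation are, by default:

====  ==========================
 id   segment
====  ==========================
 0    frontal sinus left
 1    frontal sinus right
 2    maxillary sinuses (combined)
 3    sphenoid sinus left
 4    sphenoid sinus right
 5    nasal and oral cavity
 6    air outside / mastoid cells
 7    bone
 8    tissue
====  ==========================

Splitting the combined maxillary class into left/right components yields a
10-class table (ids 9 = maxillary right, with 2 re-used as maxillary left).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

CLASS_NAMES_9 = {
    0: "frontal sinus left",
    1: "frontal sinus right",
    2: "maxillary sinuses",
    3: "sphenoid sinus left",
    4: "sphenoid sinus right",
    5: "nasal and oral cavity",
    6: "air outside",
    7: "bone",
    8: "tissue",
}

#: Sinus segments subject to balancing / plausibility checks.
SINUS_CLASS_IDS = (0, 1, 2, 3, 4)
#: Left<->right mirror pairs under a horizontal flip (combined maxillary
#: class maps to itself).
MIRROR_PAIRS = {0: 1, 3: 4}

MAXILLARY_COMBINED = 2
MAXILLARY_LEFT = 2
MAXILLARY_RIGHT = 9


@dataclass
class LabelVolume:
    """3-D integer class map with physical geometry metadata.

    voxels are indexed (z, y, x); ``spacing`` and ``origin`` are mm,
    ordered (z, y, x) as well.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    class_names: dict = field(default_factory=lambda: dict(CLASS_NAMES_9))

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError("label volume must be 3-D")
        if not np.issubdtype(self.voxels.dtype, np.integer):
            raise ValueError("label volume must be integer-typed")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive")

    @property
    def n_classes(self) -> int:
        return max(self.class_names) + 1 if self.class_names else int(self.voxels.max()) + 1

    def copy(self) -> "LabelVolume":
        return LabelVolume(
            self.voxels.copy(), tuple(self.spacing), tuple(self.origin),
            dict(self.class_names),
        )


def save_nrrd(lv: LabelVolume, path: str | Path) -> None:
    """Write a label volume as 3D-Slicer-compatible NRRD."""
    import SimpleITK as sitk

    img = sitk.GetImageFromArray(lv.voxels.astype(np.int16))
    # SimpleITK orders spacing/origin (x, y, z)
    img.SetSpacing(tuple(float(s) for s in lv.spacing[::-1]))
    img.SetOrigin(tuple(float(o) for o in lv.origin[::-1]))
    sitk.WriteImage(img, str(path), useCompression=False)


def load_nrrd(path: str | Path, class_names: dict | None = None) -> LabelVolume:
    """Read a label volume from NRRD."""
    import SimpleITK as sitk

    img = sitk.ReadImage(str(path))
    vox = sitk.GetArrayFromImage(img)
    if not np.issubdtype(vox.dtype, np.integer):
        vox = np.rint(vox).astype(np.int16)
    return LabelVolume(
        vox,
        spacing=tuple(img.GetSpacing())[::-1],
        origin=tuple(img.GetOrigin())[::-1],
        class_names=class_names or dict(CLASS_NAMES_9),
    )


def save_intensity_nrrd(volume: np.ndarray, path: str | Path,
                        spacing=(1.0, 1.0, 1.0), origin=(0.0, 0.0, 0.0)) -> None:
    """Write a float intensity volume (e.g. a CT-like phantom) as NRRD."""
    import SimpleITK as sitk

    img = sitk.GetImageFromArray(np.asarray(volume, np.float32))
    img.SetSpacing(tuple(float(s) for s in spacing[::-1]))
    img.SetOrigin(tuple(float(o) for o in origin[::-1]))
    sitk.WriteImage(img, str(path), useCompression=False)


def load_intensity_nrrd(path: str | Path) -> tuple[np.ndarray, tuple, tuple]:
    """Read a float intensity volume; returns (voxels, spacing, origin)."""
    import SimpleITK as sitk

    img = sitk.ReadImage(str(path))
    return (
        sitk.GetArrayFromImage(img).astype(float),
        tuple(img.GetSpacing())[::-1],
        tuple(img.GetOrigin())[::-1],
    )
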