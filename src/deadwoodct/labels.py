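"""Voxel class taxonomy and labeled volumes.

Every stage of the pipeline — ground-truth phantoms, the classical tunnel
segmentation and the fungal-decay classifier — speaks the same per-voxel
vocabulary: a log cross-section is background air, bark, sound wood, an
insect-excavated cavity (in bark or in wood), a shrinkage crack, a sampling
drill hole, a larva, or wood showing signs of fungal decay.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import IntEnum
from pathlib import Path

import numpy as np


class Label(IntEnum):
    """Integer voxel classes, stable across serialization."""

    BACKGROUND = 0
    BARK = 1
    WOOD = 2
    TUNNEL_BARK = 3
    TUNNEL_WOOD = 4
    CRACK = 5
    DRILLING = 6
    LARVA = 7
    DECAY = 8


#: classes that occupy physical log material (used for volume denominators)
SOLID_LABELS = (Label.BARK, Label.WOOD, Label.DECAY)
#: classes counted as insect-excavated space
TUNNEL_LABELS = (Label.TUNNEL_BARK, Label.TUNNEL_WOOD)


def label_code_map() -> dict[str, int]:
    """Name → integer code map, suitable for a JSON sidecar."""
    return {lab.name.lower(): int(lab) for lab in Label}


@dataclass
class LabelVolume:
    """Per-voxel class grid paired with the voxel geometry of its CT volume.

    Parameters
    ----------
    classes
        3-D ``uint8`` array indexed (slice z, row y, col x); values are
        members of :class:`Label`. Axis 0 is the longitudinal stem axis.
    pixel_spacing
        In-plane (y, x) voxel size in millimetres.
    slice_thickness
        Longitudinal voxel size in millimetres.
    """

    classes: np.ndarray
    pixel_spacing: tuple[float, float]
    slice_thickness: float
    meta: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.classes = np.asarray(self.classes)
        if self.classes.ndim != 3:
            raise ValueError("classes must be a 3-D (z, y, x) array")
        if self.classes.dtype != np.uint8:
            if self.classes.max(initial=0) > 255 or self.classes.min(initial=0) < 0:
                raise ValueError("class codes must fit in uint8")
            self.classes = self.classes.astype(np.uint8)
        valid = {int(lab) for lab in Label}
        present = set(np.unique(self.classes).tolist())
        if not present <= valid:
            raise ValueError(f"unknown class codes: {sorted(present - valid)}")
        py, px = self.pixel_spacing
        if py <= 0 or px <= 0 or self.slice_thickness <= 0:
            raise ValueError("voxel spacing must be positive")
        self.pixel_spacing = (float(py), float(px))
        self.slice_thickness = float(self.slice_thickness)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.classes.shape

    @property
    def voxel_volume_mm3(self) -> float:
        py, px = self.pixel_spacing
        return py * px * self.slice_thickness

    def mask(self, *labels: Label) -> np.ndarray:
        """Boolean mask of voxels belonging to any of ``labels``."""
        out = np.zeros(self.classes.shape, dtype=bool)
        for lab in labels:
            out |= self.classes == int(lab)
        return out

    def counts(self) -> dict[Label, int]:
        """Voxel count per class (zero for absent classes)."""
        binned = np.bincount(self.classes.ravel(), minlength=len(Label))
        return {lab: int(binned[int(lab)]) for lab in Label}


def write_label_volume(labels: LabelVolume, path: str | Path) -> None:
    """Write class codes as NIfTI (``.nii``/``.nii.gz``) or multi-page TIFF.

    A ``<stem>.codes.json`` sidecar documents the integer code map; TIFF
    output additionally gets the spacing sidecar used for CT volumes.
    """
    from . import ctvolume

    path = Path(path)
    vol = ctvolume.CTVolume(
        voxels=labels.classes.astype(np.int16),
        pixel_spacing=labels.pixel_spacing,
        slice_thickness=labels.slice_thickness,
        meta=dict(labels.meta),
    )
    ctvolume.write_ct_volume(vol, path)
    codes = path.parent / (path.name.split(".")[0] + ".codes.json")
    codes.write_text(json.dumps(label_code_map(), indent=2))


def read_label_volume(path: str | Path, format: str | None = None) -> LabelVolume:
    from . import ctvolume

    vol = ctvolume.read_ct_volume(path, format=format)
    return LabelVolume(
        classes=np.rint(vol.voxels).astype(np.uint8),
        pixel_spacing=vol.pixel_spacing,
        slice_thickness=vol.slice_thickness,
        meta=dict(vol.meta),
    )
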