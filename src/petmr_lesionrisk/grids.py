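"""Core image containers: 3D scalar volumes and lesion voxel masks.

All voxel math in the package runs on :class:`VolumeGrid` — a plain 3D
array plus spacing/origin metadata — and :class:`LesionVOI`, a boolean
mask congruent with a grid.  NIfTI round-trips go through nibabel with a
diagonal RAS affine built from spacing and origin.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "Modality",
    "PathologyPattern",
    "VolumeGrid",
    "LesionVOI",
    "HIGH_RISK_PATTERNS",
]


class Modality(str, enum.Enum):
    """Imaging modality of a volume."""

    PSMA_PET = "PSMA_PET"
    ADC = "ADC"
    T2W = "T2W"


class PathologyPattern(str, enum.Enum):
    """Whole-mount histopathology pattern of a lesion."""

    BPH = "BPH"
    PIN_LOW = "PIN_LOW"
    PIN_HIGH = "PIN_HIGH"
    PROSTATITIS = "PROSTATITIS"
    GLEASON3 = "GLEASON3"
    GLEASON4 = "GLEASON4"
    GLEASON5 = "GLEASON5"


#: Patterns dichotomized as high lesion risk (Gleason pattern >= 4).
HIGH_RISK_PATTERNS = frozenset({PathologyPattern.GLEASON4, PathologyPattern.GLEASON5})


@dataclass
class VolumeGrid:
    """A 3D scalar image with voxel spacing, origin and modality.

    Parameters
    ----------
    values : ndarray
        3D float array of voxel values.
    spacing_mm : tuple of float
        Voxel spacing along each axis, millimetres; all components > 0.
    origin_mm : tuple of float
        Physical position of voxel (0, 0, 0), millimetres.
    modality : Modality
        Which image this is (PSMA-PET in normalized SUV, ADC, T2w).
    """

    values: np.ndarray
    spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    modality: Modality = Modality.PSMA_PET

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("VolumeGrid values must be a 3D array")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        self.origin_mm = tuple(float(o) for o in self.origin_mm)
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("all spacing components must be > 0")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("volume contains non-finite voxels")
        self.modality = Modality(self.modality)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume_ml(self) -> float:
        """Volume of one voxel in millilitres (1 ml = 1000 mm^3)."""
        return float(np.prod(self.spacing_mm)) / 1000.0

    def affine(self) -> np.ndarray:
        aff = np.diag(list(self.spacing_mm) + [1.0])
        aff[:3, 3] = self.origin_mm
        return aff

    def to_nifti(self, path: str | Path) -> None:
        img = nib.Nifti1Image(self.values.astype(np.float32), self.affine())
        nib.save(img, str(path))

    @classmethod
    def from_nifti(cls, path: str | Path, modality: Modality | str = Modality.PSMA_PET) -> "VolumeGrid":
        img = nib.load(str(path))
        aff = img.affine
        spacing = tuple(float(x) for x in np.abs(np.diag(aff)[:3]))
        origin = tuple(float(x) for x in aff[:3, 3])
        return cls(np.asarray(img.dataobj, dtype=float), spacing, origin, Modality(modality))


def save_mask(mask: np.ndarray, spacing_mm, origin_mm, path: str | Path) -> None:
    """Write a boolean or integer label mask as a NIfTI label map."""
    aff = np.diag(list(spacing_mm) + [1.0])
    aff[:3, 3] = origin_mm
    nib.save(nib.Nifti1Image(np.asarray(mask, dtype=np.int16), aff), str(path))


def load_mask(path: str | Path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).dataobj)


@dataclass
class LesionVOI:
    """A delineated lesion: voxel mask plus identity and pathology.

    ``volume_ml`` is the mask voxel count times the voxel volume of the
    grid the mask lives on.
    """

    lesion_id: str
    patient_id: str
    mask: np.ndarray
    pathology_pattern: PathologyPattern
    volume_ml: float = field(default=0.0)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 3:
            raise ValueError("lesion mask must be 3D")
        if not self.mask.any():
            raise ValueError(f"lesion {self.lesion_id}: empty mask")
        self.pathology_pattern = PathologyPattern(self.pathology_pattern)
        if self.volume_ml <= 0:
            raise ValueError(f"lesion {self.lesion_id}: volume_ml must be > 0")

    @classmethod
    def from_mask(cls, lesion_id, patient_id, mask, pattern, spacing_mm) -> "LesionVOI":
        mask = np.asarray(mask, dtype=bool)
        vol = float(mask.sum()) * float(np.prod(spacing_mm)) / 1000.0
        return cls(lesion_id, patient_id, mask, pattern, vol)

    @property
    def is_high_risk(self) -> bool:
        return self.pathology_pattern in HIGH_RISK_PATTERNS
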