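"""In-memory volume containers and NIfTI-1 I/O.

An :class:`ImageVolume` is a 3D scalar intensity grid with isotropic or
anisotropic voxel spacing (mm) and an affine; a :class:`LabelVolume` is an
integer-coded mask on the same grid. Both round-trip through NIfTI-1 via
nibabel.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import ClassVar

import nibabel as nib
import numpy as np

__all__ = ["ImageVolume", "LabelVolume", "load_image", "load_labels"]


def _default_affine(spacing_mm: tuple[float, float, float]) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing_mm
    return aff


@dataclass
class ImageVolume:
    """3D scalar intensity grid with voxel spacing in millimetres."""

    values: np.ndarray
    spacing_mm: tuple[float, float, float]
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValueError(f"expected a 3D volume, got ndim={self.values.ndim}")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing must be three positive lengths, got {self.spacing_mm}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("image contains non-finite values")
        if self.affine is None:
            self.affine = _default_affine(self.spacing_mm)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing_mm))

    def save(self, path) -> None:
        nib.save(nib.Nifti1Image(self.values.astype(np.float32), self.affine), str(path))


@dataclass
class LabelVolume:
    """Integer-coded region/ground-truth mask aligned to an ImageVolume grid."""

    values: np.ndarray
    spacing_mm: tuple[float, float, float]
    affine: np.ndarray | None = None
    # phantom label codes
    BACKGROUND: ClassVar[int] = 0
    WM: ClassVar[int] = 1
    BG: ClassVar[int] = 2
    DPVS: ClassVar[int] = 3
    VENTRICLE: ClassVar[int] = 4
    SUBARACHNOID: ClassVar[int] = 5

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if not np.issubdtype(self.values.dtype, np.integer):
            if not np.allclose(self.values, np.round(self.values)):
                raise ValueError("label volume must be integer coded")
            self.values = np.round(self.values).astype(np.int16)
        if self.values.ndim != 3:
            raise ValueError(f"expected a 3D label volume, got ndim={self.values.ndim}")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("spacing must be positive")
        if self.affine is None:
            self.affine = _default_affine(self.spacing_mm)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def mask(self, *codes: int) -> np.ndarray:
        """Boolean mask of voxels carrying any of the given codes."""
        return np.isin(self.values, codes)

    def save(self, path) -> None:
        nib.save(nib.Nifti1Image(self.values.astype(np.int16), self.affine), str(path))


def load_image(path) -> ImageVolume:
    img = nib.load(str(path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return ImageVolume(np.asarray(img.dataobj, dtype=np.float64), spacing, np.asarray(img.affine))


def load_labels(path) -> LabelVolume:
    img = nib.load(str(path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return LabelVolume(np.asarray(img.dataobj), spacing, np.asarray(img.affine))
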