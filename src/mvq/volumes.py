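"""Image containers and NIfTI I/O.

Arrays are indexed (x, y, z) with z the axial slice axis; spacing is the
voxel pitch in mm per axis. Volumes written to disk carry a diagonal RAS
affine built from the spacing, which is all the phantom pipeline needs —
no oblique acquisitions are modelled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "ImageVolume",
    "ComplexGREVolume",
    "FilteredPhaseVolume",
    "load_volume",
    "save_volume",
    "save_mask",
    "load_mask",
]


@dataclass
class ImageVolume:
    """A 3D scalar grid with voxel spacing in mm and a modality tag."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    modality: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D volume, got shape {self.data.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positive mm values, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def same_grid(self, other: "ImageVolume") -> bool:
        return self.shape == other.shape and np.allclose(self.spacing, other.spacing)


@dataclass
class ComplexGREVolume:
    """Complex-valued gradient-echo volume (magnitude * exp(i*phase))."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    echo_metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.complex128)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D volume, got shape {self.data.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def magnitude(self) -> np.ndarray:
        return np.abs(self.data)

    @property
    def phase(self) -> np.ndarray:
        return np.angle(self.data)


@dataclass
class FilteredPhaseVolume:
    """High-pass filtered (corrected) phase in radians, wrapped to (-pi, pi]."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    central_matrix: int
    source: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.spacing = tuple(float(s) for s in self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def as_image(self) -> ImageVolume:
        return ImageVolume(self.data, self.spacing, modality="filtered_phase")


def _affine(spacing) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    return aff


def save_volume(vol: ImageVolume, path: str | Path) -> None:
    img = nib.Nifti1Image(np.asarray(vol.data, dtype=np.float32), _affine(vol.spacing))
    img.header.set_zooms(vol.spacing)
    nib.save(img, str(path))


def load_volume(path: str | Path, modality: str = "") -> ImageVolume:
    img = nib.load(str(path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return ImageVolume(np.asarray(img.dataobj, dtype=np.float64), spacing, modality=modality)


def save_mask(mask: np.ndarray, spacing, path: str | Path) -> None:
    img = nib.Nifti1Image(np.asarray(mask, dtype=np.uint8), _affine(spacing))
    img.header.set_zooms(tuple(spacing))
    nib.save(img, str(path))


def load_mask(path: str | Path) -> tuple[np.ndarray, tuple[float, float, float]]:
    img = nib.load(str(path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return np.asarray(img.dataobj) > 0, spacing
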