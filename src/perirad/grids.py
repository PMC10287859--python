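"""Gridded 3-D data: scalar volumes and binary masks with physical metadata.

All physical quantities are in millimetres.  Voxel indices are 0-based and
the centre of voxel ``(i, j, k)`` sits at ``origin + (i, j, k) * spacing``.
"""

from __future__ import annotations

from dataclasses import dataclass

import nibabel as nib
import numpy as np

from .errors import EmptyMaskError, GridMismatchError

__all__ = ["Volume", "BinaryMask", "read_volume", "read_mask"]


def _check_grid(values: np.ndarray, spacing, origin) -> None:
    if values.ndim != 3:
        raise ValueError(f"expected a 3-D array, got ndim={values.ndim}")
    if len(spacing) != 3 or any(s <= 0 for s in spacing):
        raise ValueError(f"spacing must be 3 positive lengths, got {spacing}")
    if len(origin) != 3:
        raise ValueError(f"origin must have 3 components, got {origin}")


@dataclass
class Volume:
    """A 3-D scalar image with voxel spacing (mm) and origin."""

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        _check_grid(self.values, self.spacing, self.origin)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("volume contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def same_grid(self, other: "Volume | BinaryMask") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing)
            and np.allclose(self.origin, other.origin)
        )

    def require_same_grid(self, other: "Volume | BinaryMask") -> None:
        if not self.same_grid(other):
            raise GridMismatchError(
                f"grid mismatch: {self.shape}/{self.spacing}/{self.origin} vs "
                f"{other.shape}/{other.spacing}/{other.origin}"
            )

    def affine(self) -> np.ndarray:
        aff = np.diag(list(self.spacing) + [1.0])
        aff[:3, 3] = self.origin
        return aff

    def to_nifti(self, path: str) -> None:
        nib.save(nib.Nifti1Image(self.values.astype(np.float32), self.affine()), path)


@dataclass
class BinaryMask(Volume):
    """A {0,1} mask on the same grid conventions as :class:`Volume`."""

    def __post_init__(self) -> None:
        arr = np.asarray(self.values)
        if not np.isin(arr, (0, 1)).all():
            raise ValueError("mask values must be 0 or 1")
        self.values = arr.astype(np.uint8)
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        _check_grid(self.values, self.spacing, self.origin)

    @property
    def n_voxels(self) -> int:
        return int(self.values.sum())

    @property
    def is_empty(self) -> bool:
        return self.n_voxels == 0

    def require_nonempty(self, what: str = "mask") -> None:
        if self.is_empty:
            raise EmptyMaskError(f"{what} is empty")

    def bool(self) -> np.ndarray:
        return self.values.astype(bool)

    def to_nifti(self, path: str) -> None:
        nib.save(nib.Nifti1Image(self.values.astype(np.uint8), self.affine()), path)


def _load(path: str) -> tuple[np.ndarray, tuple, tuple]:
    img = nib.load(path)
    aff = img.affine
    spacing = tuple(float(s) for s in np.abs(np.diag(aff)[:3]))
    origin = tuple(float(o) for o in aff[:3, 3])
    return np.asanyarray(img.dataobj), spacing, origin


def read_volume(path: str) -> Volume:
    values, spacing, origin = _load(path)
    return Volume(values=np.asarray(values, dtype=np.float64), spacing=spacing, origin=origin)


def read_mask(path: str) -> BinaryMask:
    values, spacing, origin = _load(path)
    return BinaryMask(values=(np.asarray(values) > 0.5).astype(np.uint8), spacing=spacing, origin=origin)
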