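"""In-memory containers for 3D images and binary ROI masks.

Arrays are indexed ``(z, y, x)`` — axis 0 walks axial slices, so ``data[k]``
is one in-plane slice. ``spacing`` follows the same order and is given in
millimetres. NIfTI files on disk use the conventional ``(x, y, z)`` layout;
the readers/writers transpose.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

__all__ = ["ImageVolume", "RoiMask", "load_volume", "load_mask"]


@dataclass
class ImageVolume:
    """A 3D scalar intensity grid with voxel spacing and a modality tag.

    Parameters
    ----------
    data : ndarray, shape (nz, ny, nx)
        Voxel intensities, float.
    spacing : tuple of float
        Voxel spacing in mm, ordered (z, y, x) to match the array axes.
    modality : {"CT", "MR"}
        Intensity semantics. CT-like values are treated as calibrated
        (no standardization); MR-like values are z-scored during
        preprocessing.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    modality: str = "CT"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"image must be 3D, got shape {self.data.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive floats, got {self.spacing}")
        if self.modality not in ("CT", "MR"):
            raise ValueError(f"modality must be 'CT' or 'MR', got {self.modality!r}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def pixel_area_mm2(self) -> float:
        """In-plane (y, x) pixel area in mm^2."""
        return self.spacing[1] * self.spacing[2]

    def save(self, path: str) -> None:
        _save_nifti(self.data, self.spacing, path)


@dataclass
class RoiMask:
    """A binary 3D mask aligned to an :class:`ImageVolume`."""

    data: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.ndim != 3:
            raise ValueError(f"mask must be 3D, got shape {arr.shape}")
        vals = np.unique(arr)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError(f"mask voxels must be 0/1, found values {vals[:8]}")
        self.data = arr.astype(bool)
        self.spacing = tuple(float(s) for s in self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_count(self) -> int:
        return int(self.data.sum())

    @property
    def pixel_area_mm2(self) -> float:
        return self.spacing[1] * self.spacing[2]

    def is_empty(self) -> bool:
        return not self.data.any()

    def bounding_box(self) -> tuple[tuple[int, int], ...]:
        """Tight axis-aligned box of nonzero voxels.

        Returns ((z0, z1), (y0, y1), (x0, x1)) with inclusive ends;
        extent along an axis is ``hi - lo + 1``.
        """
        if self.is_empty():
            raise ValueError("bounding box of an empty mask is undefined")
        out = []
        for ax in range(3):
            nz = np.any(self.data, axis=tuple(a for a in range(3) if a != ax))
            idx = np.flatnonzero(nz)
            out.append((int(idx[0]), int(idx[-1])))
        return tuple(out)

    def check_aligned(self, image: ImageVolume) -> None:
        if self.data.shape != image.data.shape:
            raise ValueError(
                f"mask shape {self.data.shape} != image shape {image.data.shape}"
            )
        if not np.allclose(self.spacing, image.spacing):
            raise ValueError(
                f"mask spacing {self.spacing} != image spacing {image.spacing}"
            )

    def save(self, path: str) -> None:
        _save_nifti(self.data.astype(np.uint8), self.spacing, path)


def _save_nifti(data_zyx: np.ndarray, spacing_zyx, path: str) -> None:
    # disk layout is (x, y, z); affine encodes the mm spacing
    arr = np.ascontiguousarray(np.transpose(data_zyx, (2, 1, 0)))
    sz, sy, sx = spacing_zyx
    affine = np.diag([sx, sy, sz, 1.0])
    nib.save(nib.Nifti1Image(arr, affine), path)


def _load_nifti(path: str) -> tuple[np.ndarray, tuple[float, float, float]]:
    img = nib.load(path)
    arr = np.asarray(img.dataobj)
    if arr.ndim != 3:
        raise ValueError(f"{path}: expected a 3D volume, got shape {arr.shape}")
    sx, sy, sz = img.header.get_zooms()[:3]
    return np.transpose(arr, (2, 1, 0)), (float(sz), float(sy), float(sx))


def load_volume(path: str, modality: str = "CT") -> ImageVolume:
    data, spacing = _load_nifti(path)
    return ImageVolume(data=data, spacing=spacing, modality=modality)


def load_mask(path: str) -> RoiMask:
    data, spacing = _load_nifti(path)
    return RoiMask(data=data, spacing=spacing)
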