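"""3D scalar volumes with grid metadata.

Arrays are indexed ``data[z, y, x]``; ``spacing`` and ``origin`` follow the
same (z, y, x) axis order in millimetres.  Voxel centre of index ``(k, j, i)``
sits at ``origin + index * spacing``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

__all__ = ["ImageVolume"]


@dataclass
class ImageVolume:
    """A 3D scalar grid carrying CT intensity or PET standardized uptake values.

    Parameters
    ----------
    data : ndarray, shape (nz, ny, nx)
        Scalar values; finite everywhere.
    spacing : tuple of float
        Voxel spacing in mm, (dz, dy, dx); strictly positive.
    origin : tuple of float
        World coordinate (mm) of voxel (0, 0, 0).
    modality : str
        ``"CT"`` or ``"PET-SUV"``.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    modality: str = "CT"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError("volume data must be 3D (z, y, x)")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite values")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive")
        if self.modality == "PET-SUV" and self.data.min() < 0:
            raise ValueError("PET-SUV values must be non-negative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def voxel_to_world(self, idx: np.ndarray) -> np.ndarray:
        """Map (n, 3) voxel indices (z, y, x) to world mm coordinates."""
        idx = np.atleast_2d(idx)
        return idx * np.asarray(self.spacing) + np.asarray(self.origin)

    def world_to_voxel(self, xyz: np.ndarray) -> np.ndarray:
        """Map (n, 3) world mm coordinates (z, y, x) to fractional indices."""
        xyz = np.atleast_2d(xyz)
        return (xyz - np.asarray(self.origin)) / np.asarray(self.spacing)

    def slice_grid(self) -> tuple[np.ndarray, np.ndarray]:
        """In-plane world coordinate arrays (y_mm, x_mm) of voxel centres."""
        _, ny, nx = self.shape
        y = np.arange(ny) * self.spacing[1] + self.origin[1]
        x = np.arange(nx) * self.spacing[2] + self.origin[2]
        return y, x

    def copy_with(self, data: np.ndarray, modality: str | None = None) -> "ImageVolume":
        return ImageVolume(
            data=np.asarray(data, dtype=np.float64),
            spacing=self.spacing,
            origin=self.origin,
            modality=self.modality if modality is None else modality,
        )

    # --- NIfTI round trip -------------------------------------------------
    def to_nifti(self, path) -> str:
        """Write as NIfTI; axes stored x-fastest so external viewers agree."""
        # nibabel expects data[x, y, z]
        arr = np.ascontiguousarray(self.data.transpose(2, 1, 0))
        affine = np.diag([self.spacing[2], self.spacing[1], self.spacing[0], 1.0])
        affine[:3, 3] = [self.origin[2], self.origin[1], self.origin[0]]
        img = nib.Nifti1Image(arr, affine)
        img.header.set_xyzt_units("mm")
        nib.save(img, str(path))
        return str(path)

    @classmethod
    def from_nifti(cls, path, modality: str = "CT") -> "ImageVolume":
        img = nib.load(str(path))
        arr = np.asarray(img.dataobj, dtype=np.float64).transpose(2, 1, 0)
        aff = img.affine
        spacing = (float(aff[2, 2]), float(aff[1, 1]), float(aff[0, 0]))
        origin = (float(aff[2, 3]), float(aff[1, 3]), float(aff[0, 3]))
        return cls(arr, spacing=spacing, origin=origin, modality=modality)
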