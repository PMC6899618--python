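"""Voxelized images on a regular grid with physical spacing.

The container is deliberately thin: a numpy array of scalar values plus the
millimetre spacing per axis and an origin offset.  Activity images, MR
guidance images, point-spread-smoothed images and boolean region masks are
all carried in this form.  NIfTI round-tripping goes through nibabel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

__all__ = ["VoxelImage", "as_values"]


@dataclass
class VoxelImage:
    """A scalar field on a regular grid.

    Parameters
    ----------
    values
        Array of voxel values (any dimensionality; 2D or 3D in practice).
    spacing
        Physical voxel side length in mm, one entry per axis.
    origin
        Physical coordinate of the first voxel, in mm.
    """

    values: np.ndarray
    spacing: tuple[float, ...] = (1.0, 1.0)
    origin: tuple[float, ...] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if np.issubdtype(self.values.dtype, np.floating) and not np.all(
            np.isfinite(self.values)
        ):
            raise ValueError("image contains non-finite values")
        self.spacing = tuple(float(s) for s in np.atleast_1d(self.spacing))
        if len(self.spacing) == 1:
            self.spacing = self.spacing * self.values.ndim
        if len(self.spacing) != self.values.ndim:
            raise ValueError("spacing length does not match image dimensionality")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive")
        if self.origin is None:
            self.origin = (0.0,) * self.values.ndim
        else:
            self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.values.shape

    @property
    def ndim(self) -> int:
        return self.values.ndim

    def copy(self) -> "VoxelImage":
        return VoxelImage(self.values.copy(), self.spacing, self.origin)

    def with_values(self, values: np.ndarray) -> "VoxelImage":
        """Same grid, new values."""
        return VoxelImage(np.asarray(values), self.spacing, self.origin)

    # -- physical coordinates -------------------------------------------------

    def coords(self) -> list[np.ndarray]:
        """Per-axis physical coordinates (mm) of voxel centers, origin-relative."""
        return [
            self.origin[a] + self.spacing[a] * np.arange(self.shape[a])
            for a in range(self.ndim)
        ]

    def centered_grids(self) -> list[np.ndarray]:
        """Meshgrid of physical coordinates measured from the grid center (mm)."""
        axes = [
            (np.arange(n) - (n - 1) / 2.0) * s
            for n, s in zip(self.shape, self.spacing)
        ]
        return list(np.meshgrid(*axes, indexing="ij"))

    # -- I/O ------------------------------------------------------------------

    def to_nifti(self, path: str) -> None:
        affine = np.eye(4)
        for a, s in enumerate(self.spacing[:3]):
            affine[a, a] = s
            affine[a, 3] = self.origin[a] if a < len(self.origin) else 0.0
        data = self.values
        if data.dtype == bool:
            data = data.astype(np.uint8)
        if data.ndim == 2:  # NIfTI is inherently 3D
            data = data[..., None]
        nib.save(nib.Nifti1Image(np.asarray(data), affine), path)

    @classmethod
    def from_nifti(cls, path: str, squeeze: bool = True) -> "VoxelImage":
        img = nib.load(path)
        data = np.asarray(img.dataobj)
        zooms = img.header.get_zooms()[: data.ndim]
        if squeeze:
            keep = [a for a in range(data.ndim) if data.shape[a] > 1]
            if keep and len(keep) < data.ndim:
                zooms = tuple(zooms[a] for a in keep)
                data = np.squeeze(data)
        return cls(data, tuple(float(z) for z in zooms))


def as_values(image) -> np.ndarray:
    """Accept a VoxelImage or a bare array and return the value array."""
    if isinstance(image, VoxelImage):
        return image.values
    return np.asarray(image)
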