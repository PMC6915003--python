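"""Voxel images with physical geometry.

A :class:`VoxelImage` is the common carrier for every gridded quantity in
this package: activity concentrations (relative kBq/mL), linear attenuation
coefficients (mm^-1 at 511 keV), and reconstructed/SUV-scaled images.  Arrays
are 2-D ``(ny, nx)`` or 3-D ``(nz, ny, nx)``; the physical position of voxel
centre ``(i, j)`` is ``origin + (i, j) * spacing`` in mm.  The default origin
places the physical point (0, 0) at the centre of the grid, which is also the
rotation centre of the projection geometry.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

__all__ = ["VoxelImage", "centered_origin"]


def centered_origin(shape: tuple[int, ...], spacing: tuple[float, ...]) -> tuple[float, ...]:
    """Origin (mm) that puts the physical coordinate 0 at the grid centre."""
    return tuple(-(n - 1) / 2.0 * s for n, s in zip(shape, spacing))


@dataclass
class VoxelImage:
    """A scalar voxel grid with physical spacing and origin (mm)."""

    values: np.ndarray
    spacing: tuple[float, ...]
    origin: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim not in (2, 3):
            raise ValueError(f"expected a 2-D or 3-D array, got ndim={self.values.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != self.values.ndim:
            raise ValueError("spacing must have one entry per array axis")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("all spacing components must be positive")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("voxel values must be finite")
        if self.origin is None:
            self.origin = centered_origin(self.values.shape, self.spacing)
        else:
            self.origin = tuple(float(o) for o in self.origin)
            if len(self.origin) != self.values.ndim:
                raise ValueError("origin must have one entry per array axis")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.values.shape

    @property
    def ndim(self) -> int:
        return self.values.ndim

    @property
    def voxel_volume(self) -> float:
        """Voxel volume in mm^ndim (area for 2-D grids)."""
        return float(np.prod(self.spacing))

    def axis_coords(self, axis: int) -> np.ndarray:
        """Physical coordinates (mm) of voxel centres along one axis."""
        n = self.shape[axis]
        return self.origin[axis] + np.arange(n) * self.spacing[axis]

    def coord_grids(self) -> tuple[np.ndarray, ...]:
        """Meshgrid of physical voxel-centre coordinates, one array per axis."""
        axes = [self.axis_coords(a) for a in range(self.ndim)]
        return tuple(np.meshgrid(*axes, indexing="ij"))

    def copy_with(self, values: np.ndarray) -> "VoxelImage":
        return VoxelImage(np.asarray(values, dtype=float), self.spacing, self.origin)

    def same_grid(self, other: "VoxelImage") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing)
            and np.allclose(self.origin, other.origin)
        )

    # -- NIfTI round trip ---------------------------------------------------

    def to_nifti(self) -> nib.Nifti1Image:
        # NIfTI axes are (x, y, z); our arrays are (y, x) / (z, y, x).
        data = np.transpose(self.values)
        spacing = self.spacing[::-1]
        origin = self.origin[::-1]
        affine = np.eye(4)
        for i, s in enumerate(spacing):
            affine[i, i] = s
            affine[i, 3] = origin[i]
        return nib.Nifti1Image(np.asarray(data, dtype=np.float64), affine)

    def save(self, path: str) -> None:
        nib.save(self.to_nifti(), path)

    @classmethod
    def load(cls, path: str) -> "VoxelImage":
        img = nib.load(path)
        data = np.transpose(np.asanyarray(img.dataobj, dtype=float))
        affine = img.affine
        ndim = data.ndim
        spacing = tuple(float(affine[i, i]) for i in range(ndim))[::-1]
        origin = tuple(float(affine[i, 3]) for i in range(ndim))[::-1]
        return cls(data, spacing, origin)
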