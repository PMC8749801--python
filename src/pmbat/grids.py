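"""Voxel grids in millimetre world coordinates, with NIfTI round-trip.

Conventions used throughout the package:

* world units are millimetres, the frame origin sits at the isocenter
  (= phantom center),
* ``x`` is the modulation axis (slit stacking direction and gantry
  rotation axis), ``z`` is the beam direction at gantry angle 0 and
  ``y`` completes a right-handed frame,
* voxel coordinates refer to voxel centers, indices are 0-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

__all__ = ["VoxelGrid", "GridSpec"]


@dataclass
class VoxelGrid:
    """A scalar field sampled on a regular axis-aligned grid.

    Parameters
    ----------
    origin:
        World position (mm) of the center of voxel ``(0, 0, 0)``.
    spacing:
        Per-axis voxel size in mm, all strictly positive.
    values:
        3-D array of voxel values, shape defines ``dims``.
    """

    origin: np.ndarray
    spacing: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float)
        self.spacing = np.asarray(self.spacing, dtype=float)
        self.values = np.asarray(self.values)
        if self.origin.shape != (3,) or self.spacing.shape != (3,):
            raise ValueError("origin and spacing must be 3-vectors")
        if np.any(self.spacing <= 0):
            raise ValueError("spacing must be positive on all axes")
        if self.values.ndim != 3 or min(self.values.shape) < 1:
            raise ValueError("values must be a 3-D array with dims >= 1")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("grid values must be finite")

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(np.prod(self.spacing))

    def axis_coords(self, axis: int) -> np.ndarray:
        """World coordinates of voxel centers along one axis."""
        n = self.values.shape[axis]
        return self.origin[axis] + self.spacing[axis] * np.arange(n)

    def voxel_centers(self) -> np.ndarray:
        """All voxel-center world coordinates, shape ``(n_voxels, 3)``.

        Ordering matches ``values.ravel()`` (C order).
        """
        xs, ys, zs = (self.axis_coords(a) for a in range(3))
        gx, gy, gz = np.meshgrid(xs, ys, zs, indexing="ij")
        return np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1)

    @property
    def affine(self) -> np.ndarray:
        aff = np.eye(4)
        aff[:3, :3] = np.diag(self.spacing)
        aff[:3, 3] = self.origin
        return aff

    def to_nifti(self, path) -> None:
        img = nib.Nifti1Image(np.asarray(self.values, dtype=np.float32), self.affine)
        nib.save(img, str(path))

    @classmethod
    def from_nifti(cls, path) -> "VoxelGrid":
        img = nib.load(str(path))
        aff = img.affine
        spacing = np.diag(aff)[:3].copy()
        origin = aff[:3, 3].copy()
        return cls(origin=origin, spacing=spacing, values=np.asarray(img.dataobj))


@dataclass
class GridSpec:
    """Geometry of a scoring grid without values (origin/spacing/dims)."""

    origin: np.ndarray
    spacing: np.ndarray
    dims: tuple[int, int, int]

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float)
        self.spacing = np.asarray(self.spacing, dtype=float)
        self.dims = tuple(int(d) for d in self.dims)
        if np.any(self.spacing <= 0) or min(self.dims) < 1:
            raise ValueError("invalid grid spec")

    @classmethod
    def centered_cube(cls, half_extent: float, spacing) -> "GridSpec":
        """Grid symmetric about the origin covering ``[-half_extent, half_extent]``."""
        spacing = np.asarray(spacing, dtype=float)
        dims = np.maximum(1, np.round(2 * half_extent / spacing).astype(int))
        origin = -(dims - 1) / 2.0 * spacing
        return cls(origin=origin, spacing=spacing, dims=tuple(dims))

    def axis_coords(self, axis: int) -> np.ndarray:
        return self.origin[axis] + self.spacing[axis] * np.arange(self.dims[axis])

    def voxel_centers(self) -> np.ndarray:
        xs, ys, zs = (self.axis_coords(a) for a in range(3))
        gx, gy, gz = np.meshgrid(xs, ys, zs, indexing="ij")
        return np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1)

    def empty_grid(self) -> VoxelGrid:
        return VoxelGrid(
            origin=self.origin.copy(),
            spacing=self.spacing.copy(),
            values=np.zeros(self.dims, dtype=float),
        )
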