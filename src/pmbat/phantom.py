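"""Synthetic water-equivalent head phantom, target volume and structures.

The phantom is a homogeneous water sphere in air; it stands in for a
patient CT so that the geometric and dosimetric behaviour of minibeam
arc plans can be studied without patient data.  Relative stopping power
is stored on a voxel grid (water = 1.0, air = 0.0) so heterogeneous
phantoms can be plugged in later, but every helper in this module
produces the uniform sphere.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .grids import VoxelGrid

__all__ = [
    "Phantom",
    "SphereTarget",
    "StructureSet",
    "make_head_phantom",
    "make_ptv",
    "make_structures",
]

#: stopping-power threshold separating body from surrounding air
BODY_THRESHOLD = 0.05

#: finest modulation-axis spacing accepted for a scoring-capable phantom grid;
#: the 400 um slit pattern is not representable on coarser grids
MAX_MODULATION_SPACING = 0.5


@dataclass
class SphereTarget:
    """Spherical planning target volume (PTV)."""

    center: np.ndarray
    diameter: float

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)
        if self.diameter <= 0:
            raise ValueError("target diameter must be positive")

    @property
    def radius(self) -> float:
        return self.diameter / 2.0

    def contains(self, points: np.ndarray) -> np.ndarray:
        points = np.atleast_2d(points)
        return np.sum((points - self.center) ** 2, axis=1) <= self.radius**2


@dataclass
class Phantom:
    """Water-equivalent head phantom: stopping-power grid plus analytic sphere.

    ``grid`` holds relative stopping power; ``radius``/``center`` describe
    the analytic sphere from which the grid was rasterized.  The dose
    engine uses the analytic surface (exact skin entry), the grid is the
    exportable CT surrogate.
    """

    grid: VoxelGrid
    radius: float
    center: np.ndarray

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)
        vals = self.grid.values
        if vals.min() < 0 or vals.max() > 3:
            raise ValueError("relative stopping power must lie in [0, 3]")

    @property
    def body_mask(self) -> np.ndarray:
        return self.grid.values > BODY_THRESHOLD

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Analytic membership test against the body sphere."""
        points = np.atleast_2d(points)
        return np.sum((points - self.center) ** 2, axis=1) <= self.radius**2

    def skin_entry(self, direction: np.ndarray) -> float:
        """Distance from the grid boundary to the body surface along a ray.

        The ray passes through the phantom center with unit ``direction``;
        the returned distance is measured from the point where the ray
        enters the grid bounding box.
        """
        direction = np.asarray(direction, dtype=float)
        n = direction / np.linalg.norm(direction)
        half = (np.asarray(self.grid.dims) - 1) / 2.0 * self.grid.spacing
        # distance from center to the box wall along -n
        with np.errstate(divide="ignore"):
            t_wall = np.min(np.where(n != 0, half / np.abs(n), np.inf))
        return float(t_wall - self.radius)


def make_head_phantom(
    radius: float = 80.0,
    spacing=(0.1, 1.0, 1.0),
    margin: float = 5.0,
) -> Phantom:
    """Build the default head phantom: a water sphere centered at the origin.

    Parameters
    ----------
    radius:
        Sphere radius in mm (>= 40, a head-like size).
    spacing:
        Per-axis voxel size in mm.  The modulation axis (x) must be
        resolved at ``<= 0.5`` mm, otherwise the 400 um slit scale of the
        collimated beams cannot live on this grid and the call refuses.
    margin:
        Air margin around the sphere, mm.
    """
    spacing = np.asarray(spacing, dtype=float)
    if radius < 40:
        raise ValueError("head phantom radius must be at least 40 mm")
    if spacing[0] > MAX_MODULATION_SPACING:
        raise ValueError(
            f"modulation-axis spacing {spacing[0]:g} mm is too coarse: the "
            f"minibeam pattern requires <= {MAX_MODULATION_SPACING} mm along x "
            "(profiles are sampled analytically, but scored grids must still "
            "resolve the slit period)"
        )
    half = radius + margin
    dims = np.maximum(1, np.round(2 * half / spacing).astype(int))
    origin = -(dims - 1) / 2.0 * spacing
    xs = origin[0] + spacing[0] * np.arange(dims[0])
    ys = origin[1] + spacing[1] * np.arange(dims[1])
    zs = origin[2] + spacing[2] * np.arange(dims[2])
    r2 = (
        xs[:, None, None] ** 2
        + ys[None, :, None] ** 2
        + zs[None, None, :] ** 2
    )
    values = np.where(r2 <= radius**2, 1.0, 0.0).astype(np.float32)
    grid = VoxelGrid(origin=origin, spacing=spacing, values=values)
    return Phantom(grid=grid, radius=float(radius), center=np.zeros(3))


def make_ptv(phantom: Phantom, diameter: float = 20.0) -> SphereTarget:
    """Place a spherical PTV at the phantom center.

    Raises if the target would escape the body.
    """
    if diameter <= 0:
        raise ValueError("PTV diameter must be positive")
    if diameter / 2.0 >= phantom.radius:
        raise ValueError(
            f"PTV of diameter {diameter:g} mm does not fit inside the "
            f"{2 * phantom.radius:g} mm phantom"
        )
    return SphereTarget(center=phantom.center.copy(), diameter=float(diameter))


@dataclass
class StructureSet:
    """PTV / normal-tissue partition of the body.

    Normal tissue is the whole body excluding the PTV, the convention
    used for all DVH and integral-dose reporting.
    """

    grid: VoxelGrid
    ptv_mask: np.ndarray
    normal_tissue_mask: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.ptv_mask & self.normal_tissue_mask):
            raise ValueError("structure masks must be disjoint")

    def to_label_volume(self, path, sidecar_path=None) -> None:
        """Write one integer label volume (0 air, 1 normal tissue, 2 PTV)."""
        labels = np.zeros(self.grid.dims, dtype=np.float32)
        labels[self.normal_tissue_mask] = 1
        labels[self.ptv_mask] = 2
        VoxelGrid(self.grid.origin, self.grid.spacing, labels).to_nifti(path)
        if sidecar_path is not None:
            with open(sidecar_path, "w") as fh:
                json.dump({"0": "air", "1": "normal_tissue", "2": "ptv"}, fh, indent=1)


def make_structures(phantom: Phantom, ptv: SphereTarget) -> StructureSet:
    """Partition the body into PTV and normal tissue on the phantom grid."""
    body = phantom.body_mask
    pts = phantom.grid.voxel_centers()
    inside = ptv.contains(pts).reshape(phantom.grid.dims)
    ptv_mask = body & inside
    normal = body & ~ptv_mask
    return StructureSet(grid=phantom.grid, ptv_mask=ptv_mask, normal_tissue_mask=normal)
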