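"""Sampling grids and NIfTI I/O.

A :class:`Grid` ties a voxel array to world (scanner) space: axis-aligned,
voxel centre of index ``i`` at ``fov_origin + i * voxel_size`` (mm), voxel
``i`` occupying the half-open interval ``[(i - 1/2), (i + 1/2)) * voxel_size``
around its centre.  Slices are indexed along the last axis.
"""

from __future__ import annotations

from dataclasses import dataclass

import nibabel as nib
import numpy as np

__all__ = ["Grid", "save_nifti", "load_nifti"]


@dataclass(frozen=True)
class Grid:
    """Axis-aligned sampling grid in world millimetres."""

    shape: tuple[int, int, int]
    voxel_size: tuple[float, float, float]
    fov_origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or len(self.voxel_size) != 3:
            raise ValueError("Grid is three-dimensional")
        if any(s <= 0 for s in self.shape):
            raise ValueError("grid shape must be positive")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel_size must be positive")
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        object.__setattr__(self, "voxel_size", tuple(float(v) for v in self.voxel_size))
        object.__setattr__(self, "fov_origin", tuple(float(v) for v in self.fov_origin))

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_size))

    @property
    def pixel_area_mm2(self) -> float:
        """In-plane pixel area (slices are along the last axis)."""
        return float(self.voxel_size[0] * self.voxel_size[1])

    def axis_centers(self, axis: int) -> np.ndarray:
        """World coordinates of voxel centres along one axis."""
        return self.fov_origin[axis] + np.arange(self.shape[axis]) * self.voxel_size[axis]

    def coordinate_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Broadcastable world-coordinate arrays (mm) for every voxel."""
        return tuple(np.meshgrid(*(self.axis_centers(a) for a in range(3)), indexing="ij"))

    def axis_extent(self, axis: int) -> tuple[float, float]:
        """World-space interval [lo, hi] covered by the grid along an axis."""
        lo = self.fov_origin[axis] - 0.5 * self.voxel_size[axis]
        hi = lo + self.shape[axis] * self.voxel_size[axis]
        return lo, hi

    def affine(self) -> np.ndarray:
        aff = np.diag(list(self.voxel_size) + [1.0])
        aff[:3, 3] = self.fov_origin
        return aff

    def same_geometry(self, other: "Grid", atol: float = 1e-9) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.voxel_size, other.voxel_size, atol=atol)
            and np.allclose(self.fov_origin, other.fov_origin, atol=atol)
        )


def save_nifti(volume: np.ndarray, grid: Grid, path) -> None:
    """Write a volume (3D, or 4D with trailing frame axis) on ``grid``."""
    arr = np.asarray(volume)
    if arr.shape[:3] != grid.shape:
        raise ValueError(f"volume shape {arr.shape} does not match grid {grid.shape}")
    img = nib.Nifti1Image(arr, grid.affine())
    img.header.set_zooms(grid.voxel_size + ((1.0,) if arr.ndim == 4 else ()))
    nib.save(img, str(path))


def load_nifti(path) -> tuple[np.ndarray, Grid]:
    """Read a NIfTI file, returning the array and its :class:`Grid`."""
    img = nib.load(str(path))
    arr = np.asarray(img.dataobj)
    aff = img.affine
    voxel_size = tuple(float(v) for v in np.abs(np.diag(aff)[:3]))
    origin = tuple(float(v) for v in aff[:3, 3])
    grid = Grid(shape=arr.shape[:3], voxel_size=voxel_size, fov_origin=origin)
    return arr, grid
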