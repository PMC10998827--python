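"""Voxel grids for phantom rasterization and volume surrogates.

World coordinates are millimetres.  Arrays are indexed ``[iz, iy, ix]`` and the
corresponding world coordinate of a voxel *center* is
``origin_mm + index * voxel_size_mm`` per axis.  Voxel ownership is by
center-point inclusion and extents are half-open.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["VoxelGrid", "default_grid"]


@dataclass(frozen=True)
class VoxelGrid:
    """A regular 3D grid: ``shape`` (nz, ny, nx), voxel size and origin in mm.

    ``origin_mm`` is the world coordinate (z, y, x) of the center of voxel
    ``(0, 0, 0)``.
    """

    shape: tuple[int, int, int]
    voxel_size_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float]

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(int(n) < 1 for n in self.shape):
            raise ValueError(f"shape must be three integers >= 1, got {self.shape}")
        if len(self.voxel_size_mm) != 3 or any(s <= 0 for s in self.voxel_size_mm):
            raise ValueError(f"voxel sizes must be positive, got {self.voxel_size_mm}")
        object.__setattr__(self, "shape", tuple(int(n) for n in self.shape))
        object.__setattr__(self, "voxel_size_mm", tuple(float(s) for s in self.voxel_size_mm))
        object.__setattr__(self, "origin_mm", tuple(float(o) for o in self.origin_mm))

    @classmethod
    def centered(cls, shape: tuple[int, int, int],
                 voxel_size_mm: float | tuple[float, float, float]) -> "VoxelGrid":
        """Grid whose world extent is symmetric about the origin."""
        if np.isscalar(voxel_size_mm):
            voxel_size_mm = (float(voxel_size_mm),) * 3  # type: ignore[assignment]
        origin = tuple(-(n - 1) / 2.0 * s for n, s in zip(shape, voxel_size_mm))
        return cls(tuple(shape), tuple(voxel_size_mm), origin)  # type: ignore[arg-type]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_size_mm))

    @property
    def voxel_volume_ml(self) -> float:
        return self.voxel_volume_mm3 / 1000.0

    def axis_coords(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Voxel-center coordinates along each axis: (z, y, x) 1D arrays."""
        return tuple(  # type: ignore[return-value]
            self.origin_mm[a] + np.arange(self.shape[a]) * self.voxel_size_mm[a]
            for a in range(3)
        )

    def meshgrid(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Broadcastable (sparse) voxel-center coordinate arrays."""
        z, y, x = self.axis_coords()
        return z[:, None, None], y[None, :, None], x[None, None, :]

    def extent_mm(self) -> tuple[tuple[float, float], ...]:
        """Half-open world extent ((zmin, zmax), (ymin, ymax), (xmin, xmax)).

        Extents run from the outer edge of the first voxel to the outer edge of
        the last voxel, i.e. world extent = shape * voxel_size.
        """
        return tuple(
            (self.origin_mm[a] - self.voxel_size_mm[a] / 2.0,
             self.origin_mm[a] + (self.shape[a] - 0.5) * self.voxel_size_mm[a])
            for a in range(3)
        )

    def world_to_index(self, point_mm: tuple[float, float, float]) -> tuple[int, int, int]:
        """Index of the voxel owning a world point (nearest center)."""
        idx = tuple(
            int(round((point_mm[a] - self.origin_mm[a]) / self.voxel_size_mm[a]))
            for a in range(3)
        )
        for a in range(3):
            if not 0 <= idx[a] < self.shape[a]:
                raise ValueError(f"point {point_mm} outside grid (axis {a}, index {idx[a]})")
        return idx  # type: ignore[return-value]

    def distance_to(self, point_mm: tuple[float, float, float]) -> np.ndarray:
        """Euclidean distance (mm) from every voxel center to a world point."""
        z, y, x = self.meshgrid()
        return np.sqrt((z - point_mm[0]) ** 2 + (y - point_mm[1]) ** 2 + (x - point_mm[2]) ** 2)


def default_grid(voxel_size_mm: float = 2.4) -> VoxelGrid:
    """Default reconstruction-style grid (2.4 mm isotropic voxels).

    Sized to contain the torso phantom including the obese shell with margin:
    roughly 302 x 192 x 365 mm along (z, y, x).
    """
    nz = int(np.ceil(302.4 / voxel_size_mm))
    ny = int(np.ceil(192.0 / voxel_size_mm))
    nx = int(np.ceil(364.8 / voxel_size_mm))
    return VoxelGrid.centered((nz, ny, nx), voxel_size_mm)
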