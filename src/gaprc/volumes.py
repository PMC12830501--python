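"""In-memory containers for co-registered CT and activity volumes.

Volumes live on a regular voxel grid described by a voxel size (dx, dy, dz)
in mm and a world-space origin (mm coordinate of the centre of voxel
(0, 0, 0)). World coordinates are voxel-centre based throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Grid", "CTVolume", "ActivityVolume", "voxel_centers"]


@dataclass(frozen=True)
class Grid:
    """Regular voxel grid: shape, voxel size (mm) and origin (mm)."""

    shape: tuple[int, int, int]
    voxel_size: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        if any(s < 1 for s in self.shape):
            raise ValueError(f"grid shape must be positive, got {self.shape}")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError(f"voxel size must be positive, got {self.voxel_size}")

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_size))

    def axis_coords(self, axis: int) -> np.ndarray:
        """World coordinates (mm) of voxel centres along one axis."""
        n = self.shape[axis]
        return self.origin[axis] + np.arange(n) * self.voxel_size[axis]

    def congruent(self, other: "Grid", atol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.voxel_size, other.voxel_size, atol=atol)
            and np.allclose(self.origin, other.origin, atol=atol)
        )


def _centered_grid(shape, voxel_size) -> Grid:
    origin = tuple(-(n - 1) / 2.0 * v for n, v in zip(shape, voxel_size))
    return Grid(tuple(shape), tuple(voxel_size), origin)


def voxel_centers(grid: Grid) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Meshgrid (ij indexing) of voxel-centre world coordinates in mm."""
    ax = [grid.axis_coords(a) for a in range(3)]
    return np.meshgrid(*ax, indexing="ij")


@dataclass
class _BaseVolume:
    data: np.ndarray
    voxel_size: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"volume must be 3D, got ndim={self.data.ndim}")
        if not np.isfinite(self.data).all():
            raise ValueError("volume contains non-finite values")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        self.origin = tuple(float(v) for v in self.origin)
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel size must be positive")

    @property
    def grid(self) -> Grid:
        return Grid(self.data.shape, self.voxel_size, self.origin)

    @property
    def voxel_volume_mm3(self) -> float:
        return self.grid.voxel_volume_mm3


@dataclass
class CTVolume(_BaseVolume):
    """CT volume in Hounsfield units."""

    @property
    def hu(self) -> np.ndarray:
        return self.data


@dataclass
class ActivityVolume(_BaseVolume):
    """Activity-concentration volume in Bq/mL (non-negative)."""

    def __post_init__(self):
        super().__post_init__()
        if (self.data < 0).any():
            raise ValueError("activity must be non-negative")

    @property
    def activity(self) -> np.ndarray:
        return self.data

    def with_data(self, data: np.ndarray) -> "ActivityVolume":
        return ActivityVolume(data, self.voxel_size, self.origin, dict(self.meta))


def centered_grid(shape, voxel_size) -> Grid:
    """Grid whose world origin sits at the volume centre (symmetric FOV)."""
    return _centered_grid(shape, voxel_size)
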