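"""Raster volumes in the DICOM patient coordinate system.

All volumes in this package share one geometric convention, stated here and
used everywhere: coordinates are millimetres in the DICOM patient frame
(LPS), arrays are indexed ``(i, j, k)`` along ``(x, y, z)``, voxel indices
are 0-based, and the world position of a voxel is the *center* of that
voxel: ``world = origin + index * spacing``. Only axis-aligned volumes
(identity direction cosines) are supported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["CTVolume", "DoseGrid"]


IDENTITY_ORIENTATION = np.eye(3)


@dataclass
class _Raster3D:
    """Common geometry of an axis-aligned 3D raster."""

    values: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray
    orientation: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.spacing = np.asarray(self.spacing, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float)
        self.orientation = np.asarray(self.orientation, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("volume must be 3D")
        if self.spacing.shape != (3,) or np.any(self.spacing <= 0):
            raise ValueError("spacing must be three strictly positive values")
        if not np.all(np.isfinite(self.origin)):
            raise ValueError("origin must be finite")
        if not np.allclose(self.orientation, IDENTITY_ORIENTATION, atol=1e-6):
            raise ValueError("only axis-aligned (identity orientation) volumes are supported")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    def voxel_centers(self, indices: np.ndarray) -> np.ndarray:
        """World coordinates (mm) of the centers of the given ``(N, 3)`` voxel indices."""
        idx = np.atleast_2d(np.asarray(indices, dtype=float))
        return self.origin + idx * self.spacing

    def world_to_index(self, points: np.ndarray) -> np.ndarray:
        """Continuous (fractional) voxel indices of ``(N, 3)`` world points."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return (pts - self.origin) / self.spacing

    def nearest_voxel(self, points: np.ndarray) -> np.ndarray:
        """Integer index of the voxel whose center is nearest each world point."""
        return np.round(self.world_to_index(points)).astype(np.int64)

    def contains_index(self, indices: np.ndarray) -> np.ndarray:
        idx = np.atleast_2d(indices)
        shape = np.array(self.shape)
        return np.all((idx >= 0) & (idx < shape), axis=1)

    def all_voxel_indices(self) -> np.ndarray:
        """All ``(N, 3)`` integer voxel indices, x fastest."""
        grid = np.indices(self.shape).reshape(3, -1).T
        return grid


@dataclass
class CTVolume(_Raster3D):
    """A CT image volume; ``values`` are Hounsfield units."""

    @property
    def hu(self) -> np.ndarray:
        return self.values


@dataclass
class DoseGrid(_Raster3D):
    """An RT-dose grid; ``values`` are absorbed dose in Gy (scaling already applied)."""

    def __post_init__(self) -> None:
        super().__post_init__()
        if np.any(self.values < 0):
            raise ValueError("dose must be non-negative everywhere")

    @property
    def dose(self) -> np.ndarray:
        return self.values
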