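"""Voxel-grid containers shared by every stage of the pipeline.

All volumes live on a regular axis-aligned grid. Arrays are indexed
``[ix, iy, iz]`` (x fastest-varying in memory order of the first axis),
and voxel *centers* map to world coordinates (mm) through

    world = origin + index * spacing

which is the plain diagonal-affine NIfTI convention used by the I/O layer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Tuple

import numpy as np

__all__ = [
    "ImageGrid",
    "DoseGrid",
    "StructureMask",
    "DisplacementField",
]


def _as_triplet(x) -> Tuple[float, float, float]:
    arr = np.asarray(x, dtype=float).reshape(-1)
    if arr.size != 3:
        raise ValueError(f"expected a 3-vector, got shape {arr.shape}")
    return (float(arr[0]), float(arr[1]), float(arr[2]))


@dataclass
class _Gridded:
    """Mixin holding the shared geometry metadata."""

    spacing: Tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: Tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.spacing = _as_triplet(self.spacing)
        self.origin = _as_triplet(self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")

    @property
    def shape(self) -> Tuple[int, int, int]:
        return tuple(self._data().shape[:3])

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def _data(self) -> np.ndarray:  # overridden by subclasses
        raise NotImplementedError

    def world_axes(self) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-axis voxel-center coordinates in mm."""
        return tuple(
            self.origin[a] + self.spacing[a] * np.arange(self.shape[a])
            for a in range(3)
        )

    def world_grid(self) -> np.ndarray:
        """Dense (nx, ny, nz, 3) array of voxel-center world coordinates."""
        ax = self.world_axes()
        xs, ys, zs = np.meshgrid(*ax, indexing="ij")
        return np.stack([xs, ys, zs], axis=-1)

    def same_geometry(self, other: "_Gridded", atol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=atol)
            and np.allclose(self.origin, other.origin, atol=atol)
        )

    def require_same_geometry(self, other: "_Gridded", what: str = "grids") -> None:
        if not self.same_geometry(other):
            raise ValueError(
                f"{what} must share shape/spacing/origin: "
                f"{self.shape}/{self.spacing}/{self.origin} vs "
                f"{other.shape}/{other.spacing}/{other.origin}"
            )


@dataclass
class ImageGrid(_Gridded):
    """Scalar intensity volume (HU-like arbitrary units)."""

    values: np.ndarray = field(default_factory=lambda: np.zeros((1, 1, 1)))
    spacing: Tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: Tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError(f"values must be 3-D, got ndim={self.values.ndim}")
        super().__post_init__()

    def _data(self) -> np.ndarray:
        return self.values


@dataclass
class DoseGrid(_Gridded):
    """Absorbed-dose volume in Gy; non-negative and finite everywhere."""

    dose: np.ndarray = field(default_factory=lambda: np.zeros((1, 1, 1)))
    spacing: Tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: Tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.dose = np.asarray(self.dose, dtype=float)
        if self.dose.ndim != 3:
            raise ValueError(f"dose must be 3-D, got ndim={self.dose.ndim}")
        if not np.all(np.isfinite(self.dose)):
            raise ValueError("dose contains non-finite values")
        if np.any(self.dose < 0):
            raise ValueError("dose must be non-negative")
        super().__post_init__()

    def _data(self) -> np.ndarray:
        return self.dose


@dataclass
class StructureMask(_Gridded):
    """Boolean voxel mask for an anatomical structure (lung, fLung, ...)."""

    inside: np.ndarray = field(default_factory=lambda: np.zeros((1, 1, 1), bool))
    spacing: Tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: Tuple[float, float, float] = (0.0, 0.0, 0.0)
    name: str = "structure"

    def __post_init__(self) -> None:
        self.inside = np.asarray(self.inside).astype(bool)
        if self.inside.ndim != 3:
            raise ValueError(f"inside must be 3-D, got ndim={self.inside.ndim}")
        super().__post_init__()

    def _data(self) -> np.ndarray:
        return self.inside

    @property
    def voxel_count(self) -> int:
        return int(self.inside.sum())

    @property
    def volume_cc(self) -> float:
        return self.voxel_count * self.voxel_volume_mm3 / 1000.0


@dataclass
class DisplacementField(_Gridded):
    """Per-voxel displacement u(x) in world-axis mm, defined on the fixed grid.

    ``vectors`` has shape (nx, ny, nz, 3); ``x + u(x)`` is the location in the
    moving image corresponding to fixed-grid point ``x``.
    """

    vectors: np.ndarray = field(default_factory=lambda: np.zeros((1, 1, 1, 3)))
    spacing: Tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: Tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=float)
        if self.vectors.ndim != 4 or self.vectors.shape[-1] != 3:
            raise ValueError(
                f"vectors must have shape (nx, ny, nz, 3), got {self.vectors.shape}"
            )
        super().__post_init__()

    def _data(self) -> np.ndarray:
        return self.vectors

    def magnitude(self) -> np.ndarray:
        return np.sqrt((self.vectors**2).sum(axis=-1))
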