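"""Voxel-grid containers shared by every pipeline stage.

World coordinates follow the convention ``world = origin + index * spacing``
per axis (0-based indices), with an optional 3x3 direction matrix for
non-axis-aligned volumes read from disk.  Phantom-generated volumes always
use the identity direction; anatomical rotation lives in the phantom spec.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

BACKGROUND, MYOCARDIUM, BLOOD_POOL = 0, 1, 2
VALID_LABELS = (BACKGROUND, MYOCARDIUM, BLOOD_POOL)


@dataclass(frozen=True)
class Grid:
    """Regular 3D sampling lattice (shape, mm spacing, mm origin, direction)."""

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    direction: tuple[float, ...] = (1, 0, 0, 0, 1, 0, 0, 0, 1)

    def __post_init__(self):
        if len(self.shape) != 3 or any(int(s) <= 0 for s in self.shape):
            raise ValueError(f"grid shape must be three positive ints, got {self.shape}")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"grid spacing must be positive, got {self.spacing}")

    @property
    def direction_matrix(self) -> np.ndarray:
        return np.asarray(self.direction, dtype=float).reshape(3, 3)

    @property
    def extent_mm(self) -> tuple[float, float, float]:
        return tuple(n * s for n, s in zip(self.shape, self.spacing))

    def world_coordinates(self) -> np.ndarray:
        """World coordinate of every voxel centre, shape ``(*shape, 3)``."""
        axes = [self.origin[i] + self.spacing[i] * np.arange(self.shape[i]) for i in range(3)]
        ii, jj, kk = np.meshgrid(*axes, indexing="ij")
        pts = np.stack([ii, jj, kk], axis=-1)
        D = self.direction_matrix
        if not np.allclose(D, np.eye(3)):
            o = np.asarray(self.origin)
            pts = (pts - o) @ D.T + o
        return pts

    def index_of(self, world: np.ndarray) -> np.ndarray:
        """Fractional voxel index of world points, shape (..., 3)."""
        world = np.asarray(world, dtype=float)
        D = self.direction_matrix
        o = np.asarray(self.origin)
        local = world - o
        if not np.allclose(D, np.eye(3)):
            local = local @ np.linalg.inv(D).T
        return local / np.asarray(self.spacing)

    @classmethod
    def centered(cls, shape, spacing) -> "Grid":
        """Grid whose voxel lattice is centred on the world origin."""
        shape = tuple(int(s) for s in np.broadcast_to(shape, 3))
        spacing = tuple(float(s) for s in np.broadcast_to(spacing, 3))
        origin = tuple(-(n - 1) / 2.0 * s for n, s in zip(shape, spacing))
        return cls(shape=shape, spacing=spacing, origin=origin)


@dataclass
class ImageVolume:
    """HU voxel array on a :class:`Grid`."""

    array: np.ndarray
    grid: Grid
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.array = np.asarray(self.array)
        if self.array.shape != tuple(self.grid.shape):
            raise ValueError(
                f"array shape {self.array.shape} does not match grid shape {self.grid.shape}"
            )
        if not np.all(np.isfinite(self.array)):
            raise ValueError("image volume contains non-finite values")

    def with_array(self, array: np.ndarray) -> "ImageVolume":
        return ImageVolume(array=array, grid=self.grid, meta=dict(self.meta))


@dataclass
class LabelVolume:
    """Integer class map: 0 background, 1 myocardium, 2 LV blood pool."""

    array: np.ndarray
    grid: Grid
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.array = np.asarray(self.array)
        if self.array.shape != tuple(self.grid.shape):
            raise ValueError(
                f"array shape {self.array.shape} does not match grid shape {self.grid.shape}"
            )
        bad = np.setdiff1d(np.unique(self.array), VALID_LABELS)
        if bad.size:
            raise ValueError(f"labels outside {VALID_LABELS}: {bad.tolist()}")

    def mask(self, class_id: int) -> np.ndarray:
        return self.array == class_id

    def class_volume_ml(self, class_id: int) -> float:
        """Volume of one class in millilitres (voxel count x voxel volume)."""
        voxel_mm3 = float(np.prod(self.grid.spacing))
        return float(np.count_nonzero(self.array == class_id)) * voxel_mm3 / 1000.0


def same_grid(a, b, atol: float = 1e-6) -> bool:
    ga, gb = a.grid, b.grid
    return (
        tuple(ga.shape) == tuple(gb.shape)
        and np.allclose(ga.spacing, gb.spacing, atol=atol)
        and np.allclose(ga.origin, gb.origin, atol=atol)
        and np.allclose(ga.direction, gb.direction, atol=atol)
    )


def require_same_grid(a, b, what: str = "volumes") -> None:
    if not same_grid(a, b):
        raise ValueError(f"{what} must share a common grid (shape/spacing/origin/direction)")
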