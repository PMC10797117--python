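"""Voxel-grid geometry shared by all image containers.

Axis convention: arrays are indexed (row, col) in 2D and (slice, row, col)
in 3D. On the coronal slices this pipeline works with, the row axis is
head-foot ("vertical") and the column axis is left-right ("horizontal").
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class ImageGrid:
    """Regular voxel grid: shape in voxels, spacing and origin in mm."""

    shape: tuple[int, ...]
    spacing: tuple[float, ...]
    origin: tuple[float, ...] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        shape = tuple(int(s) for s in self.shape)
        spacing = tuple(float(s) for s in self.spacing)
        if len(shape) not in (2, 3):
            raise ValueError(f"grid must be 2D or 3D, got shape {shape}")
        if len(spacing) != len(shape):
            raise ValueError("spacing must have one entry per axis")
        if any(s < 1 for s in shape):
            raise ValueError(f"every axis needs >= 1 voxel, got {shape}")
        if any(s <= 0 for s in spacing):
            raise ValueError(f"spacing must be positive, got {spacing}")
        origin = self.origin
        if origin is None:
            origin = (0.0,) * len(shape)
        origin = tuple(float(o) for o in origin)
        if len(origin) != len(shape):
            raise ValueError("origin must have one entry per axis")
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "origin", origin)

    @property
    def ndim(self) -> int:
        return len(self.shape)

    @property
    def extent_mm(self) -> tuple[float, ...]:
        return tuple(n * d for n, d in zip(self.shape, self.spacing))

    def coords_mm(self) -> list[np.ndarray]:
        """Physical voxel-centre coordinate array per axis (broadcastable)."""
        axes = [
            self.origin[a] + (np.arange(self.shape[a]) + 0.5) * self.spacing[a]
            for a in range(self.ndim)
        ]
        return list(np.meshgrid(*axes, indexing="ij", sparse=True))

    def affine(self) -> np.ndarray:
        """NIfTI-style 4x4 affine carrying spacing and origin."""
        aff = np.eye(4)
        for a in range(self.ndim):
            aff[a, a] = self.spacing[a]
            aff[a, 3] = self.origin[a]
        return aff

    def same_geometry(self, other: "ImageGrid", atol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=atol)
            and np.allclose(self.origin, other.origin, atol=atol)
        )


def require_same_grid(a: ImageGrid, b: ImageGrid, what: str = "inputs") -> None:
    if not a.same_geometry(b):
        raise ValueError(
            f"grid mismatch between {what}: {a.shape}@{a.spacing} vs {b.shape}@{b.spacing}"
        )
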