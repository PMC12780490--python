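"""Voxel grids and 3-D scalar volumes.

These are deliberately small containers: a grid is a shape plus per-axis
spacing in millimetres, and a volume is a grid plus a finite scalar field and a
role tag saying what it carries (the noisy target, a prior, a denoised output,
or a clean reference in synthetic experiments).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

__all__ = ["GridSpec", "Volume3D", "ROLES"]

ROLES = ("target_noisy", "prior_dwi", "prior_anatomical", "denoised", "clean_reference")


@dataclass(frozen=True)
class GridSpec:
    """A voxel grid: shape (nx, ny, nz) and spacing (mm per voxel per axis)."""

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self):
        shape = tuple(int(n) for n in self.shape)
        spacing = tuple(float(s) for s in self.spacing)
        if len(shape) != 3 or len(spacing) != 3:
            raise ValueError("GridSpec needs 3 shape entries and 3 spacings")
        if any(n < 1 for n in shape):
            raise ValueError(f"grid shape entries must be >= 1, got {shape}")
        if any(not np.isfinite(s) or s <= 0 for s in spacing):
            raise ValueError(f"grid spacings must be positive, got {spacing}")
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "spacing", spacing)

    @property
    def n_voxels(self) -> int:
        nx, ny, nz = self.shape
        return nx * ny * nz


@dataclass
class Volume3D:
    """A scalar field on a :class:`GridSpec`.

    ``meta`` opaquely carries I/O metadata (e.g. a NIfTI header and affine) so
    that outputs can be written back on the source geometry.
    """

    grid: GridSpec
    data: np.ndarray
    role: str = "target_noisy"
    meta: Any = None

    def __post_init__(self):
        data = np.asarray(self.data, dtype=float)
        if data.shape != self.grid.shape:
            raise ValueError(
                f"data shape {data.shape} does not match grid shape {self.grid.shape}"
            )
        if not np.all(np.isfinite(data)):
            raise ValueError("volume data must be finite (no NaN/inf)")
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r}; expected one of {ROLES}")
        self.data = data

    def with_data(self, data: np.ndarray, role: str | None = None) -> "Volume3D":
        """A copy on the same grid with new data (and optionally a new role)."""
        return Volume3D(self.grid, data, role or self.role, meta=self.meta)
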