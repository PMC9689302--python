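"""Staggered (MAC) Cartesian grid descriptor.

The fluid domain is the channel [0, L] x [0, D].  By default one extra row
of wall cells is added below y = 0 and above y = D so that the no-slip
boundary can be represented through the same cell mask as the stenosis;
cell centers of the lumen then tile [0, D] exactly.

Staggering convention (arrays are indexed [j, i] = [y, x]):

* pressure / scalars at cell centers, shape ``(ny, nx)``
* axial velocity u at x-faces, shape ``(ny, nx + 1)``
* transverse velocity v at y-faces, shape ``(ny + 1, nx)``
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Grid"]


@dataclass(frozen=True)
class Grid:
    """Uniform staggered grid covering [0, L] x [y0, y0 + ny*dy]."""

    L: float
    D: float
    nx: int
    ny_lumen: int
    wall_rows: bool = True

    def __post_init__(self) -> None:
        if self.L <= 0 or self.D <= 0:
            raise ValueError("grid extents must be positive")
        if self.nx < 2 or self.ny_lumen < 2:
            raise ValueError("need at least 2 cells per direction")

    @property
    def dx(self) -> float:
        return self.L / self.nx

    @property
    def dy(self) -> float:
        return self.D / self.ny_lumen

    @property
    def ny(self) -> int:
        """Total number of cell rows, including wall rows when present."""
        return self.ny_lumen + (2 if self.wall_rows else 0)

    @property
    def y0(self) -> float:
        """y coordinate of the bottom edge of the bottom cell row."""
        return -self.dy if self.wall_rows else 0.0

    # --- coordinates -----------------------------------------------------

    def x_centers(self) -> np.ndarray:
        return (np.arange(self.nx) + 0.5) * self.dx

    def y_centers(self) -> np.ndarray:
        return self.y0 + (np.arange(self.ny) + 0.5) * self.dy

    def u_face_coords(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) 1D coordinate arrays of u sample points."""
        return np.arange(self.nx + 1) * self.dx, self.y_centers()

    def v_face_coords(self) -> tuple[np.ndarray, np.ndarray]:
        return self.x_centers(), self.y0 + np.arange(self.ny + 1) * self.dy

    def cell_area(self) -> float:
        return self.dx * self.dy

    def column_of_x(self, x: float) -> int:
        return int(np.clip(x / self.dx, 0, self.nx - 1))
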