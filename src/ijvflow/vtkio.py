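"""Minimal legacy-ASCII VTK writers for inspection of fields and leaflets.

Structured-points files hold cell-centered scalar/vector fields as point
data on the cell-center lattice; polyline files hold leaflet node chains.
Readable by ParaView/VisIt and by any VTK legacy reader.
"""

from __future__ import annotations

import numpy as np

from .grid import Grid

__all__ = ["write_structured_points", "write_polylines"]


def write_structured_points(path: str, grid: Grid,
                            scalars: dict[str, np.ndarray] | None = None,
                            vectors: dict[str, tuple[np.ndarray, np.ndarray]] | None = None
                            ) -> None:
    """Write cell-centered fields (shape (ny, nx)) as a legacy VTK file."""
    ny, nx = grid.ny, grid.nx
    lines = [
        "# vtk DataFile Version 3.0",
        "ijvflow field snapshot",
        "ASCII",
        "DATASET STRUCTURED_POINTS",
        f"DIMENSIONS {nx} {ny} 1",
        f"ORIGIN {grid.dx / 2:.9g} {grid.y0 + grid.dy / 2:.9g} 0",
        f"SPACING {grid.dx:.9g} {grid.dy:.9g} 1",
        f"POINT_DATA {nx * ny}",
    ]
    for name, f in (scalars or {}).items():
        if f.shape != (ny, nx):
            raise ValueError(f"field {name!r} has shape {f.shape}, want {(ny, nx)}")
        lines.append(f"SCALARS {name} double 1")
        lines.append("LOOKUP_TABLE default")
        lines.extend(f"{v:.9g}" for v in f.ravel())
    for name, (fx, fy) in (vectors or {}).items():
        lines.append(f"VECTORS {name} double")
        lines.extend(f"{a:.9g} {b:.9g} 0" for a, b in zip(fx.ravel(), fy.ravel()))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def write_polylines(path: str, chains: list[np.ndarray]) -> None:
    """Write node chains (each (n, 2)) as VTK polylines."""
    pts = np.vstack(chains)
    lines = [
        "# vtk DataFile Version 3.0",
        "ijvflow leaflets",
        "ASCII",
        "DATASET POLYDATA",
        f"POINTS {len(pts)} double",
    ]
    lines.extend(f"{x:.9g} {y:.9g} 0" for x, y in pts)
    total = sum(len(c) + 1 for c in chains)
    lines.append(f"LINES {len(chains)} {total}")
    offset = 0
    for c in chains:
        lines.append(" ".join([str(len(c))] + [str(offset + i) for i in range(len(c))]))
        offset += len(c)
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
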