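"""Immersed-boundary fluid-structure coupling.

Leaflet fibers live on a fixed Eulerian grid.  The classical 4-point
regularized delta kernel (Peskin) interpolates fluid velocity to the
Lagrangian nodes and spreads nodal forces back to the staggered body-force
field F of the momentum equation; spreading is the exact adjoint of
interpolation, so the momentum imparted to the fluid equals and opposes the
hydrodynamic force on the leaflets to round-off.

The hydrodynamic traction on a node is a drag-type penalty
``gamma (U_interp - V_node)`` relaxing the node toward the local fluid
velocity; its reaction (and only it) is spread to the fluid.  Elastic
forces are internal to the leaflet.  This loose (one pass per step)
coupling is adequate at the mild solid/fluid density ratio of venous
tissue to blood (about 1.14).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fluid import FlowState, ProjectionSolver
from .solid import (HyperelasticMaterial, LeafletState, advance_leaflets,
                    leaflet_forces)

__all__ = [
    "IBKernel",
    "delta_weights",
    "interpolate_velocity",
    "spread_forces",
    "coupled_step",
    "CouplingConfig",
]


def _phi4(r: np.ndarray) -> np.ndarray:
    """Peskin 4-point regularized delta, support |r| < 2, partition of unity."""
    r = np.abs(np.asarray(r, dtype=float))
    out = np.zeros_like(r)
    inner = r <= 1.0
    outer = (r > 1.0) & (r < 2.0)
    ri = r[inner]
    out[inner] = (3.0 - 2.0 * ri + np.sqrt(1.0 + 4.0 * ri - 4.0 * ri ** 2)) / 8.0
    ro = r[outer]
    out[outer] = (5.0 - 2.0 * ro - np.sqrt(-7.0 + 12.0 * ro - 4.0 * ro ** 2)) / 8.0
    return out


@dataclass(frozen=True)
class IBKernel:
    """4-point regularized delta kernel; support radius 2 cells per axis."""

    support: int = 4

    def weights_1d(self, coord: np.ndarray, h: float, n: int
                   ) -> tuple[np.ndarray, np.ndarray]:
        """Indices (m, 4) and weights (m, 4) along one axis for sample
        points located at ``i * h`` (i = 0..n-1).  Indices are clipped to
        the grid so weights still sum to 1 near the edges."""
        coord = np.asarray(coord, dtype=float)
        base = np.floor(coord / h).astype(int)
        offsets = np.arange(-1, 3)
        idx = base[:, None] + offsets[None, :]
        w = _phi4(coord[:, None] / h - idx)
        return np.clip(idx, 0, n - 1), w


def delta_weights(position: np.ndarray, origin: tuple[float, float],
                  h: tuple[float, float], shape: tuple[int, int],
                  kernel: IBKernel = IBKernel()
                  ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sparse 4x4 stencil (rows, cols, weights) of one node on a field whose
    sample [j, i] sits at (origin[0] + i*h[0], origin[1] + j*h[1]).

    Weights are nonnegative and sum to 1.  Raises when the node lies
    outside the sampled region.
    """
    x, y = float(position[0]), float(position[1])
    ny, nx = shape
    if not (origin[0] <= x <= origin[0] + (nx - 1) * h[0]
            and origin[1] <= y <= origin[1] + (ny - 1) * h[1]):
        raise ValueError(f"node {position} outside the grid")
    ix, wx = kernel.weights_1d(np.array([x - origin[0]]), h[0], nx)
    jy, wy = kernel.weights_1d(np.array([y - origin[1]]), h[1], ny)
    W = wy[0][:, None] * wx[0][None, :]
    rows = np.repeat(jy[0], 4).reshape(4, 4)
    cols = np.tile(ix[0], 4).reshape(4, 4)
    return rows, cols, W


def _stencils(positions: np.ndarray, origin: tuple[float, float],
              h: tuple[float, float], shape: tuple[int, int],
              kernel: IBKernel) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    ny, nx = shape
    ix, wx = kernel.weights_1d(positions[:, 0] - origin[0], h[0], nx)
    jy, wy = kernel.weights_1d(positions[:, 1] - origin[1], h[1], ny)
    W = wy[:, :, None] * wx[:, None, :]            # (m, 4, 4)
    return jy, ix, W


def _interp_field(field: np.ndarray, positions: np.ndarray,
                  origin: tuple[float, float], h: tuple[float, float],
                  kernel: IBKernel) -> np.ndarray:
    jy, ix, W = _stencils(positions, origin, h, field.shape, kernel)
    vals = field[jy[:, :, None], ix[:, None, :]]   # (m, 4, 4)
    return np.sum(W * vals, axis=(1, 2))


def _spread_field(values: np.ndarray, positions: np.ndarray, shape,
                  origin: tuple[float, float], h: tuple[float, float],
                  kernel: IBKernel) -> np.ndarray:
    jy, ix, W = _stencils(positions, origin, h, shape, kernel)
    out = np.zeros(shape)
    contrib = values[:, None, None] * W
    np.add.at(out, (jy[:, :, None] * np.ones((1, 1, 4), int),
                    ix[:, None, :] * np.ones((1, 4, 1), int)), contrib)
    return out


def interpolate_velocity(solver: ProjectionSolver, state: FlowState,
                         nodes: np.ndarray, kernel: IBKernel = IBKernel()
                         ) -> np.ndarray:
    """Fluid velocity (m/s) at Lagrangian node positions (m); exact for
    fields affine in position."""
    g = solver.grid
    nodes = np.asarray(nodes, dtype=float)
    ux, uy = g.u_face_coords()
    vx, vy = g.v_face_coords()
    un = _interp_field(state.u, nodes, (ux[0], uy[0]), (g.dx, g.dy), kernel)
    vn = _interp_field(state.v, nodes, (vx[0], vy[0]), (g.dx, g.dy), kernel)
    return np.column_stack([un, vn])


def spread_forces(solver: ProjectionSolver, nodes: np.ndarray,
                  forces: np.ndarray, kernel: IBKernel = IBKernel()
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Spread nodal forces (N per unit depth) to staggered body-force
    densities (N/m^3) on the u and v faces.  The total spread force equals
    the total nodal force; spreading is the adjoint of interpolation."""
    g = solver.grid
    nodes = np.asarray(nodes, dtype=float)
    forces = np.asarray(forces, dtype=float)
    area = g.dx * g.dy
    ux, uy = g.u_face_coords()
    vx, vy = g.v_face_coords()
    fx = _spread_field(forces[:, 0], nodes, (g.ny, g.nx + 1),
                       (ux[0], uy[0]), (g.dx, g.dy), kernel) / area
    fy = _spread_field(forces[:, 1], nodes, (g.ny + 1, g.nx),
                       (vx[0], vy[0]), (g.dx, g.dy), kernel) / area
    return fx, fy


# ----------------------------------------------------------------------
# coupled time step
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class CouplingConfig:
    thickness: float = 0.001
    traction_beta: float = 1.0    # gamma = beta * m_node / dt
    damping: float = 0.0
    guard_cells: float = 1.0      # minimum node-wall / node-node distance, cells
    guard_stiffness: float = 50.0  # N/m^2 per unit depth, short-range penalty


def _guard_forces(leaflets: list[LeafletState], solver: ProjectionSolver,
                  cfg: CouplingConfig) -> list[np.ndarray]:
    """Short-range penalty keeping nodes one cell away from walls and from
    the opposite leaflet (prevents kernel overlap when the valve closes)."""
    g = solver.grid
    d0 = cfg.guard_cells * min(g.dx, g.dy)
    out = []
    for li, leaf in enumerate(leaflets):
        f = np.zeros_like(leaf.x)
        y = leaf.x[:, 1]
        low = y - 0.0
        f[:, 1] += cfg.guard_stiffness * np.maximum(d0 - low, 0.0)
        high = g.D - y
        f[:, 1] -= cfg.guard_stiffness * np.maximum(d0 - high, 0.0)
        for lj, other in enumerate(leaflets):
            if lj == li:
                continue
            diff = leaf.x[:, None, :] - other.x[None, :, :]   # (n, m, 2)
            dist = np.linalg.norm(diff, axis=2)
            near = dist < d0
            if near.any():
                dirn = np.where(dist[:, :, None] > 0, diff / np.maximum(dist, 1e-30)[:, :, None], 0.0)
                mag = cfg.guard_stiffness * np.maximum(d0 - dist, 0.0)
                f += np.sum(mag[:, :, None] * dirn, axis=1)
        out.append(f)
    return out


def coupled_step(solver: ProjectionSolver, state: FlowState,
                 leaflets: list[LeafletState], dt: float,
                 material: HyperelasticMaterial,
                 cfg: CouplingConfig = CouplingConfig(),
                 mu_t: np.ndarray | None = None,
                 kernel: IBKernel = IBKernel()
                 ) -> tuple[FlowState, list[LeafletState], dict]:
    """One loosely-coupled FSI step.

    Sequence: interpolate the fluid velocity to the leaflet nodes, advance
    each leaflet under its elastic forces plus a dissipative drag traction
    ``gamma (U_interp - V_node)`` toward that frozen fluid velocity
    (evaluated at the current node velocity every solid sub-step), then
    spread the exact reaction of the time-integrated traction impulse to
    the fluid body force and advance the fluid.  The momentum given to the
    fluid is equal and opposite to the hydrodynamic impulse received by
    the leaflets, to round-off, by kernel adjointness.  Returns the new
    flow state, new leaflet states and a diagnostics dict.
    """
    g = solver.grid
    guards = _guard_forces(leaflets, solver, cfg)
    fx = np.zeros((g.ny, g.nx + 1))
    fy = np.zeros((g.ny + 1, g.nx))
    new_leaflets = []
    total_on_leaflets = np.zeros(2)
    max_disp = min(g.dx, g.dy)
    for leaf, guard in zip(leaflets, guards):
        u_node = interpolate_velocity(solver, state, leaf.x, kernel)
        gamma = cfg.traction_beta * leaf.node_mass(material, cfg.thickness) / dt
        impulse = np.zeros_like(leaf.x)
        new_leaf = advance_leaflets(leaf, material, cfg.thickness, guard, dt,
                                    damping=cfg.damping, max_disp=max_disp,
                                    drag_gamma=gamma, drag_target=u_node,
                                    impulse_out=impulse)
        new_leaflets.append(new_leaf)
        # reaction spread from the mid-step node positions
        mid = 0.5 * (leaf.x + new_leaf.x)
        dfx, dfy = spread_forces(solver, mid, -impulse / dt, kernel)
        fx += dfx
        fy += dfy
        total_on_leaflets += impulse.sum(axis=0) / dt

    new_state = solver.advance(state, dt, mu_t=mu_t, fx=fx, fy=fy)
    diag = {
        "force_on_leaflets": total_on_leaflets,
        "force_on_fluid": np.array([fx.sum() * g.dx * g.dy,
                                    fy.sum() * g.dx * g.dy]),
        "max_tip_speed": max(np.abs(l.v).max() for l in new_leaflets),
    }
    return new_state, new_leaflets, diag
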