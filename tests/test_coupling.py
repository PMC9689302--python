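"""Immersed-boundary kernel contracts and coupled-step invariants."""

import numpy as np
import pytest

from ijvflow.coupling import (CouplingConfig, IBKernel, coupled_step,
                              delta_weights, interpolate_velocity,
                              spread_forces, _interp_field, _spread_field)
from ijvflow.fluid import FluidProperties, InletWaveform, ProjectionSolver
from ijvflow.geometry import build_valve, build_vessel, wall_mask, ValveSpec
from ijvflow.grid import Grid
from ijvflow.solid import HyperelasticMaterial


def make_solver(nx=60, ny=16, f=0.0, **kw):
    geom = build_vessel(f=f)
    grid = Grid(geom.L, geom.D, nx, ny)
    mask = wall_mask(geom, grid)
    return grid, ProjectionSolver(grid, mask, FluidProperties(), **kw)


# --- delta weights ----------------------------------------------------------

def test_weights_sum_to_one_random_positions():
    grid, solver = make_solver()
    rng = np.random.default_rng(0)
    shape = (grid.ny, grid.nx)
    for _ in range(1000):
        pos = (rng.uniform(0.02, 0.18), rng.uniform(0.002, 0.012))
        _, _, W = delta_weights(pos, (grid.dx / 2, grid.y0 + grid.dy / 2),
                                (grid.dx, grid.dy), shape)
        assert W.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(W >= 0)
        assert W.shape == (4, 4)


def test_weights_symmetric_at_sample_point():
    grid, _ = make_solver()
    origin = (grid.dx / 2, grid.y0 + grid.dy / 2)
    pos = (origin[0] + 10 * grid.dx, origin[1] + 5 * grid.dy)
    _, _, W = delta_weights(pos, origin, (grid.dx, grid.dy),
                            (grid.ny, grid.nx))
    # node exactly on a sample point: the active 3x3 block is symmetric
    # about it and the far row/column of the 4-point stencil vanishes
    assert np.allclose(W[:3, :3], W[:3, :3][::-1, ::-1], atol=1e-14)
    assert np.allclose(W[3, :], 0.0) and np.allclose(W[:, 3], 0.0)
    assert W.max() == pytest.approx(0.25, abs=1e-12)  # phi(0)^2


def test_weights_translation_invariance():
    grid, _ = make_solver()
    origin = (grid.dx / 2, grid.y0 + grid.dy / 2)
    pos = np.array([0.05123, 0.00631])
    r1, c1, W1 = delta_weights(pos, origin, (grid.dx, grid.dy),
                               (grid.ny, grid.nx))
    r2, c2, W2 = delta_weights(pos + [grid.dx, 0.0], origin,
                               (grid.dx, grid.dy), (grid.ny, grid.nx))
    assert np.array_equal(c2, c1 + 1)
    assert np.array_equal(r2, r1)
    assert np.allclose(W2, W1, atol=1e-12)


def test_node_outside_domain_rejected():
    grid, _ = make_solver()
    with pytest.raises(ValueError, match="outside"):
        delta_weights((-0.01, 0.005), (grid.dx / 2, grid.y0 + grid.dy / 2),
                      (grid.dx, grid.dy), (grid.ny, grid.nx))


# --- interpolation / spreading ----------------------------------------------

def test_interpolate_constant_and_linear_fields():
    grid, solver = make_solver()
    state = solver.initialize_state()
    rng = np.random.default_rng(1)
    nodes = np.column_stack([rng.uniform(0.02, 0.18, 40),
                             rng.uniform(0.003, 0.012, 40)])
    state.u[:] = 3.7
    state.v[:] = -1.2
    vel = interpolate_velocity(solver, state, nodes)
    assert np.allclose(vel[:, 0], 3.7, atol=1e-12)
    assert np.allclose(vel[:, 1], -1.2, atol=1e-12)
    # affine field reproduced exactly
    ux, uy = grid.u_face_coords()
    state.u = 2.0 + 30.0 * ux[None, :] + 10.0 * uy[:, None]
    vel = interpolate_velocity(solver, state, nodes)
    exact = 2.0 + 30.0 * nodes[:, 0] + 10.0 * nodes[:, 1]
    assert np.allclose(vel[:, 0], exact, atol=1e-10)


def test_interpolation_mirror_symmetry():
    grid, solver = make_solver()
    state = solver.initialize_state()
    rng = np.random.default_rng(2)
    state.u = rng.normal(size=state.u.shape)
    nodes = np.column_stack([rng.uniform(0.02, 0.18, 20),
                             rng.uniform(0.003, 0.012, 20)])
    vel = interpolate_velocity(solver, state, nodes)
    m_state = state.copy()
    m_state.u = state.u[::-1, :]
    m_state.v = -state.v[::-1, :]
    m_nodes = nodes.copy()
    m_nodes[:, 1] = grid.D - m_nodes[:, 1]
    m_vel = interpolate_velocity(solver, m_state, m_nodes)
    assert np.allclose(m_vel[:, 0], vel[:, 0], atol=1e-12)


def test_spread_totals_and_adjointness():
    grid, solver = make_solver()
    rng = np.random.default_rng(3)
    nodes = np.column_stack([rng.uniform(0.02, 0.18, 25),
                             rng.uniform(0.003, 0.012, 25)])
    forces = rng.normal(size=(25, 2))
    fx, fy = spread_forces(solver, nodes, forces)
    area = grid.dx * grid.dy
    assert fx.sum() * area == pytest.approx(forces[:, 0].sum(), abs=1e-12)
    assert fy.sum() * area == pytest.approx(forces[:, 1].sum(), abs=1e-12)
    # zero forces -> zero field
    zx, zy = spread_forces(solver, nodes, np.zeros((25, 2)))
    assert not zx.any() and not zy.any()
    # adjointness: <spread(f), u>_grid = <f, interp(u)>_nodes
    state = solver.initialize_state()
    state.u = rng.normal(size=state.u.shape)
    state.v = rng.normal(size=state.v.shape)
    lhs = (fx * state.u).sum() * area + (fy * state.v).sum() * area
    vel = interpolate_velocity(solver, state, nodes)
    rhs = (forces * vel).sum()
    assert lhs == pytest.approx(rhs, rel=1e-10)


# --- coupled step ------------------------------------------------------------

MAT = HyperelasticMaterial()


def test_zero_flow_nothing_moves():
    geom = build_vessel(f=0.0)
    grid = Grid(geom.L, geom.D, 60, 16)
    mask = wall_mask(geom, grid)
    inlet = InletWaveform(amplitude=0.0, offset=0.0)
    solver = ProjectionSolver(grid, mask, FluidProperties(), inlet=inlet)
    state = solver.initialize_state()
    spec = ValveSpec(n_nodes=8)
    leaflets = list(build_valve(geom.D, spec))
    cfg = CouplingConfig(thickness=spec.leaflet_thickness, guard_stiffness=0.0)
    x0 = [l.x.copy() for l in leaflets]
    for _ in range(5):
        state, leaflets, _ = coupled_step(solver, state, leaflets, 5e-4,
                                          MAT, cfg)
    # nothing moves beyond round-off in the discrete reference curvature
    assert state.max_speed() < 1e-12
    for l, x in zip(leaflets, x0):
        assert np.allclose(l.x, x, atol=1e-12)


def test_force_balance_per_step():
    """Momentum given to the fluid equals and opposes the hydrodynamic
    impulse on the leaflets (adjointness of spreading)."""
    geom = build_vessel(f=0.0)
    grid = Grid(geom.L, geom.D, 60, 16)
    mask = wall_mask(geom, grid)
    solver = ProjectionSolver(grid, mask, FluidProperties())
    state = solver.initialize_state()
    spec = ValveSpec(n_nodes=8)
    leaflets = list(build_valve(geom.D, spec))
    cfg = CouplingConfig(thickness=spec.leaflet_thickness)
    for _ in range(3):
        dt = solver.courant_dt(state, 0.5)
        state, leaflets, diag = coupled_step(solver, state, leaflets, dt,
                                             MAT, cfg)
        scale = max(np.abs(diag["force_on_leaflets"]).max(), 1e-30)
        assert np.allclose(diag["force_on_fluid"],
                           -diag["force_on_leaflets"], atol=1e-10 * scale)


def test_rigid_leaflets_block_flow_and_keep_symmetry():
    """Fully anchored (rigid-limit) leaflets act as a fixed obstacle: the
    local fluid velocity at the leaflets is driven far below the inlet
    speed, and an unperturbed symmetric configuration stays symmetric."""
    geom = build_vessel(f=0.0)
    grid = Grid(geom.L, geom.D, 100, 16)
    mask = wall_mask(geom, grid)
    inlet = InletWaveform(amplitude=0.0, offset=12.0)
    solver = ProjectionSolver(grid, mask, FluidProperties(), inlet=inlet)
    state = solver.initialize_state()
    spec = ValveSpec(n_nodes=10)
    lower, upper = build_valve(geom.D, spec)
    for leaf in (lower, upper):
        leaf.anchored[:] = True
    leaflets = [lower, upper]
    cfg = CouplingConfig(thickness=spec.leaflet_thickness)
    while state.t < 0.2:
        dt = solver.courant_dt(state, 0.5)
        state, leaflets, _ = coupled_step(solver, state, leaflets, dt, MAT, cfg)
    vel = interpolate_velocity(solver, state, leaflets[0].x[2:-1])
    speed_at_leaflet = np.linalg.norm(vel, axis=1).mean()
    # the penalty coupling enforces the obstacle softly: the local speed
    # drops well below ambient (a passive tracer would read ~1.0 ambient)
    assert speed_at_leaflet < 0.6 * 0.12
    assert np.allclose(leaflets[0].x, lower.ref, atol=1e-15)
    asym = np.abs(state.u - state.u[::-1, :]).max()
    assert asym < 1e-6 * state.max_speed()
    # and a jet forms in the valve gap (flow accelerates through d2)
    gap_col = grid.column_of_x(spec.anchor_x + 0.008)
    uc = 0.5 * (state.u[:, :-1] + state.u[:, 1:])
    assert uc[:, gap_col].max() > 1.5 * 0.12


def test_leaflets_stay_inside_lumen(desk_results):
    """No leaflet node penetrates the walls in any desk-scale case."""
    for res in desk_results.values():
        for snap in res.snapshots:
            for leaf in snap["leaflets"]:
                assert np.all(leaf.x[:, 1] >= -1e-12)
                assert np.all(leaf.x[:, 1] <= res.config.geometry.D + 1e-12)
                assert np.all(leaf.x[:, 0] > 0)
                assert np.all(leaf.x[:, 0] < res.config.geometry.L)
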