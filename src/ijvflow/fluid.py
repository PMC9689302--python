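"""Incompressible 2D flow core: fractional-step projection on a MAC grid.

Momentum and continuity (Reynolds-averaged when an eddy viscosity is
supplied):

    rho (du/dt + u . grad u) = div[ -p I + (mu + mu_T)(grad u + grad u^T) ] + F
    div u = 0

Boundary conditions follow the vein model: Dirichlet plug velocity
U_inlet(t) at the inlet, static pressure p = 0 at the outlet, no-slip on
the channel walls and on the rasterized stenosis.  The pulsatile inlet is
the sinusoidal waveform

    U_inlet(t) = 8 sin(t pi / 6) + 12   [cm/s]

(12 cm/s at t = 0, peaking at 20 cm/s at t = 3 s, back to 12 cm/s at
t = 6 s).  Time stepping: explicit 2nd-order upwind-biased advection,
explicit variable-viscosity stress divergence with mirror-ghost no-slip
walls, then an exact pressure projection by direct sparse factorization.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import TYPE_CHECKING

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu

if TYPE_CHECKING:
    from .grid import Grid

__all__ = [
    "FluidProperties",
    "InletWaveform",
    "FlowState",
    "CFLError",
    "ProjectionSolver",
    "inlet_velocity",
    "reynolds_number",
]

log = logging.getLogger("ijvflow")


@dataclass(frozen=True)
class FluidProperties:
    """Blood at 37 C: rho = 1055 kg/m^3, mu = 2.78e-3 Pa s (Newtonian)."""

    rho: float = 1055.0
    mu: float = 2.78e-3

    def __post_init__(self) -> None:
        if self.rho <= 0 or self.mu <= 0:
            raise ValueError("density and viscosity must be positive")

    @property
    def nu(self) -> float:
        return self.mu / self.rho


@dataclass(frozen=True)
class InletWaveform:
    """Sinusoidal inlet speed U(t) = amplitude * sin(t * angular) + offset, cm/s.

    Defaults model carotid-pulsation / respiratory modulation of jugular
    flow: 16 +/- 4 cm/s over a 12 s period (amplitude 8, offset 12,
    angular factor pi/6 rad/s), so U ranges over [4, 20] cm/s.
    """

    amplitude: float = 8.0      # cm/s
    offset: float = 12.0        # cm/s
    angular: float = np.pi / 6  # rad/s

    def __call__(self, t: float) -> float:
        """Inlet speed in cm/s at time t (s)."""
        return self.amplitude * np.sin(np.asarray(t, dtype=float) * self.angular) + self.offset

    def speed_ms(self, t: float) -> float:
        return self(t) * 1e-2


def inlet_velocity(t: float) -> float:
    """Default pulsatile inlet speed, cm/s: 8 sin(t pi/6) + 12."""
    if np.any(np.asarray(t) < 0):
        raise ValueError("time must be nonnegative")
    return InletWaveform()(t)


def reynolds_number(props: FluidProperties, U: float, D: float) -> float:
    """Re = rho U D / mu."""
    return props.rho * U * D / props.mu


@dataclass
class FlowState:
    """Staggered velocity + pressure at one time point.

    u: (ny, nx+1) axial velocity at x-faces; v: (ny+1, nx) transverse
    velocity at y-faces; p: (ny, nx) pressure at cell centers; optional
    turbulence fields k, omega at cell centers; t in seconds.
    """

    u: np.ndarray
    v: np.ndarray
    p: np.ndarray
    t: float = 0.0
    k: np.ndarray | None = None
    omega: np.ndarray | None = None

    def max_speed(self) -> float:
        return max(float(np.abs(self.u).max()), float(np.abs(self.v).max()))

    def copy(self) -> "FlowState":
        return FlowState(self.u.copy(), self.v.copy(), self.p.copy(), self.t,
                         None if self.k is None else self.k.copy(),
                         None if self.omega is None else self.omega.copy())


class CFLError(RuntimeError):
    def __init__(self, dt: float, admissible: float):
        super().__init__(f"dt = {dt:.4g} s violates the advective CFL bound; "
                         f"admissible dt <= {admissible:.4g} s")
        self.admissible = admissible


# ----------------------------------------------------------------------
# solver
# ----------------------------------------------------------------------

class ProjectionSolver:
    """Fractional-step solver bound to one grid + wall mask.

    Parameters
    ----------
    grid : Grid
    solid : bool array (ny, nx), True at wall cells (may be all False for
        an unbounded/free-slip channel).
    props : FluidProperties
    inlet : InletWaveform (evaluated in cm/s, converted internally)
    inlet_profile : optional array (ny,) multiplying the plug inlet speed
        row-wise (used for controlled symmetry-breaking perturbations).
    advect : include the inertial term (False = Stokes mode).
    wall_slip : free-slip tangential condition at mask/domain walls
        (testing aid; the vein walls are no-slip).
    """

    def __init__(self, grid: "Grid", solid: np.ndarray, props: FluidProperties,
                 *, inlet: InletWaveform | None = None,
                 inlet_profile: np.ndarray | None = None,
                 advect: bool = True, wall_slip: bool = False,
                 dt_max: float = 2.0e-3, visc_safety: float = 0.12):
        self.grid = grid
        self.solid = np.asarray(solid, dtype=bool)
        if self.solid.shape != (grid.ny, grid.nx):
            raise ValueError("mask shape does not match the grid")
        self.props = props
        self.inlet = inlet or InletWaveform()
        self.advect = advect
        self.wall_slip = wall_slip
        self.dt_max = dt_max
        self.visc_safety = visc_safety

        self.fluid = ~self.solid
        ny, nx = grid.ny, grid.nx
        # u-face solid flags: face i touches cells i-1 and i of its row
        s = self.solid
        self.usolid = np.zeros((ny, nx + 1), dtype=bool)
        self.usolid[:, 1:nx] = s[:, :-1] | s[:, 1:]
        self.usolid[:, 0] = s[:, 0]
        self.usolid[:, nx] = s[:, -1]
        # v-face solid flags: face j touches cells j-1 and j of its column;
        # domain top/bottom faces are impermeable
        self.vsolid = np.ones((ny + 1, nx), dtype=bool)
        self.vsolid[1:ny, :] = s[:-1, :] | s[1:, :]

        self.inlet_rows = ~self.usolid[:, 0]
        if inlet_profile is None:
            self.inlet_profile = np.ones(ny)
        else:
            self.inlet_profile = np.asarray(inlet_profile, dtype=float)
        self._build_poisson()

    # --- pressure Poisson -------------------------------------------------

    def _build_poisson(self) -> None:
        g, s = self.grid, self.solid
        ny, nx = g.ny, g.nx
        idx = np.arange(ny * nx).reshape(ny, nx)
        ax, ay = 1.0 / g.dx ** 2, 1.0 / g.dy ** 2
        rows, cols, vals = [], [], []

        def add(r, c, v):
            rows.append(r); cols.append(c); vals.append(v)

        for j in range(ny):
            for i in range(nx):
                me = idx[j, i]
                if s[j, i]:
                    add(me, me, 1.0)
                    continue
                diag = 0.0
                # west: inlet face (Neumann) or neighbor
                if i > 0 and not s[j, i - 1]:
                    add(me, idx[j, i - 1], ax); diag -= ax
                # east: outlet face is Dirichlet p = 0 at the face
                if i + 1 < nx:
                    if not s[j, i + 1]:
                        add(me, idx[j, i + 1], ax); diag -= ax
                else:
                    diag -= 2.0 * ax
                if j > 0 and not s[j - 1, i]:
                    add(me, idx[j - 1, i], ay); diag -= ay
                if j + 1 < ny and not s[j + 1, i]:
                    add(me, idx[j + 1, i], ay); diag -= ay
                if diag == 0.0:  # isolated cell: pin the pressure
                    diag = -1.0
                add(me, me, diag)

        A = sp.csc_matrix((vals, (rows, cols)), shape=(ny * nx, ny * nx))
        self._lu = splu(A)

    # --- helpers ----------------------------------------------------------

    def inlet_speed_ms(self, t: float) -> float:
        return self.inlet.speed_ms(t)

    def _apply_inlet(self, u: np.ndarray, t: float) -> None:
        u[self.inlet_rows, 0] = self.inlet_speed_ms(t) * self.inlet_profile[self.inlet_rows]

    def divergence(self, state: FlowState) -> np.ndarray:
        g = self.grid
        div = (np.diff(state.u, axis=1) / g.dx + np.diff(state.v, axis=0) / g.dy)
        div[self.solid] = 0.0
        return div

    def initialize_state(self, t: float = 0.0) -> FlowState:
        """Plug flow at U(t) in the lumen, zero transverse velocity, p = 0,
        followed by one projection so the field is discretely solenoidal."""
        g = self.grid
        u = np.zeros((g.ny, g.nx + 1))
        u[~self.usolid] = self.inlet_speed_ms(t)
        self._apply_inlet(u, t)
        v = np.zeros((g.ny + 1, g.nx))
        state = FlowState(u, v, np.zeros((g.ny, g.nx)), t)
        self._project(state, dt=1.0)
        state.p[:] = 0.0
        return state

    def courant_dt(self, state: FlowState, cfl: float,
                   mu_t: np.ndarray | None = None) -> float:
        """Advective CFL bound cfl * h / max|u|, additionally capped by the
        explicit-diffusion limit and dt_max; returns dt_max at rest."""
        if not 0.0 < cfl <= 1.0:
            raise ValueError("cfl must lie in (0, 1]")
        g = self.grid
        h = min(g.dx, g.dy)
        mu_eff = self.props.mu + (0.0 if mu_t is None else float(np.max(mu_t)))
        dt_visc = self.visc_safety * self.props.rho * h ** 2 / mu_eff
        speed = state.max_speed()
        if speed == 0.0:
            return min(self.dt_max, dt_visc)
        return min(cfl * h / speed, dt_visc, self.dt_max)

    # --- discrete operators -----------------------------------------------

    @staticmethod
    def _upwind(q: np.ndarray, vel: np.ndarray, h: float, axis: int,
                valid: np.ndarray) -> np.ndarray:
        """Upwind-biased derivative of q along axis, 2nd order where the two
        upstream samples are usable, 1st order otherwise."""
        qm1 = np.roll(q, 1, axis=axis)
        qm2 = np.roll(q, 2, axis=axis)
        qp1 = np.roll(q, -1, axis=axis)
        qp2 = np.roll(q, -2, axis=axis)
        vm1 = np.roll(valid, 1, axis=axis)
        vm2 = np.roll(valid, 2, axis=axis)
        vp1 = np.roll(valid, -1, axis=axis)
        vp2 = np.roll(valid, -2, axis=axis)
        # kill wrap-around
        edge = [slice(None)] * q.ndim
        for k, sl in ((1, slice(0, 1)), (2, slice(0, 2))):
            e = list(edge); e[axis] = sl
            (vm1 if k == 1 else vm2)[tuple(e)] = False
        for k, sl in ((1, slice(-1, None)), (2, slice(-2, None))):
            e = list(edge); e[axis] = sl
            (vp1 if k == 1 else vp2)[tuple(e)] = False

        g1b = np.where(vm1, (q - qm1) / h, 0.0)
        g2b = np.where(vm1 & vm2, (3 * q - 4 * qm1 + qm2) / (2 * h), g1b)
        g1f = np.where(vp1, (qp1 - q) / h, 0.0)
        g2f = np.where(vp1 & vp2, (-3 * q + 4 * qp1 - qp2) / (2 * h), g1f)
        return np.where(vel >= 0, g2b, g2f)

    def _advection(self, state: FlowState) -> tuple[np.ndarray, np.ndarray]:
        g = self.grid
        u, v = state.u, state.v
        ufl = ~self.usolid
        vfl = ~self.vsolid

        # v averaged to u-faces (ny, nx+1)
        vpad = np.pad(v, ((0, 0), (1, 1)), mode="edge")
        v_at_u = 0.25 * (vpad[:-1, :-1] + vpad[:-1, 1:] + vpad[1:, :-1] + vpad[1:, 1:])
        adv_u = (u * self._upwind(u, u, g.dx, 1, ufl.copy())
                 + v_at_u * self._upwind(u, v_at_u, g.dy, 0, ufl.copy()))

        # u averaged to v-faces (ny+1, nx)
        upad = np.pad(u, ((1, 1), (0, 0)), mode="edge")
        u_at_v = 0.25 * (upad[:-1, :-1] + upad[:-1, 1:] + upad[1:, :-1] + upad[1:, 1:])
        adv_v = (u_at_v * self._upwind(v, u_at_v, g.dx, 1, vfl.copy())
                 + v * self._upwind(v, v, g.dy, 0, vfl.copy()))
        adv_u[self.usolid] = 0.0
        adv_v[self.vsolid] = 0.0
        return adv_u, adv_v

    def _tangential_grad(self, q: np.ndarray, qsolid: np.ndarray, h: float
                         ) -> np.ndarray:
        """d(q)/dn across stacked rows of a face field, evaluated on the
        lines between rows (one extra line at each end), with quadratic
        no-slip ghosts at solid rows (or zero-gradient for free slip)."""
        n0 = q.shape[0]
        fl = ~qsolid
        qz = np.where(fl, q, 0.0)
        grad = np.zeros((n0 + 1, q.shape[1]))
        up, dn = qz[1:], qz[:-1]
        upfl, dnfl = fl[1:], fl[:-1]
        both = upfl & dnfl
        grad[1:n0] = np.where(both, (up - dn) / h, 0.0)
        if self.wall_slip:
            return grad
        # fluid below a solid row: ghost above = -2 q1 + q2/3 (quadratic,
        # wall exactly on the line); fall back to linear mirror at the ends
        dn2 = np.zeros_like(dn); dn2[1:] = qz[:-2]
        dn2fl = np.zeros_like(dnfl); dn2fl[1:] = fl[:-2]
        ghost_up = np.where(dn2fl, -2.0 * dn + dn2 / 3.0, -dn)
        grad[1:n0] = np.where(dnfl & ~upfl, (ghost_up - dn) / h, grad[1:n0])
        up2 = np.zeros_like(up); up2[:-1] = qz[2:]
        up2fl = np.zeros_like(upfl); up2fl[:-1] = fl[2:]
        ghost_dn = np.where(up2fl, -2.0 * up + up2 / 3.0, -up)
        grad[1:n0] = np.where(upfl & ~dnfl, (up - ghost_dn) / h, grad[1:n0])
        # domain edges (only reachable without wall rows): mirror no-slip
        grad[0] = np.where(fl[0], 2.0 * qz[0] / h, 0.0)
        grad[n0] = np.where(fl[-1], -2.0 * qz[-1] / h, 0.0)
        return grad

    def _viscous(self, state: FlowState, mu_t: np.ndarray | None
                 ) -> tuple[np.ndarray, np.ndarray]:
        """Divergence of the deviatoric stress (mu + mu_T)(grad u + grad u^T)."""
        g = self.grid
        ny, nx = g.ny, g.nx
        mu_c = np.full((ny, nx), self.props.mu)
        if mu_t is not None:
            mu_c = mu_c + np.where(self.fluid, mu_t, 0.0)

        # normal stresses at centers
        t11 = 2.0 * mu_c * np.diff(state.u, axis=1) / g.dx
        t22 = 2.0 * mu_c * np.diff(state.v, axis=0) / g.dy
        t11[self.solid] = 0.0
        t22[self.solid] = 0.0

        # shear stress at corners (ny+1, nx+1)
        mu_pad = np.pad(mu_c, 1, mode="edge")
        mu_n = 0.25 * (mu_pad[:-1, :-1] + mu_pad[:-1, 1:]
                       + mu_pad[1:, :-1] + mu_pad[1:, 1:])
        dudy = self._tangential_grad(state.u, self.usolid, g.dy)       # (ny+1, nx+1)
        dvdx = self._tangential_grad(state.v.T, self.vsolid.T, g.dx).T  # (ny+1, nx+1)
        t12 = mu_n * (dudy + dvdx)

        visc_u = np.zeros_like(state.u)
        visc_u[:, 1:nx] = ((t11[:, 1:] - t11[:, :-1]) / g.dx
                           + (t12[1:, 1:nx] - t12[:-1, 1:nx]) / g.dy)
        visc_v = np.zeros_like(state.v)
        visc_v[1:ny, :] = ((t12[1:ny, 1:] - t12[1:ny, :-1]) / g.dx
                           + (t22[1:, :] - t22[:-1, :]) / g.dy)
        visc_u[self.usolid] = 0.0
        visc_v[self.vsolid] = 0.0
        return visc_u, visc_v

    def _project(self, state: FlowState, dt: float) -> None:
        """In-place pressure projection: afterwards div u = 0 on fluid cells."""
        g = self.grid
        ny, nx = g.ny, g.nx
        rho = self.props.rho
        rhs = (rho / dt) * self.divergence(state)
        p = self._lu.solve(rhs.ravel()).reshape(ny, nx)
        p[self.solid] = 0.0

        both_fluid = self.fluid[:, :-1] & self.fluid[:, 1:]
        gradx = np.where(both_fluid, np.diff(p, axis=1) / g.dx, 0.0)
        state.u[:, 1:nx][both_fluid] -= (dt / rho) * gradx[both_fluid]
        # outlet face: Dirichlet p = 0 at the face itself
        out = self.fluid[:, -1]
        state.u[out, nx] -= (dt / rho) * (0.0 - p[out, -1]) / (g.dx / 2)
        both_fluid_v = self.fluid[:-1, :] & self.fluid[1:, :]
        grady = np.where(both_fluid_v, np.diff(p, axis=0) / g.dy, 0.0)
        state.v[1:ny, :][both_fluid_v] -= (dt / rho) * grady[both_fluid_v]
        state.p = p

    # --- time stepping ------------------------------------------------------

    def advance(self, state: FlowState, dt: float,
                mu_t: np.ndarray | None = None,
                fx: np.ndarray | None = None,
                fy: np.ndarray | None = None) -> FlowState:
        """One fractional step to t + dt.

        ``mu_t`` is an eddy-viscosity field at cell centers (Pa s); ``fx``,
        ``fy`` are body-force densities (N/m^3) on the u / v faces (the
        immersed-boundary term F of the momentum equation).
        """
        g = self.grid
        speed = state.max_speed()
        if speed > 0:
            admissible = min(g.dx, g.dy) / speed
            if dt > admissible * (1 + 1e-12):
                raise CFLError(dt, admissible)
        rho = self.props.rho
        new = state.copy()
        new.t = state.t + dt

        visc_u, visc_v = self._viscous(state, mu_t)
        du = visc_u / rho
        dv = visc_v / rho
        if self.advect:
            adv_u, adv_v = self._advection(state)
            du -= adv_u
            dv -= adv_v
        if fx is not None:
            du = du + fx / rho
        if fy is not None:
            dv = dv + fy / rho

        new.u = state.u + dt * du
        new.v = state.v + dt * dv
        new.u[self.usolid] = 0.0
        new.v[self.vsolid] = 0.0
        self._apply_inlet(new.u, new.t)
        new.u[self.fluid[:, -1], g.nx] = new.u[self.fluid[:, -1], g.nx - 1]

        self._project(new, dt)

        if not (np.all(np.isfinite(new.u)) and np.all(np.isfinite(new.v))):
            raise FloatingPointError(
                f"non-finite velocity at t = {new.t:.4f} s "
                f"(max |u| before failure {speed:.3g} m/s)")
        return new

    def stokes_mode_advance(self, state: FlowState, dt: float,
                            mu_t: np.ndarray | None = None,
                            fx: np.ndarray | None = None,
                            fy: np.ndarray | None = None) -> FlowState:
        """Advance without the inertial (advection) term."""
        saved = self.advect
        self.advect = False
        try:
            return self.advance(state, dt, mu_t=mu_t, fx=fx, fy=fy)
        finally:
            self.advect = saved
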