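"""Hyperelastic venous-valve model.

Two layers:

1. the pointwise compressible neo-Hookean constitutive model in a
   plane-strain embedding,

       Ws = mu_s/2 (I1 - 3) - mu_s ln J + lambda_s/2 (ln J)^2,
       S  = dWs/dE = mu_s (I - C^-1) + lambda_s ln J C^-1,
       sigma = J^-1 F S F^T,

   with I1 = tr(C) + 1 (out-of-plane stretch fixed at 1), C = F^T F,
   J = det F, and Lame parameters mu_s = E / 2(1+nu),
   lambda_s = E nu / (1+nu)(1-2nu);

2. a discrete inertial fiber model of each thin leaflet whose stretching
   stiffness E*h and bending stiffness E*h^3/12 (per unit depth, h the
   leaflet thickness) are the small-strain limits of the same material.
   Leaflet roots are clamped (U_solid = 0 at the wall anchor); interior
   nodes carry inertia rho_s * h per unit area and are integrated with
   velocity Verlet, sub-stepped below the elastic stability limit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "HyperelasticMaterial",
    "LeafletState",
    "InvertedElementError",
    "lame_from_modulus",
    "strain_energy",
    "green_lagrange_strain",
    "pk2_stress",
    "cauchy_stress",
    "leaflet_forces",
    "leaflet_energy",
    "advance_leaflets",
    "stable_substep",
]


class InvertedElementError(ValueError):
    """Deformation gradient with non-positive determinant."""


def lame_from_modulus(E: float, nu: float) -> tuple[float, float]:
    """Lame parameters (mu_s, lambda_s) from Young's modulus and Poisson ratio.

    mu_s = E / (2 (1 + nu));  lambda_s = E nu / ((1 + nu)(1 - 2 nu)).
    The incompressible limit nu = 0.5 is rejected.
    """
    if E <= 0:
        raise ValueError("Young's modulus must be positive")
    if not 0.0 <= nu < 0.5:
        raise ValueError("Poisson ratio must satisfy 0 <= nu < 0.5")
    mu = E / (2.0 * (1.0 + nu))
    lam = E * nu / ((1.0 + nu) * (1.0 - 2.0 * nu))
    return mu, lam


@dataclass(frozen=True)
class HyperelasticMaterial:
    """Valve material: default jugular-leaflet values E = 2.6 MPa, nu = 0.3,
    rho_s = 1200 kg/m^3, giving mu_s = 1.0 MPa and lambda_s = 1.5 MPa."""

    E: float = 2.6e6
    nu: float = 0.3
    rho_s: float = 1200.0

    def __post_init__(self) -> None:
        lame_from_modulus(self.E, self.nu)  # validates
        if self.rho_s <= 0:
            raise ValueError("solid density must be positive")

    @property
    def mu_s(self) -> float:
        return lame_from_modulus(self.E, self.nu)[0]

    @property
    def lam_s(self) -> float:
        return lame_from_modulus(self.E, self.nu)[1]


# ----------------------------------------------------------------------
# pointwise constitutive model (plane strain)
# ----------------------------------------------------------------------

def _det2(F: np.ndarray) -> float:
    return F[0, 0] * F[1, 1] - F[0, 1] * F[1, 0]


def green_lagrange_strain(F: np.ndarray) -> np.ndarray:
    """epsilon = (F^T F - I) / 2."""
    F = np.asarray(F, dtype=float)
    return 0.5 * (F.T @ F - np.eye(2))


def strain_energy(F: np.ndarray, material: HyperelasticMaterial) -> float:
    """Compressible neo-Hookean strain energy density (J/m^3)."""
    F = np.asarray(F, dtype=float)
    J = _det2(F)
    if J <= 0:
        raise InvertedElementError(f"det F = {J} <= 0")
    mu, lam = material.mu_s, material.lam_s
    I1 = float(np.trace(F.T @ F)) + 1.0  # plane strain: out-of-plane stretch 1
    lnJ = np.log(J)
    return 0.5 * mu * (I1 - 3.0) - mu * lnJ + 0.5 * lam * lnJ ** 2


def pk2_stress(F: np.ndarray, material: HyperelasticMaterial) -> np.ndarray:
    """Second Piola-Kirchhoff stress S = dWs/d(epsilon) (Pa), in-plane 2x2."""
    F = np.asarray(F, dtype=float)
    J = _det2(F)
    if J <= 0:
        raise InvertedElementError(f"det F = {J} <= 0")
    mu, lam = material.mu_s, material.lam_s
    C = F.T @ F
    Cinv = np.linalg.inv(C)
    return mu * (np.eye(2) - Cinv) + lam * np.log(J) * Cinv


def cauchy_stress(F: np.ndarray, S: np.ndarray) -> np.ndarray:
    """sigma = J^-1 F S F^T (Pa)."""
    F = np.asarray(F, dtype=float)
    J = _det2(F)
    if J <= 0:
        raise InvertedElementError(f"det F = {J} <= 0")
    return (F @ np.asarray(S, dtype=float) @ F.T) / J


# ----------------------------------------------------------------------
# discrete leaflet (inertial fiber)
# ----------------------------------------------------------------------

@dataclass
class LeafletState:
    """Lagrangian state of one leaflet fiber.

    ``x`` are node positions (n, 2) in meters, ``v`` node velocities,
    ``ref`` the reference configuration, ``anchored`` flags nodes held at
    the wall (zero velocity).  ``ds`` are reference segment lengths.
    """

    x: np.ndarray
    v: np.ndarray
    ref: np.ndarray
    anchored: np.ndarray
    ds: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        self.ref = np.asarray(self.ref, dtype=float)
        self.anchored = np.asarray(self.anchored, dtype=bool)
        if self.x.shape[0] < 3:
            raise ValueError("a leaflet needs at least 3 nodes")
        self.ds = np.linalg.norm(np.diff(self.ref, axis=0), axis=1)
        if np.any(self.ds <= 0):
            raise ValueError("coincident adjacent reference nodes")
        if np.any(self.v[self.anchored] != 0.0):
            raise ValueError("anchored nodes must have zero velocity")

    @classmethod
    def from_reference(cls, ref: np.ndarray, anchored: np.ndarray) -> "LeafletState":
        ref = np.asarray(ref, dtype=float)
        return cls(x=ref.copy(), v=np.zeros_like(ref), ref=ref,
                   anchored=anchored)

    @property
    def n_nodes(self) -> int:
        return self.x.shape[0]

    def node_mass(self, material: HyperelasticMaterial, thickness: float) -> np.ndarray:
        """Lumped node mass per unit depth (kg/m): rho_s * h * ds_node."""
        half = np.zeros(self.n_nodes)
        half[:-1] += self.ds / 2
        half[1:] += self.ds / 2
        return material.rho_s * thickness * half

    def tip_displacement(self) -> np.ndarray:
        return self.x[-1] - self.ref[-1]

    def copy(self) -> "LeafletState":
        return LeafletState(self.x.copy(), self.v.copy(), self.ref.copy(),
                            self.anchored.copy())


def leaflet_forces(state: LeafletState, material: HyperelasticMaterial,
                   thickness: float) -> np.ndarray:
    """Elastic nodal forces (N per unit depth): stretching + bending.

    Forces are the negative gradient of the discrete energy

        E = sum_seg  (EA ds / 2) (lambda - 1)^2
          + sum_int  (EI / (2 ds^3)) |x_{i+1} - 2 x_i + x_{i-1}|^2

    with EA = E*h and EI = E*h^3/12 per unit depth; zero in the reference
    configuration and invariant under rigid translation.
    """
    x, ds = state.x, state.ds
    EA = material.E * thickness
    EI = material.E * thickness ** 3 / 12.0

    seg = np.diff(x, axis=0)
    length = np.linalg.norm(seg, axis=1)
    if np.any(length <= 0):
        raise ValueError("coincident adjacent nodes")
    tangent = seg / length[:, None]
    tension = EA * (length / ds - 1.0)           # N per depth, + in tension
    f = np.zeros_like(x)
    f[:-1] += tension[:, None] * tangent
    f[1:] -= tension[:, None] * tangent

    if state.n_nodes >= 3:
        b = x[2:] - 2.0 * x[1:-1] + x[:-2]       # (n-2, 2)
        ds_mid = 0.5 * (ds[:-1] + ds[1:])
        w = (EI / ds_mid ** 3)[:, None] * b
        f[:-2] -= w
        f[1:-1] += 2.0 * w
        f[2:] -= w
    return f


def leaflet_energy(state: LeafletState, material: HyperelasticMaterial,
                   thickness: float) -> float:
    """Total mechanical energy (J per unit depth): kinetic + stretching +
    bending, consistent with the discrete forces of ``leaflet_forces``."""
    EA = material.E * thickness
    EI = material.E * thickness ** 3 / 12.0
    mass = state.node_mass(material, thickness)
    ke = 0.5 * float(np.sum(mass[:, None] * state.v ** 2))
    length = np.linalg.norm(np.diff(state.x, axis=0), axis=1)
    stretch = 0.5 * float(np.sum(EA * state.ds * (length / state.ds - 1.0) ** 2))
    b = state.x[2:] - 2.0 * state.x[1:-1] + state.x[:-2]
    ds_mid = 0.5 * (state.ds[:-1] + state.ds[1:])
    bend = 0.5 * float(np.sum(EI / ds_mid ** 3 * np.sum(b ** 2, axis=1)))
    return ke + stretch + bend


def stable_substep(state: LeafletState, material: HyperelasticMaterial,
                   thickness: float, safety: float = 0.35) -> float:
    """Explicit stability bound for the stiffest fiber mode.

    Exact highest frequencies of the linearized discrete chain:
    stretching 2 sqrt(EA / (rho h)) / ds, bending
    4 sqrt(EI / (rho h)) / ds^2; the sub-step is ``safety * 2 / omega_max``.
    """
    ds = float(state.ds.min())
    rho_h = material.rho_s * thickness
    EA = material.E * thickness
    EI = material.E * thickness ** 3 / 12.0
    om_stretch = 2.0 * np.sqrt(EA / rho_h) / ds
    om_bend = 4.0 * np.sqrt(EI / rho_h) / ds ** 2
    return safety * 2.0 / max(om_stretch, om_bend)


def advance_leaflets(state: LeafletState, material: HyperelasticMaterial,
                     thickness: float, external: np.ndarray, dt: float,
                     *, damping: float = 0.0, max_disp: float | None = None,
                     substep_safety: float = 0.3,
                     drag_gamma: np.ndarray | None = None,
                     drag_target: np.ndarray | None = None,
                     impulse_out: np.ndarray | None = None) -> LeafletState:
    """Advance one leaflet by ``dt`` under elastic + external forces.

    Velocity-Verlet sub-stepping below the elastic stability limit; elastic
    forces are recomputed every sub-step, the external force (N per depth
    per node) is held fixed over ``dt``.  An optional drag coupling
    ``drag_gamma * (drag_target - v)`` toward a frozen target velocity is
    evaluated at the current node velocity every sub-step (this keeps the
    fluid traction dissipative); its exact time-integrated impulse is
    accumulated into ``impulse_out`` so the caller can transfer the equal
    and opposite momentum to the fluid.  Anchored nodes do not move.
    Raises when any node travels more than ``max_disp`` in one call
    (instability guard).
    """
    new = state.copy()
    mass = new.node_mass(material, thickness)[:, None]
    free = ~new.anchored
    h = stable_substep(new, material, thickness, substep_safety)
    n_sub = max(1, int(np.ceil(dt / h)))
    h = dt / n_sub
    gam = None if drag_gamma is None else np.asarray(drag_gamma)[:, None]

    def kick(s: LeafletState, f_el: np.ndarray, tau: float) -> None:
        f = f_el
        if damping:
            f = f - damping * mass * s.v
        if gam is not None:
            drag = gam * (drag_target - s.v)
            f = f + drag
            if impulse_out is not None:
                # anchored nodes still exert their reaction on the fluid
                # (the anchor supplies the balancing constraint force)
                impulse_out[:] += tau * drag
        a = f / mass
        s.v[free] += tau * a[free]

    f_el = leaflet_forces(new, material, thickness) + external
    for _ in range(n_sub):
        kick(new, f_el, 0.5 * h)
        new.x[free] += h * new.v[free]
        f_el = leaflet_forces(new, material, thickness) + external
        kick(new, f_el, 0.5 * h)

    step = np.linalg.norm(new.x - state.x, axis=1).max()
    if max_disp is not None and step > max_disp:
        raise RuntimeError(
            f"leaflet moved {step:.3e} m in one step (> {max_disp:.3e} m); "
            "reduce the fluid time step")
    return new
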