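"""Wilcox-type k-omega closure supplying eddy viscosity to the flow core.

Transport equations (density rho, molecular viscosity mu):

    rho (dk/dt + u . grad k) = div[(mu + mu_T sigma*) grad k] + Pk - rho beta* omega k
    rho (dw/dt + u . grad w) = div[(mu + mu_T sigma ) grad w] + alpha w/k Pk - rho beta w^2

with mu_T = rho k / omega and production

    Pk = mu_T [ grad u : (grad u + grad u^T) - 2/3 (div u)^2 ] - 2/3 rho k div u.

Closure coefficients: alpha = 13/25, beta = beta0 f_beta with beta0 = 13/125,
beta* = beta0* f_beta* with beta0* = 9/100, sigma = sigma* = 1/2.  The
vortex-stretching function f_beta (chi_omega built from Omega_ij Omega_jk S_ki)
is identically 1 in strict 2D flow and is retained only for completeness;
f_beta* is the printed piecewise function of chi_k = grad k . grad omega / omega^3.

Walls are treated by low-Re direct integration: k = 0 at solid cells and the
near-wall omega asymptote omega_wall = 6 mu / (rho beta0 d^2) with d half a
cell.  Positivity (k >= 0, omega >= omega_min) is enforced by clipping;
clip counts are reported for logging.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "KOmegaCoefficients",
    "TurbulenceState",
    "eddy_viscosity",
    "production",
    "f_beta_star",
    "advance_k_omega",
    "inlet_k_omega",
    "homogeneous_decay",
]


@dataclass(frozen=True)
class KOmegaCoefficients:
    alpha: float = 13.0 / 25.0
    beta0: float = 13.0 / 125.0
    beta0_star: float = 9.0 / 100.0
    sigma: float = 0.5
    sigma_star: float = 0.5
    omega_min: float = 1e-6

    def __post_init__(self) -> None:
        vals = (self.alpha, self.beta0, self.beta0_star, self.sigma,
                self.sigma_star, self.omega_min)
        if any(v <= 0 for v in vals):
            raise ValueError("all k-omega coefficients must be positive")
        if self.sigma != self.sigma_star:
            raise ValueError("this closure uses sigma = sigma*")


@dataclass
class TurbulenceState:
    k: np.ndarray       # m^2/s^2
    omega: np.ndarray   # 1/s
    clip_events: int = 0

    def copy(self) -> "TurbulenceState":
        return TurbulenceState(self.k.copy(), self.omega.copy(), self.clip_events)


def eddy_viscosity(rho: float, k: np.ndarray, omega: np.ndarray,
                   omega_min: float = 1e-6) -> np.ndarray:
    """mu_T = rho k / omega, with omega floored at omega_min (Pa s)."""
    k = np.maximum(np.asarray(k, dtype=float), 0.0)
    om = np.maximum(np.asarray(omega, dtype=float), omega_min)
    return rho * k / om


def production(grad_u: tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray],
               mu_t: np.ndarray, rho: float, k: np.ndarray) -> np.ndarray:
    """Turbulence production Pk from the velocity-gradient components
    (du/dx, du/dy, dv/dx, dv/dy) at cell centers.

    For discretely divergence-free fields the div-u terms contribute only
    round-off.
    """
    dudx, dudy, dvdx, dvdy = grad_u
    div = dudx + dvdy
    double_inner = 2.0 * (dudx ** 2 + dvdy ** 2) + (dudy + dvdx) ** 2
    return mu_t * (double_inner - (2.0 / 3.0) * div ** 2) - (2.0 / 3.0) * rho * k * div


def f_beta_star(chi_k: np.ndarray) -> np.ndarray:
    """Piecewise cross-diffusion function: 1 for chi_k <= 0, else
    (1 + 680 chi_k^2) / (1 + 400 chi_k^2)."""
    chi_k = np.asarray(chi_k, dtype=float)
    ratio = (1.0 + 680.0 * chi_k ** 2) / (1.0 + 400.0 * chi_k ** 2)
    return np.where(chi_k > 0, ratio, 1.0)


def _center_gradients(q: np.ndarray, dx: float, dy: float,
                      fluid: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """One-sided-at-boundary central gradients of a cell-centered field,
    not reaching across solid cells."""
    qe = np.where(fluid, q, 0.0)
    gx = np.zeros_like(q)
    gy = np.zeros_like(q)
    fx = fluid
    # x
    left = np.zeros_like(fx); left[:, 1:] = fx[:, :-1]
    right = np.zeros_like(fx); right[:, :-1] = fx[:, 1:]
    qm = np.zeros_like(q); qm[:, 1:] = qe[:, :-1]
    qp = np.zeros_like(q); qp[:, :-1] = qe[:, 1:]
    gx = np.where(left & right, (qp - qm) / (2 * dx),
                  np.where(right, (qp - qe) / dx,
                           np.where(left, (qe - qm) / dx, 0.0)))
    # y
    down = np.zeros_like(fx); down[1:, :] = fx[:-1, :]
    up = np.zeros_like(fx); up[:-1, :] = fx[1:, :]
    qm = np.zeros_like(q); qm[1:, :] = qe[:-1, :]
    qp = np.zeros_like(q); qp[:-1, :] = qe[1:, :]
    gy = np.where(down & up, (qp - qm) / (2 * dy),
                  np.where(up, (qp - qe) / dy,
                           np.where(down, (qe - qm) / dy, 0.0)))
    gx[~fluid] = 0.0
    gy[~fluid] = 0.0
    return gx, gy


def _diffuse(q: np.ndarray, coef: np.ndarray, dx: float, dy: float,
             fluid: np.ndarray, wall_value: np.ndarray | float | None
             ) -> np.ndarray:
    """div(coef grad q) with face-averaged coefficients; no-flux across
    domain edges and, when ``wall_value`` is None, across solid faces;
    otherwise Dirichlet ``wall_value`` at the solid neighbor center."""
    out = np.zeros_like(q)
    for axis, h in ((1, dx), (0, dy)):
        qm = np.roll(q, 1, axis=axis); qp = np.roll(q, -1, axis=axis)
        fm = np.roll(fluid, 1, axis=axis); fp = np.roll(fluid, -1, axis=axis)
        cm = np.roll(coef, 1, axis=axis); cp = np.roll(coef, -1, axis=axis)
        edge = [slice(None)] * 2
        e0 = list(edge); e0[axis] = 0
        e1 = list(edge); e1[axis] = -1
        fm[tuple(e0)] = False
        fp[tuple(e1)] = False
        if wall_value is not None:
            qm = np.where(fm, qm, wall_value)
            qp = np.where(fp, qp, wall_value)
            inner_m = np.ones_like(fm); inner_m[tuple(e0)] = False
            inner_p = np.ones_like(fp); inner_p[tuple(e1)] = False
            fm, fp = inner_m, inner_p
            cm = np.where(fm, cm, coef)
            cp = np.where(fp, cp, coef)
        flux_m = np.where(fm, 0.5 * (coef + cm) * (q - qm) / h, 0.0)
        flux_p = np.where(fp, 0.5 * (coef + cp) * (qp - q) / h, 0.0)
        out += (flux_p - flux_m) / h
    out[~fluid] = 0.0
    return out


def _up_grad(q: np.ndarray, h: float, axis: int, fluid: np.ndarray,
             back: bool) -> np.ndarray:
    """One-sided gradient along an axis, zero where the upwind neighbor is
    solid or outside the domain."""
    shift = 1 if back else -1
    qn = np.roll(q, shift, axis=axis)
    fn = np.roll(fluid, shift, axis=axis)
    edge = [slice(None)] * q.ndim
    edge[axis] = slice(0, 1) if back else slice(-1, None)
    fn[tuple(edge)] = False
    grad = np.where(fn & fluid, (q - qn) / h if back else (qn - q) / h, 0.0)
    return grad


def omega_wall_value(mu: float, rho: float, d: float,
                     coeffs: KOmegaCoefficients) -> float:
    """Near-wall specific-dissipation asymptote 6 mu / (rho beta0 d^2)."""
    return 6.0 * mu / (rho * coeffs.beta0 * d ** 2)


def advance_k_omega(turb: TurbulenceState, uc: np.ndarray, vc: np.ndarray,
                    grad_u: tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray],
                    dt: float, dx: float, dy: float, fluid: np.ndarray,
                    rho: float, mu: float,
                    coeffs: KOmegaCoefficients = KOmegaCoefficients(),
                    inlet_bc: tuple[float, float] | None = None,
                    wall_bc: bool = False,
                    production_limit: float = 10.0) -> TurbulenceState:
    """Advance (k, omega) by one step.

    Advection (first-order upwind), diffusion and (limited) production are
    explicit; the destruction terms are Patankar-implicit, which keeps both
    fields positive and integrates the homogeneous omega decay exactly.
    Production is capped at ``production_limit * rho * beta0* k omega``
    (standard limiter, prevents startup blow-up in impulsively started
    shear layers).  ``uc``, ``vc`` and the gradient components are
    cell-centered; ``fluid`` flags open cells.  ``inlet_bc = (k_in,
    omega_in)`` pins the first fluid column; ``wall_bc`` applies k = 0 /
    omega = omega_wall at solid cells.
    """
    om_wall = omega_wall_value(mu, rho, dy / 2.0, coeffs)

    k0, om0 = turb.k, turb.omega
    om_f = np.maximum(om0, coeffs.omega_min)
    mu_t = eddy_viscosity(rho, k0, om_f, coeffs.omega_min)
    pk = production(grad_u, mu_t, rho, k0)
    pk = np.minimum(pk, production_limit * rho * coeffs.beta0_star * k0 * om_f)
    gkx, gky = _center_gradients(k0, dx, dy, fluid)
    gox, goy = _center_gradients(om0, dx, dy, fluid)
    chi_k = (gkx * gox + gky * goy) / om_f ** 3
    beta_star = coeffs.beta0_star * f_beta_star(chi_k)
    beta = coeffs.beta0  # f_beta = 1: vortex stretching vanishes in 2D

    # upwind advection
    adv_k = (np.maximum(uc, 0) * _up_grad(k0, dx, 1, fluid, back=True)
             + np.minimum(uc, 0) * _up_grad(k0, dx, 1, fluid, back=False)
             + np.maximum(vc, 0) * _up_grad(k0, dy, 0, fluid, back=True)
             + np.minimum(vc, 0) * _up_grad(k0, dy, 0, fluid, back=False))
    adv_om = (np.maximum(uc, 0) * _up_grad(om0, dx, 1, fluid, back=True)
              + np.minimum(uc, 0) * _up_grad(om0, dx, 1, fluid, back=False)
              + np.maximum(vc, 0) * _up_grad(om0, dy, 0, fluid, back=True)
              + np.minimum(vc, 0) * _up_grad(om0, dy, 0, fluid, back=False))

    k_star = k0 + dt * (-adv_k + _diffuse(
        k0, mu + mu_t * coeffs.sigma_star, dx, dy, fluid,
        0.0 if wall_bc else None) / rho + pk / rho)
    om_star = om0 + dt * (-adv_om + _diffuse(
        om0, mu + mu_t * coeffs.sigma, dx, dy, fluid,
        om_wall if wall_bc else None) / rho
        + coeffs.alpha * om_f / np.maximum(k0, 1e-30) * pk / rho)
    # implicit sinks
    om_new = om_star / (1.0 + dt * beta * om_f)
    k_new = k_star / (1.0 + dt * beta_star * np.maximum(om_new, coeffs.omega_min))
    k_new = np.where(fluid, k_new, k0)
    om_new = np.where(fluid, om_new, om0)

    if not (np.all(np.isfinite(k_new)) and np.all(np.isfinite(om_new))):
        raise FloatingPointError("non-finite k or omega")

    clips = int(np.sum(k_new < 0)) + int(np.sum(om_new < coeffs.omega_min))
    k_new = np.maximum(k_new, 0.0)
    om_new = np.maximum(om_new, coeffs.omega_min)
    if wall_bc:
        k_new[~fluid] = 0.0
        om_new[~fluid] = om_wall
    if inlet_bc is not None:
        first = fluid[:, 0]
        k_new[first, 0], om_new[first, 0] = inlet_bc
    return TurbulenceState(k_new, om_new, turb.clip_events + clips)


def inlet_k_omega(U_inlet: float, intensity: float = 0.05,
                  length_scale: float = 0.001,
                  C: float = 0.09 ** 0.25) -> tuple[float, float]:
    """Inlet boundary values from turbulence intensity and length scale:
    k = 1.5 (I U)^2, omega = sqrt(k) / (C l) with C = C_mu^{1/4} = 0.09^0.25."""
    if intensity <= 0:
        raise ValueError("turbulence intensity must be positive")
    k = 1.5 * (intensity * U_inlet) ** 2
    omega = np.sqrt(k) / (C * length_scale)
    return float(k), float(omega)


def homogeneous_decay(k0: float, om0: float, t: np.ndarray,
                      coeffs: KOmegaCoefficients = KOmegaCoefficients()
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Closed-form homogeneous decay of the sink terms:
    omega(t) = om0 / (1 + beta0 om0 t),
    k(t) = k0 (1 + beta0 om0 t)^(-beta0*/beta0)."""
    t = np.asarray(t, dtype=float)
    g = 1.0 + coeffs.beta0 * om0 * t
    return k0 * g ** (-coeffs.beta0_star / coeffs.beta0), om0 / g
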