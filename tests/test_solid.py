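"""Neo-Hookean constitutive layer and discrete leaflet dynamics."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from ijvflow.solid import (HyperelasticMaterial, InvertedElementError,
                           LeafletState, advance_leaflets, cauchy_stress,
                           green_lagrange_strain, lame_from_modulus,
                           leaflet_energy, leaflet_forces, pk2_stress,
                           stable_substep, strain_energy)

MAT = HyperelasticMaterial()  # E = 2.6 MPa, nu = 0.3, rho_s = 1200


def small_F(seed, scale=1e-3):
    rng = np.random.default_rng(seed)
    return np.eye(2) + scale * rng.normal(size=(2, 2))


# --- Lame conversion -------------------------------------------------------

def test_lame_values_of_study_material():
    mu, lam = lame_from_modulus(2.6e6, 0.3)
    assert mu == pytest.approx(1.0e6, rel=1e-12)
    assert lam == pytest.approx(1.5e6, rel=1e-12)


def test_lame_zero_poisson():
    mu, lam = lame_from_modulus(1.0e6, 0.0)
    assert mu == 0.5e6 and lam == 0.0


@given(st.floats(1e3, 1e9), st.floats(0.0, 0.49))
def test_lame_roundtrip_identity(E, nu):
    mu, lam = lame_from_modulus(E, nu)
    E_back = mu * (3 * lam + 2 * mu) / (lam + mu)
    assert E_back == pytest.approx(E, rel=1e-12)


def test_lame_rejects_incompressible():
    with pytest.raises(ValueError):
        lame_from_modulus(1e6, 0.5)
    with pytest.raises(ValueError):
        lame_from_modulus(-1.0, 0.3)


# --- strain energy / stresses ----------------------------------------------

def test_energy_zero_at_reference():
    assert strain_energy(np.eye(2), MAT) == 0.0
    assert np.allclose(pk2_stress(np.eye(2), MAT), 0.0)
    assert np.allclose(cauchy_stress(np.eye(2), pk2_stress(np.eye(2), MAT)), 0.0)


def test_energy_simple_shear_small_strain():
    gam = 1e-3
    F = np.array([[1.0, gam], [0.0, 1.0]])
    Ws = strain_energy(F, MAT)
    assert Ws == pytest.approx(MAT.mu_s * gam ** 2 / 2, rel=1e-3)


def test_energy_dilation_against_arbitrary_precision():
    """Uniform dilation J = 1.1: compare against an independent sympy
    evaluation of the energy density formula."""
    import sympy as sp
    c = np.sqrt(1.1)
    F = c * np.eye(2)
    Ws = strain_energy(F, MAT)
    mu, lam = sp.Rational(10 ** 6), sp.Rational(3, 2) * 10 ** 6
    J = sp.Rational(11, 10)
    I1 = 2 * J + 1  # two in-plane stretches c^2 = J each, out-of-plane 1
    expected = sp.Rational(1, 2) * mu * (I1 - 3) - mu * sp.log(J) \
        + sp.Rational(1, 2) * lam * sp.log(J) ** 2
    assert Ws == pytest.approx(float(expected.evalf(30)), rel=1e-12)


def test_inverted_element_rejected():
    F = np.array([[-1.0, 0.0], [0.0, 1.0]])
    for fn in (strain_energy, pk2_stress):
        with pytest.raises(InvertedElementError):
            fn(F, MAT)


@pytest.mark.parametrize("seed", range(5))
def test_pk2_matches_energy_derivative(seed):
    """S : dE equals the directional derivative of Ws for random small
    perturbations (central differences)."""
    F = small_F(seed, 2e-2)
    S = pk2_stress(F, MAT)
    rng = np.random.default_rng(100 + seed)
    h = 1e-6
    for _ in range(3):
        dF = rng.normal(size=(2, 2))
        num = (strain_energy(F + h * dF, MAT)
               - strain_energy(F - h * dF, MAT)) / (2 * h)
        dE = 0.5 * (dF.T @ F + F.T @ dF)
        assert num == pytest.approx(float(np.sum(S * dE)), rel=1e-6)


@pytest.mark.parametrize("seed", range(5))
def test_pk2_symmetric(seed):
    S = pk2_stress(small_F(seed, 0.05), MAT)
    assert np.allclose(S, S.T, atol=1e-9 * max(1.0, np.abs(S).max()))


@pytest.mark.parametrize("seed", range(5))
def test_cauchy_objectivity(seed):
    """sigma(R F) = R sigma(F) R^T for rotations R."""
    F = small_F(seed, 0.05)
    rng = np.random.default_rng(200 + seed)
    th = rng.uniform(0, 2 * np.pi)
    R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    sig = cauchy_stress(F, pk2_stress(F, MAT))
    sig_rot = cauchy_stress(R @ F, pk2_stress(R @ F, MAT))
    assert np.allclose(sig_rot, R @ sig @ R.T,
                       atol=1e-12 * max(1.0, np.abs(sig).max()))


def test_small_strain_limit_uniaxial():
    """Uniaxial (laterally constrained) strain: sigma_11 -> (lam + 2 mu) e,
    with error decreasing as the strain shrinks."""
    errs = []
    for e in (1e-3, 1e-4, 1e-5):
        F = np.diag([1.0 + e, 1.0])
        sig = cauchy_stress(F, pk2_stress(F, MAT))
        lin = (MAT.lam_s + 2 * MAT.mu_s) * e
        errs.append(abs(sig[0, 0] - lin) / lin)
    assert errs[1] < 0.01
    assert errs[0] > errs[1] > errs[2]


def test_green_lagrange_strain():
    F = small_F(3, 0.05)
    eps = green_lagrange_strain(F)
    assert np.allclose(eps, 0.5 * (F.T @ F - np.eye(2)))


# --- leaflet fiber ----------------------------------------------------------

def straight_leaflet(n=10, length=0.01, angle=0.6, anchored_root=True):
    s = np.linspace(0, length, n)
    ref = np.column_stack([s * np.cos(angle), s * np.sin(angle)])
    anchored = np.zeros(n, dtype=bool)
    if anchored_root:
        anchored[:2] = True
    return LeafletState.from_reference(ref, anchored)


def test_forces_zero_in_reference_and_translation():
    leaf = straight_leaflet()
    f = leaflet_forces(leaf, MAT, 0.001)
    assert np.allclose(f, 0.0, atol=1e-12)
    leaf.x += np.array([0.003, -0.002])
    f = leaflet_forces(leaf, MAT, 0.001)
    assert np.allclose(f, 0.0, atol=1e-9)


def test_uniform_stretch_tension():
    """Uniform stretch lambda = 1.01: end-node axial force within 1 % of
    the linear-spring value E h (lambda - 1) per unit depth."""
    leaf = straight_leaflet(angle=0.0)
    lam = 1.01
    leaf.x = leaf.ref * lam
    h = 0.001
    f = leaflet_forces(leaf, MAT, h)
    expected = MAT.E * h * (lam - 1)
    assert -f[-1, 0] == pytest.approx(expected, rel=0.01)
    assert abs(f[-1, 1]) < 1e-12 * expected


def test_mirror_symmetry_of_forces():
    leaf = straight_leaflet()
    rng = np.random.default_rng(4)
    leaf.x = leaf.ref + 1e-4 * rng.normal(size=leaf.ref.shape)
    mirrored = leaf.copy()
    mirrored.x[:, 1] *= -1
    mirrored.ref[:, 1] *= -1
    f = leaflet_forces(leaf, MAT, 0.001)
    fm = leaflet_forces(mirrored, MAT, 0.001)
    assert np.array_equal(fm[:, 0], f[:, 0])
    assert np.array_equal(fm[:, 1], -f[:, 1])


def test_coincident_nodes_rejected():
    leaf = straight_leaflet()
    leaf.x[3] = leaf.x[2]
    with pytest.raises(ValueError, match="coincident"):
        leaflet_forces(leaf, MAT, 0.001)


def test_advance_rest_state_unchanged():
    leaf = straight_leaflet()
    new = advance_leaflets(leaf, MAT, 0.001, np.zeros_like(leaf.x), 1e-4)
    # unchanged up to round-off in the discrete reference curvature
    assert np.allclose(new.x, leaf.x, atol=1e-15)
    assert np.abs(new.v).max() < 1e-10


def test_free_fiber_rigid_acceleration():
    """A fully free fiber under a uniform force density accelerates rigidly
    at a = f / (rho_s h)."""
    leaf = straight_leaflet(anchored_root=False)
    h = 0.001
    q = 2.0  # N/m^2 per unit depth
    mass = leaf.node_mass(MAT, h)
    ext = np.zeros_like(leaf.x)
    ext[:, 1] = q * mass / (MAT.rho_s * h)  # uniform force density
    dt = 1e-4
    new = advance_leaflets(leaf, MAT, h, ext, dt)
    a_expected = q / (MAT.rho_s * h)
    assert np.allclose(new.v[:, 1], a_expected * dt, rtol=1e-6)
    # no elastic deformation develops
    assert np.ptp(new.v[:, 1]) < 1e-9 * a_expected * dt


def test_anchored_nodes_never_move():
    leaf = straight_leaflet()
    ext = np.zeros_like(leaf.x)
    ext[:, 1] = 5.0
    new = advance_leaflets(leaf, MAT, 0.001, ext, 5e-4)
    assert np.array_equal(new.x[:2], leaf.x[:2])
    assert np.all(new.v[:2] == 0.0)
    assert not np.array_equal(new.x[2:], leaf.x[2:])


def test_cantilever_frequency_euler_bernoulli():
    """Small-amplitude first-mode oscillation frequency of a clamped fiber
    within 5 % of the Euler-Bernoulli value
    omega_1 = (1.875)^2 sqrt(EI / (m L^4))."""
    soft = HyperelasticMaterial(E=1e4, nu=0.3, rho_s=1200.0)
    n, h = 33, 0.01
    L = 0.1
    leaf = straight_leaflet(n=n, length=L, angle=0.0)
    ds = leaf.ds[0]
    L_eff = L - ds  # clamp sits at the second node
    EI = soft.E * h ** 3 / 12
    m = soft.rho_s * h
    om1 = 1.875104 ** 2 * np.sqrt(EI / (m * L_eff ** 4))
    period = 2 * np.pi / om1

    # deflect with the static tip-load shape (dominantly first mode), release
    s = np.maximum(np.linalg.norm(leaf.ref, axis=1) - ds, 0.0)
    shape = (3 * L_eff * s ** 2 - s ** 3) / (2 * L_eff ** 3)
    leaf.x[:, 1] += 1e-4 * shape
    tip_y = []
    dt = period / 400
    state = leaf
    for _ in range(1000):
        state = advance_leaflets(state, soft, h, np.zeros_like(leaf.x), dt)
        tip_y.append(state.x[-1, 1])
    tip = np.asarray(tip_y) - np.mean(tip_y)
    # measure the period from zero crossings
    sign = np.sign(tip)
    crossings = np.nonzero(np.diff(sign) != 0)[0]
    periods = 2 * np.diff(crossings) * dt
    measured = periods.mean()
    assert measured == pytest.approx(period, rel=0.05)


def test_energy_drift_in_vacuum():
    """Oscillating leaflet in vacuum: total mechanical energy drifts by
    less than 1 % over 10^3 sub-steps at the default sub-step."""
    leaf = straight_leaflet(n=12, length=0.01, angle=0.0)
    leaf.x[:, 1] += 2e-4 * (np.linalg.norm(leaf.ref, axis=1) / 0.01) ** 2
    h = 0.001
    sub = stable_substep(leaf, MAT, h)
    e0 = leaflet_energy(leaf, MAT, h)
    state = advance_leaflets(leaf, MAT, h, np.zeros_like(leaf.x), 1000 * sub)
    e1 = leaflet_energy(state, MAT, h)
    assert abs(e1 - e0) / e0 < 0.01
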