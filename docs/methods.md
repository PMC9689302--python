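# Methods

## Problem and model

`ijvflow` simulates blood flow through an idealized two-dimensional
internal jugular vein (IJV): a channel of length L = 200 mm and width
D = 15 mm with a nozzle-like stenosis near the inlet and a flexible
two-leaflet venous valve downstream.  The stenosis occludes a fraction
f of the width, leaving an open throat gap d1 = (1 − f)·D; the four
standard cases are f = 0 (A), 0.30 (B), 0.60 (C) and 0.75 (D).  The valve
leaflets are anchored on opposite walls and meet near the centerline with
a tip gap d2 = 3 mm.

Blood is Newtonian with ρ = 1055 kg·m⁻³ and μ = 2.78 × 10⁻³ Pa·s
(values for blood at 37 °C).  The inlet carries a pulsatile plug velocity

    U_inlet(t) = 8 sin(t·π/6) + 12   [cm/s],

i.e. 12 cm/s initially, 20 cm/s at t = 3 s, back to 12 cm/s at t = 6 s,
mimicking carotid-pulsation/respiratory modulation of jugular flow
(16 ± 4 cm/s).  The outlet holds static pressure p = 0; all walls are
no-slip.  With these values the inlet Reynolds number ρUD/μ is about
900–1100 over the cycle; the package computes and logs Re for each run.
(The flow regime is therefore transitional at best; a Stokes-flow mode —
inertial terms dropped — is available as a configuration switch, and the
k-ω closure below reproduces the Reynolds-averaged configuration.  The
solver retains the inertial terms by default.)

## Fluid solver

Incompressible momentum/continuity are discretized on a staggered (MAC)
Cartesian grid with the solid geometry (walls, stenosis) rasterized to a
cell mask, and integrated by an explicit fractional-step scheme:

* advection: second-order upwind-biased differences, falling back to
  first order adjacent to solids/boundaries;
* diffusion: explicit divergence of the full deviatoric stress
  (μ + μ_T)(∇u + ∇uᵀ), which remains correct for a spatially varying
  eddy viscosity;
* projection: a pressure Poisson solve with a direct sparse factorization
  (cached per grid/mask), Neumann at walls and inlet, Dirichlet p = 0 at
  the outlet.  The post-step discrete divergence is at round-off
  (≲ 10⁻¹² relative), far below the 10⁻⁸ contract.

Walls cut the grid midway between velocity samples; the no-slip
condition enters the shear stress through quadratic ghost values
(u_ghost = −2u₁ + u₂/3), which makes a parabolic profile discretely
exact at the wall.  With a straight channel at Re = 8 the computed exit
profile matches plane Poiseuille flow to 0.05 % in L2 and gives
max/mean = 1.4979 on a 64 × 32 grid.

Time stepping is bounded by the advective CFL (default number 0.5), by
the explicit-diffusion limit 0.12·ρh²/μ_eff (the 0.12 includes the
factor-2 normal-stress terms and the stiffer wall ghost; 0.25 is
marginally unstable), and by a configured dt_max.

## k-ω closure

An optional Wilcox-type k-ω model supplies μ_T = ρk/ω to the stress.
Closure coefficients: α = 13/25, β₀ = 13/125, β₀* = 9/100,
σ = σ* = 1/2.  The cross-diffusion function f_β* is the standard
piecewise expression in χ_k = (∇k·∇ω)/ω³; the vortex-stretching
function f_β is identically 1 in strict 2D (Ω_ij Ω_jk S_ki ≡ 0) and is
retained only for completeness.  Transport uses first-order upwind
advection and explicit variable-coefficient diffusion; production is
capped at 10·ρβ₀*kω (the standard limiter — without it the impulsive
start of a stenotic jet drives a k → μ_T → P_k feedback that diverges in
a few steps) and the destruction terms are Patankar-implicit, which
preserves positivity and integrates the homogeneous ω decay exactly;
k ≥ 0 and ω ≥ ω_min are additionally enforced by clipping (events
counted and logged).  Walls use low-Re direct integration with
k = 0 and the near-wall asymptote ω_wall = 6μ/(ρβ₀d²), d = half a cell.
Inlet values follow k = 1.5(I·U)², ω = √k/(C·l) with intensity I = 5 %,
l = 0.07·D and C = C_μ^{1/4} = 0.09^{1/4}; the inlet intensity is a
package parameter (the momentum equations use I for the identity tensor;
no printed inlet turbulence level exists).

In homogeneous conditions the discrete sink terms reproduce the closed
form ω(t) = ω₀/(1+β₀ω₀t), k(t) = k₀(1+β₀ω₀t)^(−β₀*/β₀) to better than
0.1 % at dt = 10⁻³ s over 1 s.

## Valve model

The leaflet material is compressible neo-Hookean with
W_s = (μ_s/2)(I₁ − 3) − μ_s ln J + (λ_s/2)(ln J)², in a plane-strain
embedding (out-of-plane stretch 1, so I₁ = tr C + 1).  Defaults are
E = 2.6 MPa, ν = 0.3 (hence μ_s = 1.0 MPa, λ_s = 1.5 MPa) and
ρ_s = 1200 kg·m⁻³.  The tensorial layer (energy, second Piola–Kirchhoff
stress S = μ_s(I − C⁻¹) + λ_s ln J·C⁻¹, Cauchy stress σ = J⁻¹FSFᵀ) is
validated pointwise: S equals the numerical derivative of W_s, σ is
objective under rotations, and the small-strain limit recovers
plane-strain linear elasticity with error decreasing as strain → 0.

Dynamically each leaflet is a thin structure and is reduced to a 1D
inertial fiber whose stretching stiffness E·h and bending stiffness
E·h³/12 per unit depth (h = 1 mm thickness) are the small-strain limits
of the same material.  Discrete forces are the exact negative gradient
of the stretching + bending energy, so they vanish in the reference
configuration and under rigid translation.  Nodes carry lumped mass
ρ_s·h·ds and are integrated with velocity Verlet, sub-stepped below the
exact linearized stability limits (2√(EA/ρh)/ds for stretching,
4√(EI/ρh)/ds² for bending, safety 0.35).  The wall anchor is a clamped
root — the first two nodes are held fixed (U_solid = 0) — which gives
the leaflet a defined rest orientation.  Small-amplitude oscillations
match the Euler–Bernoulli cantilever frequency within 5 %, and total
mechanical energy drifts by < 1 % over 10³ sub-steps.

With these material values the leaflets are stiff at venous loads: tip
excursions in the simulations are sub-millimeter.  The asymmetry of the
tip excursions, not their magnitude, is the quantity of interest.

## Fluid–structure coupling

Coupling is immersed-boundary on the fixed grid, with the classical
4-point regularized delta kernel.  Interpolation is exact for affine
velocity fields; spreading is its exact adjoint (inner-product identity
holds to 10⁻¹⁰), so total momentum exchanged balances to round-off.

Each coupled step: (1) interpolate the fluid velocity to the leaflet
nodes; (2) advance the leaflet under its elastic forces plus a drag
penalty traction γ(U_interp − V_node) toward that frozen fluid velocity,
with γ = m_node/dt, evaluated at the current node velocity every solid
sub-step; (3) spread the reaction of the exact time-integrated traction
impulse to the staggered body force and advance the fluid.  Evaluating
the drag against the evolving node velocity (rather than freezing the
traction) is what keeps the exchange dissipative; a frozen traction
pumps the stiff fiber modes resonantly and is unstable at any usable
time step.  Loose coupling (one pass per step) is adequate at the mild
density ratio ρ_s/ρ ≈ 1.14.  A short-range penalty keeps nodes one cell
away from walls and from the opposite leaflet, preventing kernel-overlap
artifacts if the valve closes.

## Case orchestration and presets

* `study` preset: 400 × 30 lumen cells (0.5 mm), 6 s, k-ω enabled — the
  full-scale study configuration.
* `desk` preset: 200 × 16 lumen cells, 3 s — a reduced configuration
  used by the test suite and the property checks; every qualitative
  phenomenon of interest (stenotic jet, separation, asymmetric
  instability, leaflet distortion) already emerges at this size, and one
  case runs in a few minutes on one CPU.  Desk runs use 12 nodes per
  leaflet so the fiber spacing matches the cell size.

Runs are deterministic given their configuration.  The only seeded
element is an optional inlet perturbation: a fixed, smooth,
generically asymmetric distortion of the plug profile (three low-order
transverse sine modes, normalized, amplitude 0.5 % in the comparison
runs, off by default).  Symmetric cases would otherwise break symmetry
only through round-off at an unpredictable time; the controlled
perturbation makes the jet instability of the severe-stenosis cases
trigger reproducibly and identically across cases.

## Disturbance metrics

The study's findings are reported visually; the package quantifies them
as follows (all definitions configurable):

* **Max-velocity profile**: per-cross-section maximum speed vs x.
* **Reverse-flow area**: total area with axial velocity < −ε_rev,
  ε_rev = 10⁻³ × the instantaneous maximum speed, restricted to the
  downstream-of-stenosis region of interest x ∈ [x_s + l_s/2, anchor_x]
  (between throat exit and valve anchor, isolating stenosis effects from
  the valve wake); connected recirculation regions are labeled.
* **Asymmetry index**: Σ|q − M(q)| / Σ(|q| + |M(q)|) over lumen cells
  and both velocity components, M the mirror about y = D/2 (the
  transverse component changes sign); 0 for symmetric fields, 1 for
  purely antisymmetric ones, scale-invariant.  Reported both over the
  whole field and restricted to the region upstream of the valve anchor:
  every case sheds an (asymmetric) valve wake, so the upstream
  restriction is what separates stenosis-driven disturbance — which
  fills the whole course in the severe cases — from the common wake.
* **Centerline offset**: lateral position of the cross-section speed
  maximum minus D/2, with parabolic sub-cell refinement.
* **Leaflet asymmetry**: | |d_tip,upper| − |d_tip,lower| |.
* **Post-throat dip**: (throat peak − profile minimum over the
  downstream region) / throat peak.

## Geometry choices where the layout is under-determined

The source geometry fixes L, D, d1 and d2 but not the stenosis shape or
the valve dimensions.  Defaults: bilateral step contraction ("rapid
contraction"), length l_s = 5 mm centered at x_s = 20 mm (a cosine bump
and a one-sided variant are config options); valve anchors at
x = 110 mm, leaflet length 10 mm, thickness 1 mm, 32 nodes per leaflet
(12 at desk scale).  Whether the stenosis is one- or two-sided is not
derivable from the source figures; the bilateral form preserves the
mirror symmetry that makes the asymmetry metrics meaningful.

## Numerical choices

* Pressure solve: direct sparse LU, residual at round-off.
* Advective CFL number 0.5; explicit-diffusion safety 0.12; solid
  sub-step safety 0.35.
* Reverse-flow threshold 10⁻³·U_max; mirror-based asymmetry index — both
  package definitions, exposed in config.
* Degenerate inputs rejected with errors: f ≥ 1, stenosis overlapping
  the valve, a throat resolved by fewer than 4 cells, d2 ≥ D, inverted
  deformation gradients, coincident fiber nodes, CFL violations (error
  names the admissible dt), non-finite fields (abort with diagnostics).

## What the synthetic cases do and do not emulate

The generator reproduces the idealized 2D channel geometry of the study:
parametric stenosis, symmetric two-leaflet valve, pulsatile plug inlet.
It does not emulate patient morphology, vessel compliance, 3D or
axisymmetric effects, non-Newtonian rheology, or the paired-vein /
vertebral-plexus network; passing tests demonstrate the mechanism
(stenotic jet → separation → asymmetric vortices → leaflet distortion)
in the idealized setting, not clinical magnitudes.

## Known limitations

* At desk resolution the severe-stenosis jet instability grows from the
  0.5 % inlet perturbation with a finite transient; the 60 % case is
  still transitioning at t = 3 s while the 75 % case has saturated.
* The staircase mask is first-order at the stenosis corners.
* The fiber reduction of the leaflet ignores through-thickness stress
  variation; the full tensorial constitutive model is exercised
  pointwise, not as a 2D solid mesh.
* Loose coupling with a penalty traction enforces the no-slip condition
  on the leaflet only approximately (the leaflet is porous to a residual
  slip velocity of order the penalty relaxation).
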