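# Methods

## Problem and scope

The package models one compartment of a flat-on-flat total knee
replacement as a transient, mixed-lubrication elastohydrodynamic (EHL)
line contact. The femoral anterior–posterior radius R_f and the tibial
radius R_t reduce to an equivalent radius R = R_f·R_t/(R_f+R_t); both
bodies' elasticity condenses into a single equivalent body with

    E  = [E_f² E_t (1+ν_f²)² + E_t² E_f (1+ν_t²)²] / [E_f(1+ν_t) + E_t(1+ν_f)]²
    ν  = [E_f ν_t (1+ν_t) + E_t ν_f (1+ν_f)] / [E_f(1+ν_t) + E_t(1+ν_f)]

implemented exactly in this printed form rather than the more common
reduced-modulus convention. The Hertzian reference half-width
a_H = √(4 w R/(π E_ps)) and peak pressure p_H = 2w/(π a_H) use the
plane-strain modulus of the *equivalent body*, E_ps = E/(1−ν²), so the
normalisation is consistent with the elasticity model that produces the
deflections. The reference load is taken at the phase of maximum
compartment load (configurable).

Out of model scope by construction: musculoskeletal simulation, thermal,
piezo-viscous and shear-thinning effects, tibial rotation,
medial–lateral curvature, and wear-geometry evolution.

## Defaults and their provenance

| parameter | default | note |
|---|---|---|
| R_f, R_t | 38, 58 mm | implant geometry (AP direction) |
| l (med/lat) | 28.3 / 27.3 mm | contact lengths |
| E_f, ν_f | 240 GPa, 0.29 | CoCr femoral component |
| E_t, ν_t | 660 MPa, 0.46 | UHMWPE inlay |
| ρ, η | 1000 kg/m³, 0.1 Pa·s | synovial fluid, diseased-joint high-shear value |
| σ | 1.95 µm | combined RMS roughness |
| λ_cut | 4.0 | Gaussian tail negligible (F_{5/2}(4)/F_{5/2}(0) < 1e-4) |
| μ | 0.25 | solid–solid friction; cancels in normalised P_f |
| cycle duration | 1.1 s | walking cadence order |

Greenwood–Tripp constants are not measurable from a roughness value
alone; the prefactor K = (16√2/15)π(η_s β σ)²√(σ/β) is built from the
commonly used composite values η_s βσ = 0.04 and σ/β = 10⁻³, and the
asperity elastic modulus defaults to the equivalent-body plane-strain
modulus. Both are configuration keys. With a polymer-scale modulus this
curve is soft (p_a ≲ 0.1 MPa), which has consequences discussed under
*Boundary-contact regularisation*.

## Synthetic gait profiles

The generator interpolates control points with a shape-preserving
periodic cubic (PCHIP on a triple-period extension): specified extrema
are attained exactly, no overshoot occurs between control points, and
the phase-0/1 seam is C¹. Channels:

- total force in body weights: heel strike (0.9 BW), stance peaks at
  phases 0.15/0.50 with subject-specific magnitudes, mid-stance valley
  (1.8 BW), swing minima 0.15/0.12 BW at phases 0.65/0.90, swing bump
  0.35 BW; floor 0.05 BW keeps the contact loaded all cycle;
- entrainment velocity: zero at heel strike and at the reversal phases
  0.20/0.55/0.80, one signed lobe between consecutive zeros with
  amplitudes (0.30, 0.45, 1.00, 0.65)·0.18 m/s — stance velocities small,
  swing velocities larger, peak ≈ 0.18 m/s (order of condylar surface
  speeds at normal cadence); the lateral compartment gets 0.85× the
  medial velocity and 40% of the load (medial share 0.6);
- femoral/tibial surfaces split the entrainment with a fixed
  slide-to-roll ratio (default 1).

Optional zero-mean Fourier noise (seeded) emulates inter-cycle
variability; default off. The medial/lateral split ratio and velocity
magnitudes are not published values — they are configurable emulation
choices.

What the generator does *not* emulate: subject-specific waveform detail,
double-support asymmetries, inter-cycle correlation structure, and any
coupling between load and velocity channels. Passing tests on these
profiles therefore validate the *solver* under physiological magnitudes
and timing, not any individual subject's gait.

## Discretisation and solution scheme

Reynolds equation (dimensionless): linear finite elements on a uniform
grid over Ω_c = [−4.5, 4.5] half-widths (161 nodes by default),
weak form ε(H³P')' − (HŪ)' − ∂H/∂T = 0 with ε = a_H³p_H/(12 η u_ref R²).
The Couette (film-transport) term uses donor-cell upwinding by default —
this is the convection stabilisation; the centred second-order variant
and an additional isotropic-diffusion term are available. On a refined
mesh, switching between upwind and centred changes the converged peak
pressure by ≈0.1% (<1% contract).

Cavitation: penalty term ξ·min(P,0) with ξ = 10⁴; converged states keep
min P ≥ −10⁻³ (observed ≈ −10⁻⁴ on the demo runs).

Elasticity: plane-strain FEM on a 60×60 half-width rectangle, bilinear
quadrilaterals with mean-dilatation (B-bar) treatment — plain
displacement elements lock for the nearly incompressible equivalent
material (ν ≈ 0.46) — on a mesh uniform under the contact and
geometrically graded (ratio 1.3) to the far field. The factorised
operator is condensed once into a dense compliance matrix; applying a
Hertzian semi-ellipse flattens the parabolic gap to 0.2% of its unit
scale (2% tolerance), validating both discretisation and scaling.

Coupling and time stepping: unknowns (nodal P, rigid-body offset H₀) are
solved monolithically by damped Newton with an analytic Jacobian; the
film H is eliminated through an inner Newton solve of
H = H₀ + X²/2 + κ C(P + p_a(H)/p_H + p_c(H)/p_H). Asperity and
gap-penalty pressures are re-evaluated from H inside every iteration.
Time integration is BDF2 (BDF1 first step); when a step fails to
converge (film collapse or reformation at motion reversals) it is
automatically subdivided into up to 64 first-order sub-steps with
linearly interpolated load and velocity. Line search: fraction-to-the-
boundary on film positivity (iterates may not lose more than 98% of the
film minimum at the step start), then an Armijo backtracking on the
residual 2-norm that falls back to the best feasible trial. Newton
tolerance 10⁻⁶ on the max-norm of the dimensionless residual, which
bounds the relative load-balance defect by ~10⁻⁶.

The time scale uses u_ref = max |u_m| over the cycle rather than
u_m(t_ref) literally: the reference phase sits at peak load where the
entrainment can vanish, which would degenerate the time scale; the
choice is a pure rescaling and does not affect dimensional results. The
literal option is available.

## Boundary-contact regularisation

With the composite default constants and a polymer modulus the
Greenwood–Tripp curve saturates near 70 kPa — far below the MPa-scale
contact pressures — so it cannot arrest film collapse during stance.
Squeeze-film drainage at η = 0.1 Pa·s then drives the film below the
roughness scale, where a smooth-film Reynolds description is no longer
meaningful and the discrete problem loses its positive-gap solution. Two
regularisations keep the model well-posed there:

1. **Leakage floor**: below λ = 0.1 the Poiseuille mobility H³ is
   replaced by H_reg²·H (continuous at the threshold, vanishing with the
   gap), representing residual inter-asperity leakage; a draining film
   decays exponentially instead of reaching zero in finite time.
2. **Gap penalty**: below λ = 0.05 a unilateral quadratic penalty
   pressure p_c = 30·p_H·((H_c−H)/H_c)² transfers load directly between
   the solids. It is reported separately from p_a, included in the total
   pressure and the load balance, and **excluded** from the frictional-
   power metric, which integrates the statistical asperity pressure only.

Both thresholds act below the scale where roughness dominates the
physics; converged films that sit on the penalty (λ ≈ 0.05) should be
read as "boundary contact", not as a resolved fluid film.

## Outputs and metrics

Per phase: max total pressure (p + p_a + p_c), max asperity pressure,
min film, min film parameter, asperity load share. Per cycle: the solid
frictional power P_f = ∫∫ μ p_a l dx dt, computed with the solver's
trapezoidal quadrature in x and the periodic trapezoidal rule in t. As
defined it carries no sliding velocity (units N·s); a flag adds
|u_fem − u_tib| (units J) as a documented deviation. Comparisons always
use values normalised to the data-set maximum, which removes μ exactly.

## Verification

The oracle suite (also exposed as `tkr-ehl validate`):

- equivalent-contact constants against exact rational arithmetic;
- Greenwood–Tripp tabulation against direct adaptive quadrature
  (≤10⁻⁴ of curve scale) and a brute-force Simpson evaluation;
- Hertz flat-gap property of the compliance operator;
- quasi-static zero-entrainment approach reproduces the dry Hertz
  solution (peak within 2% of p_H, width within 3% of 2a_H); the
  approach is stopped at the closest quasi-static state — with
  asperities disabled nothing supports the film, and beyond that point
  the implicit step has no positive-gap root;
- rigid iso-viscous pure squeeze against the closed form obtained by
  direct integration (≤1%);
- steady/transient consistency (≤0.5%), squeeze/Couette term ratio
  <10⁻³ at stationarity;
- mirror symmetry under entrainment reversal (exact to solver
  tolerance on the symmetric mesh);
- observed temporal order ≈ 2 on a smooth load-modulated rigid problem;
  mesh-halving study run with the centred scheme at a smooth operating
  point (the upwind default converges first order at the exit
  constriction).

Problem sizes used in tests and the reproduction script: 161 contact
nodes, 75–200 time steps per cycle, three subjects × two compartments;
the convergence studies use up to 641 nodes and 2048 steps.

## Known limitations

- During stance the demo subjects operate on the gap penalty
  (λ_min ≈ 0.05): the model reports boundary contact where a stiffer
  asperity curve (larger K or a metal-scale asperity modulus) would
  instead floor the film near λ ≈ 1. Published TKR studies reporting
  λ between 1 and 2 under comparable loads are consistent with such a
  stiffer solid-contact curve; with the soft polymer-scale defaults the
  corresponding film-parameter band is not reachable, and peak total
  pressures follow the dry-Hertz value at peak load (16–23 MPa for the
  demo subjects).
- One cycle is simulated by default from a Hertzian initial state; the
  first few per-cent of the cycle carry an initialisation transient.
  A cyclic-convergence mode repeats cycles until the friction integrand
  stabilises (<1% change).
- First-order accuracy of the upwind transport near the exit
  constriction; the centred scheme is second order but fragile at
  collapsed films.
- No thermal, piezo-viscous, non-Newtonian or tibial-rotation effects;
  no wear-geometry update.
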