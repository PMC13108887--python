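# Methods

`adefield` simulates the equilibrium shapes of lipid-bilayer vesicles with a
three-dimensional phase-field (diffuse-interface) model that couples bending
elasticity to **area-difference elasticity (ADE)** under soft volume and
surface-area constraints, and relaxes the field by an Allen–Cahn-type
gradient flow solved with Fourier-spectral schemes.

## Model

The membrane is the zero level set of a phase field φ(x) on a periodic cube
[0, L)³, with φ ≈ +1 inside the vesicle and −1 outside and a tanh transition
layer of width ~ε.  The total energy is

    E_M(φ) = W(φ) + G(φ) + M₁ (V(φ) − α)² + M₂ (A(φ) − β)²

with

* **Bending energy**
  `W = (κ/2ε) ∫ f_c² dx`, `f_c = εΔφ − (1/ε)(φ² − 1)(φ + Cε)`,
  the diffuse-interface Willmore/Helfrich energy; C is twice the spontaneous
  curvature c₀ (all presets use C = 0 so the ADE term alone drives
  asymmetry).
* **ADE energy**
  `G = (κ̄π / 2A₀D²) (ΔA(φ) − ΔA₀)²`, a *global* quadratic penalty on the
  deviation of the leaflet area difference from its relaxed value ΔA₀.
  D is the distance between the neutral surfaces of the two monolayers
  (physically about two-thirds of the bilayer thickness; the model couples it
  to the numerical interface width as D = (2/3)ε).  The diffuse form of the
  geometric identity ΔA = D∮2H dA is
  `ΔA = −(3D/4) ∫ (1−φ²)Δφ + (1/ε²)φ(1−φ²)² dx`;
  with interior {φ > 0}, a sphere of radius R gives ΔA = +8πDR.
  A₀ is anchored to the target area β.
* **Constraints**: interior volume `V = ∫(φ+1)/2` and membrane area
  `A = (3√2/4) B`, with B the standard Modica–Mortola functional, enforced
  softly by quadratic penalties (defaults M₁ = 10⁵, M₂ = 10⁴).

Shapes are classified by the reduced volume `v = V / ((4π/3)R_s³)` and the
reduced area difference `Δa₀ = ΔA₀ / (8πD R_s)`, `R_s = √(A/4π)`; both equal
1 for a sphere.  The competition between W and G as (v, Δa₀) vary produces
discocytes, tori, prolates, budded/fissioned doublets, pears, starfish and
nested shapes.

## Dynamics and schemes

The field relaxes by the gradient flow φ_t = −δE_M/δφ.  Three steppers:

* **Forward Euler** — reference only; stable only for tiny Δt.
* **Semi-implicit (default)** — the stiff linear part of the bending
  variation, κ(εΔ² + (2/ε)Δ)φ, is treated implicitly (diagonal solve in
  Fourier space); all remaining nonlinear, ADE and penalty terms are
  explicit at φⁿ.  First-order accurate in time; energy decay is verified
  numerically (see below).  The implicit symbol
  1/Δt + κ(ε|k|⁴ − (2/ε)|k|²) must stay positive, which bounds
  Δt < ε³/κ; a violation raises a stability error naming the offending mode.
* **Fully implicit symmetrized** — uses two-argument symmetric forms
  f(φ,η), g(φ,η), h(φ,η) that satisfy *exact* discrete energy-difference
  identities, so the solution obeys the per-step energy law
  `E(φⁿ⁺¹) − E(φⁿ) + (1/Δt)∫(φⁿ⁺¹−φⁿ)² dx = 0` to solver tolerance.
  Solved by Picard iteration preconditioned with the semi-implicit linear
  operator (default tolerance 1e−10 in max norm, 200 iterations; Newton was
  not needed at the Δt values of interest).

The symmetric ADE form implemented here is the exact factorization of
ΔA(φ) − ΔA(η): Laplacian part −½(φ+η)Δ(φ+η) − ½Δ(φ²+η²) and polynomial
part 1 − 2(φ²+φη+η²) + (φ⁴+φ³η+φ²η²+φη³+η⁴).  It reduces to the
one-argument variation at φ = η and is the unique symmetric form for which
the discrete energy law holds exactly (we verify it to ≤1e−13 relative).

### Discretization choices

* Collocation (pseudo-spectral) products, no dealiasing by default; an
  explicit 2/3-rule is unnecessary at the resolutions used because the tanh
  profiles are spectrally resolved (≥3 cells per ε).  Nodes are x_i = i·h,
  h = L/N; the real-input FFT keeps every operator output real by
  construction.
* ∫|∇φ|² inside the area functional is evaluated as −∫φΔφ — the exact
  discrete integration by parts for the spectral Laplacian.  This choice
  (rather than summing squared spectral gradients) is what makes the
  energy-difference identities and the discrete energy law exact at the
  roundoff level, including the even-N Nyquist mode.
* Quadrature is the periodic trapezoid rule h³Σ, spectrally accurate for
  smooth periodic integrands.
* The global scalars (ΔA − ΔA₀), (V − α), (A − β) are computed once per
  derivative evaluation.
* Divergence guard: max|φ| > 2.5 or any non-finite value aborts the step
  with the partial time series attached.

### Steady-state detection

The stopping rule is Δt-independent: ‖φⁿ⁺¹ − φⁿ‖∞/Δt ≤ 10⁻³ (φ-units per
unit time) for 100 consecutive steps *and* relative energy change per
logging interval ≤ 10⁻⁸.  Both thresholds are configurable.

## Initial conditions and targets

Initial fields are tanh profiles of implicit surfaces,
`tanh((r₀ − √(Σ(xᵢ−cᵢ)²/dᵢ))/(√2 ε))` for ellipsoids (semi-axes √dᵢ·r₀) and
`tanh(max(r₁−d₁, r₂−d₂)/(√2 ε))` for two-sphere unions (the pear-shape
initializer).  The experiments prescribe (v, Δa₀); the absolute targets are
derived from the initial field: β = A(φ₀), R_s = √(β/4π),
α = v·(4π/3)R_s³, ΔA₀ = Δa₀·8πD·R_s.  (The area constraint is anchored to
the initial condition; an override uses the measured V(φ₀) for α instead.)
An optional seeded band-limited perturbation is available for symmetry
breaking; it is off by default because the presets break symmetry through
asymmetric initial data.

Preset registry (defaults Ω=[0,1]³, N=64, κ=1, κ̄=1.4, M₁=10⁵, M₂=10⁴,
C=0, D=(2/3)ε): `discocyte` (ε=0.04, Δt=1e−6, v=0.8, Δa₀=1.2, oblate
ellipsoid init), `torus` (same at Δa₀=1.4), `budding_a`–`budding_f`
(v=0.9, ε=0.02, Δt=5e−7, Δa₀ ∈ {1.1, 1.4, 1.5, 1.6, 1.7, 1.8}, prolate
init; the endpoint fissions into two daughter vesicles), `chain`, `arms3`,
`arms4`, `arms6` (starfish), `nested` (Ω=[0,2]³, N=100, ε=0.03, κ̄=4,
M₁=M₂=10⁴), `pear` (two unequal spheres; v and Δa₀ are required inputs and
a (v, Δa₀) continuation sweep is the intended driver), and `cauchy_table1`
(the convergence-study configuration).  The `chain` preset carries the same
parameter set as `budding_b`; which of the two steady states is reached
depends on details beyond these parameters (basin of attraction, symmetry
breaking), so both presets ship and the ambiguity is documented rather than
resolved — the perturbation seed and continuation sweeps are the tools for
exploring it.  The two-sphere pear initializer defaults to the smaller
radius at the lower center; both radii are exposed so either orientation
can be run.

## Verification

All checks run from `adefield verify` and the test suite:

* **Sphere oracles** — for a tanh sphere, V, A, ΔA are compared with
  4πR³/3, 4πR², 8πDR.  These certify the reconstructed constants
  (3√2/4 in A, the √2ε tanh width, the 3D/4 prefactor of ΔA).  Note that
  the *continuum* tanh-ball volume exceeds 4πR³/3 by (π²/2)(ε/R)²
  (≈1.6% at ε=0.02, R=0.35) — an intrinsic property of the profile, not a
  discretization error; A and ΔA carry much smaller biases.  Errors for all
  three shrink as ε decreases at fixed R.
* **Gradient consistency** — Richardson-extrapolated central directional
  derivatives of W, G, T₁, T₂ match ⟨δE/δφ, ψ⟩ to ≤1e−6 relative on random
  band-limited fields; this pins the ADE prefactor κ̄π/(2A₀D²) (the π must
  be in the numerator for the chain rule applied to G to reproduce the
  one-argument variation h) and the (3√2/2) constant in δT₂/δφ.
* **Energy-difference identities** and the **discrete energy law** of the
  fully implicit scheme hold to roundoff (≤1e−13 observed).
* **Temporal convergence** — a Cauchy test (no closed-form solution exists):
  e_Δt = ‖φ_Δt − φ_{Δt/2}‖_L² at fixed horizon T = 2e−6 for
  Δt ∈ {2e−7, …, 1.25e−8} on the 64³ discocyte configuration; orders
  log₂(e_Δt/e_{Δt/2}) approach 1, confirming first-order accuracy of the
  semi-implicit splitting (measured 1.03 → 1.004 across the ladder).
* **Energy stability** — scaled-down (48³) semi-implicit runs of the
  discocyte and torus presets show strictly non-increasing energy at every
  step over 3000 steps (~650 → ~40 energy units) approaching a plateau.
  Full-scale steady-state runs of every preset are desk jobs driven by the
  CLI (hours on one core); the test suite exercises the morphology
  classifiers on constructed steady-state analogues instead.

## Shape diagnostics

* Voxel masks use the level-set convention interior = {φ > 0}.
* Connected components are labeled with 6-connectivity by default
  (26 optional) and merged across periodic faces via a roll-based label
  graph; the membrane sheet count is interior + exterior − 1.
* **Arm counting** (a diagnostic of our own construction):
  interior voxels farther from the (circular-mean, periodic) centroid than
  `core_fraction` (default 0.5) × the maximum centroid distance form a
  shell; its periodic components are candidate arms.  A single shell
  component wraps a round/compact body rather than marking a protrusion, so
  counts < 2 report 0 (a sphere has 0 arms, a three-lobed body 3).
* **Reflection asymmetry**: the field is reflected about the plane through
  the centroid normal to the principal (largest-spread) axis of the
  interior indicator, via cubic interpolation with periodic wrap; the score
  is ‖φ − φ_reflected‖₁/‖φ + 1‖₁ ∈ [0, 1] (0 symmetric; the unequal-sphere
  pear initializer scores > 0.05).

## Problem sizes and limitations

The shipped verification suites use 32³–64³ grids and short horizons
(hundreds to a few thousand steps), chosen so each check completes in
seconds to minutes on one core; steady-state morphology reproduction at the
full resolutions (64³–100³, 10⁵+ steps) is run through
`adefield run`/`sweep`.  Known limitations: no dealiasing (irrelevant at
resolved ε but untested for ε < 2h), fixed time step (no adaptivity),
penalties are soft, so equilibria carry a residual constraint offset (at
the default M₁ the 48³ discocyte run settles ~0.1 above its reduced-volume
target; larger M₁/M₂ shrink the offset at the cost of stiffness), no
Gaussian-curvature energy, no hydrodynamics, and the Fig-9-style phase
diagram boundary localization is compute-bound and out of scope for the
automated suite.
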