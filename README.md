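# adefield

Phase-field simulation of three-dimensional vesicle membranes with
**area-difference elasticity (ADE)**.

Lipid-bilayer vesicles adopt a striking variety of equilibrium shapes —
discocytes, tori, budded doublets, asymmetric pears, starfish, nested
vesicles — controlled by just two dimensionless numbers: the reduced volume
*v* and the reduced area difference Δa₀.  The bilayer's two leaflets are
separated by a distance D, so bending the membrane changes their area
difference ΔA = D∮2H dA; the ADE model penalizes deviations of ΔA from a
relaxed value ΔA₀, and this non-local term is what stabilizes asymmetric
shapes (pears, budded multiplets) that pure bending energy cannot.

`adefield` represents the membrane as the zero level set of a smooth phase
field φ on a periodic cube and minimizes

    E_M(φ) = (κ/2ε)∫f_c² dx  +  (κ̄π/2A₀D²)(ΔA(φ) − ΔA₀)²
             + M₁(V(φ) − α)² + M₂(A(φ) − β)²,

where f_c = εΔφ − (1/ε)(φ²−1)(φ+Cε), by an Allen–Cahn gradient flow
φ_t = −δE_M/δφ.  Spatial operators are Fourier-spectral; time stepping is
semi-implicit (stiff linear bending terms solved diagonally in Fourier
space) or fully implicit with an exact per-step discrete energy law.
Because the interface is diffuse, topological transitions — budding,
fission, nesting — happen without any surface tracking.  See
`docs/methods.md` for the full model, numerical choices and verification.

Intended users: researchers in membrane biophysics and computational
mathematics who want a reproducible, tested reference implementation of the
ADE phase-field model and its energy-stable spectral schemes.

## Worked example

Relax the discocyte experiment (v = 0.8, Δa₀ = 1.2, ε = 0.04) at reduced
resolution and inspect the result:

    $ adefield run --preset discocyte --N 48 --max-steps 12000 --output out
    [18:28:39] run: preset=discocyte N=48 eps=0.04 dt=1e-06 v=0.8 da0=1.2 scheme=semi_implicit
    [18:33:59] finished after 12000 steps (max_steps); E=39.0704

    $ adefield analyze out/phi_final.h5
    [18:34:00] shape metrics for out/phi_final.h5:
      v: 0.9094472749588408
      da: 1.0950797731302682
      n_interior_components: 1
      n_exterior_components: 1
      n_membrane_components: 1
      n_arms: 0
      asymmetry: 3.6876796257140596e-13
      principal_moments: (0.004277029623135697, 0.015187167186180895, 0.015187167186180921)

The energy has fallen from 653.5 to 39.07 (logged in `out/energy.csv`,
strictly non-increasing) and has plateaued.  One principal moment much
smaller than the two (equal) others identifies a flattened, axisymmetric
oblate shape; a single membrane sheet, no arms and zero reflection
asymmetry complete the classification.  The measured reduced parameters
(v ≈ 0.91, Δa ≈ 1.10) sit between the deflated initial ellipsoid
(v ≈ 0.56) and the targets (0.8, 1.2): the constraints are soft quadratic
penalties, so the equilibrium balances them against the bending and ADE
forces rather than pinning them exactly, and the residual offset shrinks
as the penalty coefficients grow.  Snapshots are written as HDF5 (exact
restart) and legacy VTK (visualization).

Other presets reproduce the remaining experiments: `torus`,
`budding_a`–`budding_f` (the Δa₀ ladder 1.1 → 1.8 ending in fission),
`arms3`/`arms4`/`arms6` starfish, `nested`, and `pear` (two unequal
spheres; supply `--v`/`--da0`, typically via a continuation `sweep`).
Full steady states at full resolution (64³–100³) take hours on one core.

Numerical verification suites (variational-derivative checks, tanh-sphere
geometry oracles, discrete energy law, temporal convergence):

    adefield verify --suite all

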