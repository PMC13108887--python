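"""Numerical-verification routines.

Self-contained checks of the discretization against independent oracles:
closed-form tanh-sphere geometry, Richardson-extrapolated directional
derivatives for every energy component, the exact discrete
energy-difference identities of the symmetrized implicit scheme, the
per-step discrete energy law, and the Cauchy-type temporal convergence
study of the semi-implicit scheme.  Shared by the CLI ``verify``
subcommand, the test suite and the acceptance script.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import pi

import numpy as np

from .config import preset, build_run
from .dynamics import StepperConfig, step_fully_implicit, step_semi_implicit, run_simulation
from .grid import PeriodicGrid, make_grid
from .model import (
    ConstraintTargets,
    ModelParams,
    ade_energy_G,
    area_A,
    bending_energy_W,
    delta_area,
    penalties,
    penalty_derivatives,
    symmetrized_forms,
    total_energy,
    variational_g,
    variational_h,
    volume_V,
)
from .observables import reduced_parameters
from .shapes import ShapeSpec, smooth_random_field, tanh_ellipsoid

__all__ = [
    "sphere_oracles",
    "gradient_checks",
    "difference_identities",
    "energy_law_residuals",
    "cauchy_table",
    "energy_stability",
    "CAUCHY_DTS",
]

CAUCHY_DTS = (2.0e-7, 1.0e-7, 5.0e-8, 2.5e-8, 1.25e-8)


def tanh_sphere(grid: PeriodicGrid, R: float, epsilon: float) -> np.ndarray:
    c = grid.L / 2.0
    spec = ShapeSpec(
        kind="ellipsoid", center=(c, c, c), denominators=(1.0, 1.0, 1.0), r0=R
    )
    return tanh_ellipsoid(grid, spec, epsilon)


def sphere_oracles(N: int = 64, R: float = 0.35, epsilon: float = 0.02) -> dict:
    """Relative errors of V, A, dA, v, da for a tanh sphere vs closed forms.

    A resolved sphere of radius R has V = 4*pi*R^3/3, A = 4*pi*R^2,
    dA = 8*pi*D*R and (v, da) = (1, 1).
    """
    grid = make_grid(1.0, N)
    params = ModelParams(epsilon=epsilon)
    phi = tanh_sphere(grid, R, epsilon)
    V = volume_V(grid, phi)
    A = area_A(grid, phi, params)
    dA = delta_area(grid, phi, params)
    v, da = reduced_parameters(grid, phi, params)
    return {
        "V": abs(V - 4.0 * pi * R**3 / 3.0) / (4.0 * pi * R**3 / 3.0),
        "A": abs(A - 4.0 * pi * R**2) / (4.0 * pi * R**2),
        "dA": abs(dA - 8.0 * pi * params.D * R) / (8.0 * pi * params.D * R),
        "v": abs(v - 1.0),
        "da": abs(da - 1.0),
    }


# ----------------------------------------------------------------------
# gradient consistency
# ----------------------------------------------------------------------
def _random_state(grid, rng, amplitude=0.9):
    return smooth_random_field(grid, rng, kmax_frac=0.25, amplitude=amplitude)


def _offset_targets(grid, phi, params):
    """Targets deliberately away from the field's current observables so
    every derivative term is active."""
    V = volume_V(grid, phi)
    A = area_A(grid, phi, params)
    dA = delta_area(grid, phi, params)
    return ConstraintTargets(alpha=V + 0.07, beta=abs(A) + 0.3, dA0=dA + 0.11)


def _richardson(E, phi, psi, t):
    def central(s):
        return (E(phi + s * psi) - E(phi - s * psi)) / (2.0 * s)

    return (4.0 * central(t / 2.0) - central(t)) / 3.0


def gradient_checks(
    seed: int = 0, N: int = 32, epsilon: float = 0.1, n_pairs: int = 5, t: float = 1.0e-2
) -> dict:
    """Max relative error of <dE/dphi, psi> vs Richardson-extrapolated
    central differences, per component, over random smooth (phi, psi) pairs.

    Certifies the variational derivatives including the reconstructed
    area constants and the ADE prefactor.
    """
    grid = make_grid(1.0, N)
    params = ModelParams(epsilon=epsilon, C=0.4, M1=10.0, M2=10.0)
    rng = np.random.default_rng(seed)
    worst = {"W": 0.0, "G": 0.0, "T1": 0.0, "T2": 0.0}
    for _ in range(n_pairs):
        phi = _random_state(grid, rng)
        psi = _random_state(grid, rng, amplitude=1.0)
        targets = _offset_targets(grid, phi, params)
        lap = grid.laplacian(phi)

        cases = {
            "W": (
                lambda u: bending_energy_W(grid, u, params),
                params.kappa * variational_g(grid, phi, params, lap=lap),
            ),
            "G": (
                lambda u: ade_energy_G(grid, u, params, targets),
                variational_h(grid, phi, params, targets, lap=lap),
            ),
            "T1": (
                lambda u: penalties(grid, u, params, targets)[0],
                penalty_derivatives(grid, phi, params, targets, lap=lap)[0],
            ),
            "T2": (
                lambda u: penalties(grid, u, params, targets)[1],
                penalty_derivatives(grid, phi, params, targets, lap=lap)[1],
            ),
        }
        for name, (E, grad) in cases.items():
            expected = grid.integrate(grad * psi)
            measured = _richardson(E, phi, psi, t)
            rel = abs(measured - expected) / max(abs(expected), 1.0e-14)
            worst[name] = max(worst[name], rel)
    return worst


def difference_identities(seed: int = 0, N: int = 48, n_pairs: int = 5) -> dict:
    """Max relative error of the exact energy-difference identities.

    For random smooth (phi, eta):
      W(phi)-W(eta)  = Int (phi-eta) * kappa * g2
      G(phi)-G(eta)  = Int (phi-eta) * h2
      T1(phi)-T1(eta) = M1 (V+V-2a) * Int (phi-eta)/2
      T2(phi)-T2(eta) = M2 (A+A-2b) * Int (phi-eta) * (-(3*sqrt2/4) f2)
    """
    grid = make_grid(1.0, N)
    params = ModelParams(epsilon=0.08, C=0.3, M1=10.0, M2=10.0)
    rng = np.random.default_rng(seed)
    worst = {"W": 0.0, "G": 0.0, "T1": 0.0, "T2": 0.0}
    const = 3.0 * np.sqrt(2.0) / 4.0
    for _ in range(n_pairs):
        phi = _random_state(grid, rng)
        eta = _random_state(grid, rng)
        targets = _offset_targets(grid, phi, params)
        f2, g2, h2 = symmetrized_forms(grid, phi, eta, params, targets)
        d = phi - eta
        lhs = {
            "W": bending_energy_W(grid, phi, params) - bending_energy_W(grid, eta, params),
            "G": ade_energy_G(grid, phi, params, targets)
            - ade_energy_G(grid, eta, params, targets),
            "T1": penalties(grid, phi, params, targets)[0]
            - penalties(grid, eta, params, targets)[0],
            "T2": penalties(grid, phi, params, targets)[1]
            - penalties(grid, eta, params, targets)[1],
        }
        V_sum = volume_V(grid, phi) + volume_V(grid, eta) - 2.0 * targets.alpha
        A_sum = (
            area_A(grid, phi, params) + area_A(grid, eta, params) - 2.0 * targets.beta
        )
        rhs = {
            "W": grid.integrate(d * params.kappa * g2),
            "G": grid.integrate(d * h2),
            "T1": params.M1 * V_sum * grid.integrate(d * 0.5),
            "T2": params.M2 * A_sum * grid.integrate(d * (-const * f2)),
        }
        for name in worst:
            rel = abs(lhs[name] - rhs[name]) / max(abs(lhs[name]), 1.0e-14)
            worst[name] = max(worst[name], rel)
    return worst


# ----------------------------------------------------------------------
# time-stepping verification
# ----------------------------------------------------------------------
def _fixture(preset_name: str, N: int):
    cfg = preset(preset_name, N=N)
    grid, phi0, params, targets, _ = build_run(cfg)
    return grid, phi0, params, targets, cfg


def energy_law_residuals(
    N: int = 32, dt: float = 1.0e-7, steps: int = 20, picard_tol: float = 1.0e-13
) -> np.ndarray:
    """Per-step residual of the discrete energy law, relative to |E|.

    For the fully implicit symmetrized scheme the identity
    ``E(phi^{n+1}) - E(phi^n) + (1/dt) Int (phi^{n+1}-phi^n)^2 dx = 0``
    holds exactly; the returned residuals are limited by the Picard
    tolerance and roundoff.
    """
    grid, phi, params, targets, _ = _fixture("discocyte", N)
    out = np.empty(steps)
    E_prev = total_energy(grid, phi, params, targets).E
    for i in range(steps):
        new = step_fully_implicit(
            grid, phi, dt, params, targets, tol=picard_tol, max_iter=500
        )
        E_new = total_energy(grid, new, params, targets).E
        residual = E_new - E_prev + grid.integrate(np.square(new - phi)) / dt
        out[i] = abs(residual) / max(abs(E_new), 1.0e-300)
        phi, E_prev = new, E_new
    return out


def _advance(grid, phi0, dt, n_steps, params, targets):
    phi = phi0
    for i in range(n_steps):
        phi = step_semi_implicit(grid, phi, dt, params, targets, step=i)
    return phi


def cauchy_table(N: int = 64, T: float = 2.0e-6, dts=CAUCHY_DTS):
    """Temporal Cauchy convergence study of the semi-implicit scheme.

    Runs the discocyte configuration to a fixed horizon T for each dt in
    the halving ladder and reports rows ``(dt, error, order)`` with
    ``error = ||phi_dt - phi_{dt/2}||_L2`` at T and
    ``order = log2(error_prev / error)``; first-order accuracy gives
    orders approaching 1.
    """
    grid, phi0, params, targets, _ = _fixture("cauchy_table1", N)
    dts = list(dts)
    solutions = {}
    for dt in list(dts) + [dts[-1] / 2.0]:
        n = round(T / dt)
        if abs(n * dt - T) > 1.0e-12 * T:
            raise ValueError(f"horizon T={T} is not an integer multiple of dt={dt}")
        solutions[dt] = _advance(grid, phi0, dt, n, params, targets)
    rows = []
    prev_err = None
    for dt in dts:
        err = grid.l2_norm(solutions[dt] - solutions[dt / 2.0])
        order = np.nan if prev_err is None else float(np.log2(prev_err / err))
        rows.append((dt, err, order))
        prev_err = err
    return rows


@dataclass
class StabilityReport:
    max_relative_increase: float
    final_plateau_change: float
    result: object


def energy_stability(
    preset_name: str = "discocyte", N: int = 48, max_steps: int = 5000, log_every: int = 10
) -> StabilityReport:
    """Run a preset with the semi-implicit scheme and measure energy monotonicity.

    Returns the largest per-interval energy increase relative to |E| over
    the logged series (0 for a perfectly monotone run) and the relative
    energy change over the last 10% of the run (plateau indicator).
    """
    cfg = preset(preset_name, N=N, max_steps=max_steps, log_every=log_every)
    grid, phi0, params, targets, stepper = build_run(cfg)
    result = run_simulation(grid, phi0, stepper, params, targets)
    E = result.energies
    dE = np.diff(E)
    increase = float(np.max(dE / np.abs(E[:-1]))) if len(dE) else 0.0
    tail = max(2, len(E) // 10)
    plateau = abs(E[-1] - E[-tail]) / abs(E[-1])
    return StabilityReport(
        max_relative_increase=max(increase, 0.0),
        final_plateau_change=float(plateau),
        result=result,
    )
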