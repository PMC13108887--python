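"""Gradient-flow dynamics and time-stepping schemes.

The phase field relaxes by the Allen–Cahn-type gradient flow

    phi_t = -dE_M/dphi = -(kappa*g + h + dT1/dphi + dT2/dphi),

driven to a steady state.  Three steppers are provided:

* ``forward_euler`` — fully explicit; stable only for very small dt;
* ``semi_implicit`` — the workhorse: the stiff linear part of kappa*g,
  namely ``kappa*(eps*Lap^2 + (2/eps)*Lap)``, is treated implicitly
  (a diagonal solve in Fourier space), all remaining nonlinear, ADE and
  penalty terms explicitly;
* ``fully_implicit`` — the symmetrized scheme whose solution satisfies
  the exact discrete energy law
  ``E(phi^{n+1}) - E(phi^n) + (1/dt) * Int (phi^{n+1} - phi^n)^2 dx = 0``;
  solved by Picard iteration preconditioned with the semi-implicit
  linear operator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .exceptions import BlowUpError, SolverError
from .grid import PeriodicGrid
from .model import (
    ConstraintTargets,
    EnergyBreakdown,
    ModelParams,
    delta_area,
    f_field,
    penalty_derivatives,
    symmetrized_forms,
    total_energy,
    variational_g,
    variational_h,
    volume_V,
    area_A,
)

__all__ = [
    "StepperConfig",
    "SimulationResult",
    "gradient_flow_rhs",
    "step_forward_euler",
    "step_semi_implicit",
    "step_fully_implicit",
    "run_simulation",
]

SCHEMES = ("forward_euler", "semi_implicit", "fully_implicit")


@dataclass(frozen=True)
class StepperConfig:
    """Time-stepping and termination settings.

    The steady-state criterion is rate-based and dt-independent: the run
    stops once ``max|phi^{n+1} - phi^n| / dt <= steady_rate_tol`` for
    ``steady_window`` consecutive steps and the relative energy change per
    logging interval is below ``steady_energy_tol``.
    """

    scheme: str = "semi_implicit"
    dt: float = 1.0e-6
    max_steps: int = 100_000
    log_every: int = 100
    steady_rate_tol: float = 1.0e-3
    steady_window: int = 100
    steady_energy_tol: float = 1.0e-8
    picard_tol: float = 1.0e-10
    picard_max_iter: int = 200
    divergence_guard: float = 2.5

    def __post_init__(self):
        if self.scheme not in SCHEMES:
            raise ValueError(f"scheme must be one of {SCHEMES}, got {self.scheme!r}")
        if not self.dt > 0:
            raise ValueError("dt must be positive")
        for name in ("steady_rate_tol", "steady_energy_tol", "picard_tol"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class SimulationResult:
    """Final field plus the logged energy/observable time series."""

    final_field: np.ndarray
    energy_series: list[EnergyBreakdown]
    steps_taken: int
    converged: bool
    termination_reason: str  # 'steady' | 'max_steps' | 'diverged' | 'solver_failure'

    @property
    def times(self) -> np.ndarray:
        return np.array([e.t for e in self.energy_series])

    @property
    def energies(self) -> np.ndarray:
        return np.array([e.E for e in self.energy_series])


# ----------------------------------------------------------------------
# right-hand side and steppers
# ----------------------------------------------------------------------
def gradient_flow_rhs(
    grid: PeriodicGrid, phi, params: ModelParams, targets: ConstraintTargets
):
    """``-dE_M/dphi`` assembled from the variational derivatives."""
    lap = grid.laplacian(phi)
    g = variational_g(grid, phi, params, lap=lap)
    h = variational_h(grid, phi, params, targets, lap=lap)
    dT1, dT2 = penalty_derivatives(grid, phi, params, targets, lap=lap)
    rhs = -(params.kappa * g + h + dT1 + dT2)
    if not np.all(np.isfinite(rhs)):
        raise BlowUpError("non-finite value in gradient-flow right-hand side")
    return rhs


def _check_guard(phi, guard: float, step=None):
    m = np.max(np.abs(phi))
    if not np.isfinite(m) or m > guard:
        raise BlowUpError(
            f"phase field out of bounds (max|phi|={m:.3g} > {guard:g})"
            + (f" at step {step}" if step is not None else ""),
            step=step,
        )


def step_forward_euler(grid, phi, dt, params, targets, guard=2.5, step=None):
    """Explicit Euler step ``phi + dt * rhs(phi)``."""
    out = phi + dt * gradient_flow_rhs(grid, phi, params, targets)
    _check_guard(out, guard, step)
    return out


def _semi_implicit_rhs(grid, phi, dt, params, targets):
    """Explicit side of the semi-implicit scheme, sharing spectral work."""
    e = params.epsilon
    C = params.C
    phi2 = phi * phi
    lap = grid.laplacian(phi)
    lap_phi3 = grid.laplacian(phi2 * phi)
    lap_phi2 = grid.laplacian(phi2)
    # explicit remainder of g after removing eps*Lap^2 + (2/eps)*Lap
    expl = (
        -lap_phi3 / e
        - C * lap_phi2
        - 3.0 / e * phi2 * lap
        - 2.0 * C * phi * lap
        + (3.0 * phi2 + 2.0 * C * e * phi - 1.0)
        * (phi2 - 1.0)
        * (phi + C * e)
        / e**3
    )
    h = variational_h(grid, phi, params, targets, lap=lap)
    dT1, dT2 = penalty_derivatives(grid, phi, params, targets, lap=lap)
    return phi / dt - params.kappa * expl - h - dT1 - dT2


def step_semi_implicit(grid, phi, dt, params, targets, guard=2.5, step=None):
    """One step of the spectral semi-implicit scheme.

    Solves ``(1/dt + kappa*(eps*Lap^2 + (2/eps)*Lap)) phi^{n+1} = rhs(phi^n)``
    diagonally in Fourier space.
    """
    rhs = _semi_implicit_rhs(grid, phi, dt, params, targets)
    out = grid.solve_implicit_operator(
        rhs, 1.0 / dt, 2.0 * params.kappa / params.epsilon, params.kappa * params.epsilon
    )
    _check_guard(out, guard, step)
    return out


def _implicit_residual_rhs(grid, phi_n, eta, dt, params, targets):
    """Fully implicit right-hand side ``F(phi^n, eta)`` of the symmetrized scheme."""
    f2, g2, h2 = symmetrized_forms(grid, phi_n, eta, params, targets)
    V_sum = volume_V(grid, eta) + volume_V(grid, phi_n) - 2.0 * targets.alpha
    A_sum = area_A(grid, eta, params) + area_A(grid, phi_n, params) - 2.0 * targets.beta
    area_const = 3.0 * np.sqrt(2.0) / 4.0
    return (
        params.kappa * g2
        + h2
        + 0.5 * params.M1 * V_sum
        + area_const * params.M2 * A_sum * (-f2)
    )


def step_fully_implicit(
    grid, phi, dt, params, targets,
    tol=1.0e-10, max_iter=200, guard=2.5, step=None,
):
    """One step of the fully implicit symmetrized scheme (Picard iteration).

    Iterates ``(1/dt + L) eta_{k+1} = phi^n/dt + L eta_k - F(phi^n, eta_k)``
    with ``L = kappa*(eps*Lap^2 + (2/eps)*Lap)`` until successive iterates
    differ by at most ``tol`` in max norm; at the fixed point,
    ``(eta - phi^n)/dt = -F(phi^n, eta)`` exactly.
    """
    s0 = 1.0 / dt
    s2 = 2.0 * params.kappa / params.epsilon
    s4 = params.kappa * params.epsilon
    eta = phi.copy()
    for _ in range(max_iter):
        F = _implicit_residual_rhs(grid, phi, eta, dt, params, targets)
        # L*eta with s0 = 0
        L_eta = grid.apply_implicit_operator(eta, 0.0, s2, s4)
        new = grid.solve_implicit_operator(phi / dt - F + L_eta, s0, s2, s4)
        diff = float(np.max(np.abs(new - eta)))
        eta = new
        if diff <= tol:
            _check_guard(eta, guard, step)
            return eta
    raise SolverError(
        f"Picard iteration did not converge in {max_iter} iterations "
        f"(last update {diff:.3e} > tol {tol:.1e}); reduce dt",
        residual=diff,
    )


_STEPPERS = {
    "forward_euler": step_forward_euler,
    "semi_implicit": step_semi_implicit,
    "fully_implicit": step_fully_implicit,
}


def _take_step(grid, phi, cfg: StepperConfig, params, targets, step):
    if cfg.scheme == "fully_implicit":
        return step_fully_implicit(
            grid, phi, cfg.dt, params, targets,
            tol=cfg.picard_tol, max_iter=cfg.picard_max_iter,
            guard=cfg.divergence_guard, step=step,
        )
    return _STEPPERS[cfg.scheme](
        grid, phi, cfg.dt, params, targets, guard=cfg.divergence_guard, step=step
    )


def run_simulation(
    grid: PeriodicGrid,
    phi0: np.ndarray,
    cfg: StepperConfig,
    params: ModelParams,
    targets: ConstraintTargets,
    callbacks: Sequence[Callable] = (),
) -> SimulationResult:
    """Iterate the chosen stepper until steady state, max_steps or failure.

    ``callbacks`` are called as ``cb(step, t, phi, energy)`` at every
    logging point.  The run is deterministic for a fixed configuration.
    On stepper failure the partial series is attached to the raised
    exception as ``exc.result``.
    """
    phi = np.asarray(phi0, dtype=float).copy()
    series: list[EnergyBreakdown] = []
    e0 = total_energy(grid, phi, params, targets).at_time(0.0)
    series.append(e0)
    for cb in callbacks:
        cb(0, 0.0, phi, e0)
    last_logged_E = e0.E
    energy_flat = False
    rate_count = 0
    step = 0
    try:
        while step < cfg.max_steps:
            new = _take_step(grid, phi, cfg, params, targets, step)
            rate = float(np.max(np.abs(new - phi))) / cfg.dt
            phi = new
            step += 1
            t = step * cfg.dt
            if rate <= cfg.steady_rate_tol:
                rate_count += 1
            else:
                rate_count = 0
            at_log = step % cfg.log_every == 0
            steady = rate_count >= cfg.steady_window and energy_flat
            if at_log or steady or step == cfg.max_steps:
                e = total_energy(grid, phi, params, targets).at_time(t)
                series.append(e)
                for cb in callbacks:
                    cb(step, t, phi, e)
                if at_log:
                    denom = max(abs(last_logged_E), 1.0e-300)
                    energy_flat = abs(e.E - last_logged_E) / denom <= cfg.steady_energy_tol
                    last_logged_E = e.E
                steady = rate_count >= cfg.steady_window and energy_flat
            if steady:
                return SimulationResult(phi, series, step, True, "steady")
    except (BlowUpError, SolverError) as exc:
        reason = "diverged" if isinstance(exc, BlowUpError) else "solver_failure"
        exc.result = SimulationResult(phi, series, step, False, reason)
        raise
    return SimulationResult(phi, series, step, False, "max_steps")
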