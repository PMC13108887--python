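"""Energy functionals and variational derivatives of the ADE phase-field model.

The vesicle membrane is the zero level set of a phase field ``phi`` that is
close to +1 inside the vesicle and -1 outside, with a tanh transition layer
of width ~``epsilon``.  The total energy is

    E_M(phi) = W(phi) + G(phi) + M1*(V(phi) - alpha)^2 + M2*(A(phi) - beta)^2

with

* ``W`` — the diffuse-interface bending (Willmore/Helfrich) energy
  ``(kappa/(2*eps)) * Int f_c^2 dx``, where
  ``f_c = eps*Lap(phi) - (1/eps)*(phi^2 - 1)*(phi + C*eps)`` and ``C`` is
  twice the spontaneous curvature;
* ``G`` — the area-difference-elasticity (ADE) energy
  ``(kbar*pi / (2*A0*D^2)) * (dA(phi) - dA0)^2``, a global quadratic
  penalty on the deviation of the leaflet area difference from its
  relaxed value.  ``D`` is the separation of the two monolayer neutral
  surfaces; ``dA(phi)`` is the diffuse-interface form of ``D*Int 2H dA``;
* quadratic penalties softly enforcing the interior volume ``V`` and the
  membrane area ``A`` (with ``A = (3*sqrt(2)/4) * B``, ``B`` the usual
  Modica–Mortola functional).

All spatial operators are spectral (see :mod:`adefield.grid`).  The
``Int |grad phi|^2`` term inside ``B`` is evaluated as ``-Int phi*Lap(phi)``,
the exact discrete integration by parts for the spectral Laplacian; this
makes the discrete energy-difference identities used by the fully implicit
scheme hold to roundoff.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from math import pi, sqrt

import numpy as np

from .exceptions import InvalidTargetsError
from .grid import PeriodicGrid

__all__ = [
    "ModelParams",
    "ConstraintTargets",
    "EnergyBreakdown",
    "f_field",
    "fc_field",
    "bending_energy_W",
    "volume_V",
    "area_A",
    "delta_area",
    "ade_energy_G",
    "penalties",
    "total_energy",
    "variational_g",
    "variational_h",
    "penalty_derivatives",
    "symmetrized_forms",
]

_AREA_CONST = 3.0 * sqrt(2.0) / 4.0  # A = (3*sqrt(2)/4) * B


@dataclass(frozen=True)
class ModelParams:
    """Physical and penalty parameters of the model.

    Parameters
    ----------
    epsilon : float
        Interface width (length units of the domain).
    kappa : float
        Bending modulus of the membrane.
    kappa_ade : float
        ADE modulus (``kbar``); 0 switches the ADE term off.
    C : float
        Twice the spontaneous curvature ``c0`` (1/length).
    D : float, optional
        Separation between the leaflet neutral surfaces.  Defaults to
        ``(2/3) * epsilon`` (roughly two-thirds of the bilayer thickness).
    M1, M2 : float
        Volume and surface-area penalty coefficients.
    """

    epsilon: float
    kappa: float = 1.0
    kappa_ade: float = 1.4
    C: float = 0.0
    D: float | None = None
    M1: float = 1.0e5
    M2: float = 1.0e4

    def __post_init__(self):
        if not self.epsilon > 0:
            raise ValueError("epsilon must be positive")
        if not self.kappa > 0:
            raise ValueError("kappa must be positive")
        if self.kappa_ade < 0 or self.M1 < 0 or self.M2 < 0:
            raise ValueError("kappa_ade, M1, M2 must be non-negative")
        if self.D is None:
            object.__setattr__(self, "D", 2.0 / 3.0 * self.epsilon)
        if not self.D > 0:
            raise ValueError("D must be positive")


@dataclass(frozen=True)
class ConstraintTargets:
    """Targets for the soft constraints and the ADE reference values.

    ``alpha`` is the target interior volume, ``beta`` the target membrane
    area, ``dA0`` the preferred (relaxed) leaflet area difference.  ``A0``
    is the reference area in the ADE prefactor and equals ``beta``; ``Rs``
    is the radius of the sphere with area ``beta``.
    """

    alpha: float
    beta: float
    dA0: float

    def __post_init__(self):
        if not self.beta > 0:
            raise InvalidTargetsError(f"target area must be positive, got {self.beta}")

    @property
    def A0(self) -> float:
        return self.beta

    @property
    def Rs(self) -> float:
        return sqrt(self.beta / (4.0 * pi))


@dataclass(frozen=True)
class EnergyBreakdown:
    """Energy components and shape observables at one time point."""

    W: float
    G: float
    T1: float
    T2: float
    E: float
    V: float
    A: float
    dA: float
    v: float
    da: float
    t: float = 0.0

    FIELDS = ("t", "W", "G", "T1", "T2", "E", "V", "A", "dA", "v", "da")

    def as_row(self) -> tuple:
        return tuple(getattr(self, name) for name in self.FIELDS)

    def at_time(self, t: float) -> "EnergyBreakdown":
        return replace(self, t=t)


# ----------------------------------------------------------------------
# pointwise fields
# ----------------------------------------------------------------------
def f_field(grid: PeriodicGrid, phi, params: ModelParams, lap=None):
    """Allen–Cahn operator ``f = eps*Lap(phi) - (1/eps)*(phi^2 - 1)*phi``."""
    if lap is None:
        lap = grid.laplacian(phi)
    e = params.epsilon
    return e * lap - (phi * phi - 1.0) * phi / e


def fc_field(grid: PeriodicGrid, phi, params: ModelParams, lap=None):
    """Spontaneous-curvature variant ``f_c = eps*Lap(phi) - (1/eps)*(phi^2-1)*(phi + C*eps)``."""
    if lap is None:
        lap = grid.laplacian(phi)
    e = params.epsilon
    return e * lap - (phi * phi - 1.0) * (phi + params.C * e) / e


# ----------------------------------------------------------------------
# energies and observables
# ----------------------------------------------------------------------
def bending_energy_W(grid, phi, params, lap=None) -> float:
    """Bending energy ``W = (kappa/(2*eps)) * Int f_c^2 dx`` (>= 0)."""
    fc = fc_field(grid, phi, params, lap=lap)
    return params.kappa / (2.0 * params.epsilon) * grid.integrate(fc * fc)


def volume_V(grid, phi) -> float:
    """Interior volume ``V = Int (phi + 1)/2 dx``."""
    return grid.integrate((phi + 1.0) * 0.5)


def area_A(grid, phi, params, lap=None) -> float:
    """Membrane area ``A = (3*sqrt(2)/4) * B(phi)``.

    ``B = Int eps/2 |grad phi|^2 + (1/(4 eps)) (phi^2 - 1)^2 dx`` with the
    gradient term evaluated as ``-Int phi * Lap(phi)`` (spectral, exact
    discrete integration by parts).
    """
    if lap is None:
        lap = grid.laplacian(phi)
    e = params.epsilon
    grad_sq = -grid.integrate(phi * lap)
    well = grid.integrate(np.square(phi * phi - 1.0))
    return _AREA_CONST * (0.5 * e * grad_sq + well / (4.0 * e))


def delta_area(grid, phi, params, lap=None) -> float:
    """Leaflet area difference ``dA``.

    Diffuse-interface form of ``D * Int 2H dA``:
    ``dA = -(3D/4) * Int (1 - phi^2) Lap(phi) + (1/eps^2) phi (1 - phi^2)^2 dx``.
    With interior = {phi > 0}, a sphere of radius R gives ``+8*pi*D*R``.
    """
    if lap is None:
        lap = grid.laplacian(phi)
    e = params.epsilon
    one_m = 1.0 - phi * phi
    integrand = one_m * lap + phi * np.square(one_m) / (e * e)
    return -0.75 * params.D * grid.integrate(integrand)


def ade_energy_G(grid, phi, params, targets: ConstraintTargets, dA=None) -> float:
    """ADE energy ``G = (kbar*pi/(2*A0*D^2)) * (dA - dA0)^2`` (>= 0)."""
    if targets.A0 <= 0:
        raise InvalidTargetsError("A0 must be positive")
    if dA is None:
        dA = delta_area(grid, phi, params)
    pref = params.kappa_ade * pi / (2.0 * targets.A0 * params.D**2)
    return pref * (dA - targets.dA0) ** 2


def penalties(grid, phi, params, targets, V=None, A=None) -> tuple[float, float]:
    """Quadratic constraint penalties ``(T1, T2)``."""
    if V is None:
        V = volume_V(grid, phi)
    if A is None:
        A = area_A(grid, phi, params)
    return (
        params.M1 * (V - targets.alpha) ** 2,
        params.M2 * (A - targets.beta) ** 2,
    )


def total_energy(grid, phi, params, targets, lap=None) -> EnergyBreakdown:
    """All energy components and observables; ``E = W + G + T1 + T2``."""
    if lap is None:
        lap = grid.laplacian(phi)
    W = bending_energy_W(grid, phi, params, lap=lap)
    V = volume_V(grid, phi)
    A = area_A(grid, phi, params, lap=lap)
    dA = delta_area(grid, phi, params, lap=lap)
    G = ade_energy_G(grid, phi, params, targets, dA=dA)
    T1, T2 = penalties(grid, phi, params, targets, V=V, A=A)
    if A > 0:
        Rs = sqrt(A / (4.0 * pi))
        v = V / (4.0 * pi / 3.0 * Rs**3)
        da = dA / (8.0 * pi * params.D * Rs)
    else:  # no interface; reduced parameters undefined
        v = np.nan
        da = np.nan
    return EnergyBreakdown(
        W=W, G=G, T1=T1, T2=T2, E=W + G + T1 + T2,
        V=V, A=A, dA=dA, v=v, da=da,
    )


# ----------------------------------------------------------------------
# variational derivatives
# ----------------------------------------------------------------------
def variational_g(grid, phi, params, lap=None, fc=None):
    """``g = Lap(f_c) - (1/eps^2)(3 phi^2 + 2 C eps phi - 1) f_c``;  dW/dphi = kappa*g."""
    if fc is None:
        fc = fc_field(grid, phi, params, lap=lap)
    e = params.epsilon
    cubic = 3.0 * phi * phi + 2.0 * params.C * e * phi - 1.0
    return grid.laplacian(fc) - cubic * fc / (e * e)


def variational_h(grid, phi, params, targets, lap=None, dA=None):
    """ADE derivative field ``h = dG/dphi``.

    ``h = -(3*kbar*pi/(4*A0*D)) * (dA - dA0) *
    [-2 phi Lap(phi) - Lap(phi^2) + (1/eps^2)(1 - 6 phi^2 + 5 phi^4)]``.
    The scalar ``(dA - dA0)`` is global and computed once per call.
    """
    if lap is None:
        lap = grid.laplacian(phi)
    if dA is None:
        dA = delta_area(grid, phi, params, lap=lap)
    e = params.epsilon
    phi2 = phi * phi
    bracket = (
        -2.0 * phi * lap
        - grid.laplacian(phi2)
        + (1.0 - 6.0 * phi2 + 5.0 * phi2 * phi2) / (e * e)
    )
    pref = -0.75 * params.kappa_ade * pi / (targets.A0 * params.D) * (dA - targets.dA0)
    return pref * bracket


def penalty_derivatives(grid, phi, params, targets, lap=None, f=None):
    """``(dT1/dphi, dT2/dphi)`` as fields.

    ``dT1/dphi = M1 (V - alpha)`` (a constant field);
    ``dT2/dphi = (3*sqrt(2)/2) M2 (A - beta) (-f)``.
    """
    if lap is None:
        lap = grid.laplacian(phi)
    if f is None:
        f = f_field(grid, phi, params, lap=lap)
    V = volume_V(grid, phi)
    A = area_A(grid, phi, params, lap=lap)
    dT1 = np.full(grid.shape, params.M1 * (V - targets.alpha))
    dT2 = (2.0 * _AREA_CONST) * params.M2 * (A - targets.beta) * (-f)
    return dT1, dT2


def symmetrized_forms(grid, phi, eta, params, targets):
    """Two-argument symmetric forms ``(f2, g2, h2)`` of the implicit scheme.

    Each reduces to its one-argument counterpart at ``eta == phi`` and is
    symmetric under argument swap; they satisfy exact discrete
    energy-difference identities, e.g.
    ``W(phi) - W(eta) = Int (phi - eta) * kappa * g2(phi, eta) dx``.
    """
    if phi.shape != eta.shape or phi.shape != grid.shape:
        raise ValueError("phi and eta must both live on the given grid")
    e = params.epsilon
    lap_phi = grid.laplacian(phi)
    lap_eta = grid.laplacian(eta)

    f2 = 0.5 * e * (lap_phi + lap_eta) - (
        (phi * phi + eta * eta - 2.0) * (phi + eta)
    ) / (4.0 * e)

    fc_sum = fc_field(grid, phi, params, lap=lap_phi) + fc_field(
        grid, eta, params, lap=lap_eta
    )
    s_factor = (
        phi * phi + phi * eta + eta * eta + params.C * e * (phi + eta) - 1.0
    )
    g2 = 0.5 * grid.laplacian(fc_sum) - s_factor * fc_sum / (2.0 * e * e)

    dA_phi = delta_area(grid, phi, params, lap=lap_phi)
    dA_eta = delta_area(grid, eta, params, lap=lap_eta)
    phi2 = phi * phi
    eta2 = eta * eta
    # Symmetric factorization of dA(phi) - dA(eta) = Int (phi-eta)*bracket:
    # quartic part (phi^5 - eta^5)/(phi - eta), quadratic part
    # -2*(phi^3 - eta^3)/(phi - eta), and the Laplacian terms paired so the
    # discrete integration by parts is exact.
    poly = (
        1.0
        - 2.0 * (phi2 + phi * eta + eta2)
        + phi2 * phi2
        + phi2 * phi * eta
        + phi2 * eta2
        + phi * eta2 * eta
        + eta2 * eta2
    )
    s = phi + eta
    bracket = (
        -0.5 * s * (lap_phi + lap_eta)
        - 0.5 * grid.laplacian(phi2 + eta2)
        + poly / (e * e)
    )
    pref = (
        -3.0 * params.kappa_ade * pi / (8.0 * targets.A0 * params.D)
        * (dA_phi + dA_eta - 2.0 * targets.dA0)
    )
    h2 = pref * bracket
    return f2, g2, h2
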