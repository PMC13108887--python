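"""Analytic tanh initial conditions and constraint-target derivation.

Initial phase fields are tanh profiles of implicit surfaces,

    phi0 = tanh( (r0 - sqrt(sum_i (x_i - c_i)^2 / d_i)) / (sqrt(2)*eps) )

for ellipsoids (zero level set: the ellipsoid with semi-axes
``sqrt(d_i) * r0``), and

    phi0 = tanh( max(r1 - dist1, r2 - dist2) / (sqrt(2)*eps) )

for the union of two spheres.  The experiment presets prescribe target
reduced volume ``v`` and reduced area difference ``da0``; the absolute
targets (alpha, beta, dA0) are derived from the measured area of the
initial field via beta = A(phi0), Rs = sqrt(beta/(4*pi)),
alpha = v * (4*pi/3) * Rs^3, dA0 = da0 * 8*pi*D*Rs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from math import pi, sqrt

import numpy as np

from .grid import PeriodicGrid
from .model import ConstraintTargets, ModelParams, area_A, volume_V

__all__ = [
    "ShapeSpec",
    "tanh_ellipsoid",
    "tanh_two_spheres",
    "make_initial_field",
    "derive_constraint_targets",
    "smooth_random_field",
]

_SQRT2 = sqrt(2.0)


@dataclass(frozen=True)
class ShapeSpec:
    """Geometry of an analytic initial condition.

    For ``kind='ellipsoid'``: ``center``, ``denominators`` (the ``d_i``
    under the squared coordinates; semi-axes are ``sqrt(d_i)*r0``) and the
    level-set offset ``r0``.  For ``kind='two_spheres'``: ``centers`` and
    ``radii`` of the two spheres whose union is taken.
    """

    kind: str  # 'ellipsoid' | 'two_spheres'
    center: tuple[float, float, float] = (0.5, 0.5, 0.5)
    denominators: tuple[float, float, float] = (0.5, 0.5, 0.1)
    r0: float = 0.35
    centers: tuple = ((0.5, 0.5, 0.4), (0.5, 0.5, 0.7))
    radii: tuple = (0.22, 0.4)

    def __post_init__(self):
        if self.kind not in ("ellipsoid", "two_spheres"):
            raise ValueError(f"unknown shape kind {self.kind!r}")
        if self.kind == "ellipsoid":
            if self.r0 <= 0 or any(d <= 0 for d in self.denominators):
                raise ValueError("ellipsoid parameters must be positive")
        else:
            if any(r <= 0 for r in self.radii):
                raise ValueError("sphere radii must be positive")


def _check_clearance(grid: PeriodicGrid, extent_per_axis, epsilon: float):
    """Warn when the shape comes within 3*eps of the periodic box faces."""
    for axis, (lo, hi) in enumerate(extent_per_axis):
        if lo < 3.0 * epsilon or hi > grid.L - 3.0 * epsilon:
            warnings.warn(
                f"initial shape within 3*eps of the domain boundary along axis "
                f"{axis} (extent [{lo:.3g}, {hi:.3g}] in [0, {grid.L:g}]); the "
                "periodic images may interact",
                stacklevel=3,
            )
            return


def tanh_ellipsoid(grid: PeriodicGrid, spec: ShapeSpec, epsilon: float) -> np.ndarray:
    """Tanh profile of an ellipsoidal level set; ~+1 inside, ~-1 outside."""
    X, Y, Z = grid.meshgrid()
    cx, cy, cz = spec.center
    dx, dy, dz = spec.denominators
    rho = np.sqrt((X - cx) ** 2 / dx + (Y - cy) ** 2 / dy + (Z - cz) ** 2 / dz)
    semi = [sqrt(d) * spec.r0 for d in spec.denominators]
    _check_clearance(
        grid,
        [(c - a, c + a) for c, a in zip(spec.center, semi)],
        epsilon,
    )
    return np.tanh((spec.r0 - rho) / (_SQRT2 * epsilon))


def tanh_two_spheres(grid: PeriodicGrid, spec: ShapeSpec, epsilon: float) -> np.ndarray:
    """Tanh profile of the union of two spheres: ``tanh(max_i(r_i - d_i)/(sqrt(2) eps))``."""
    X, Y, Z = grid.meshgrid()
    signed = None
    extents = [[np.inf, -np.inf] for _ in range(3)]
    for (cx, cy, cz), r in zip(spec.centers, spec.radii):
        d = np.sqrt((X - cx) ** 2 + (Y - cy) ** 2 + (Z - cz) ** 2)
        s = r - d
        signed = s if signed is None else np.maximum(signed, s)
        for axis, c in enumerate((cx, cy, cz)):
            extents[axis][0] = min(extents[axis][0], c - r)
            extents[axis][1] = max(extents[axis][1], c + r)
    _check_clearance(grid, extents, epsilon)
    return np.tanh(signed / (_SQRT2 * epsilon))


def make_initial_field(grid: PeriodicGrid, spec: ShapeSpec, epsilon: float) -> np.ndarray:
    """Dispatch on ``spec.kind``."""
    if spec.kind == "ellipsoid":
        return tanh_ellipsoid(grid, spec, epsilon)
    return tanh_two_spheres(grid, spec, epsilon)


def derive_constraint_targets(
    grid: PeriodicGrid,
    phi0: np.ndarray,
    v_target: float,
    da0_target: float,
    params: ModelParams,
    alpha_from_field: bool = False,
) -> ConstraintTargets:
    """Derive (alpha, beta, dA0) from the initial field and (v, da0).

    beta is the measured area of ``phi0`` (the area constraint is anchored
    to the initial condition); Rs = sqrt(beta/(4*pi)); the prescribed
    reduced volume and reduced area difference then fix
    alpha = v * (4*pi/3) * Rs^3 and dA0 = da0 * 8*pi*D*Rs.  With
    ``alpha_from_field`` the measured volume of ``phi0`` is used instead
    of the reduced-volume target.
    """
    beta = area_A(grid, phi0, params)
    if not beta > 0 or not np.isfinite(beta):
        raise ValueError("initial field has no interface (zero measured area)")
    Rs = sqrt(beta / (4.0 * pi))
    if alpha_from_field:
        alpha = volume_V(grid, phi0)
    else:
        alpha = v_target * (4.0 * pi / 3.0) * Rs**3
    dA0 = da0_target * 8.0 * pi * params.D * Rs
    return ConstraintTargets(alpha=alpha, beta=beta, dA0=dA0)


def smooth_random_field(
    grid: PeriodicGrid,
    rng: np.random.Generator,
    kmax_frac: float = 0.25,
    amplitude: float = 1.0,
) -> np.ndarray:
    """Band-limited random field (low-pass-filtered white noise).

    Used for symmetry-breaking perturbations and as "random smooth field"
    input in verification routines.  ``kmax_frac`` is the retained fraction
    of the Nyquist wavenumber; the result is scaled to the given max-norm
    amplitude.
    """
    noise = rng.standard_normal(grid.shape)
    k_nyq = pi / grid.h
    mask = grid.k2 <= (kmax_frac * k_nyq) ** 2
    u = grid.ifft(grid.fft(noise) * mask)
    m = np.max(np.abs(u))
    if m == 0:
        return u
    return amplitude / m * u
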