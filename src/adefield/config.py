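"""Run configuration and the experiment preset registry.

A :class:`RunConfig` fully determines a simulation: grid, model
parameters, stepper settings, the analytic initial shape, and the target
reduced volume / reduced area difference from which the absolute
constraint targets are derived.  Presets bundle the standard experiment
parameter sets; defaults (unless a preset overrides them) are
a unit box at 64^3, kappa=1, kbar=1.4, M1=1e5, M2=1e4, C=0 and
D = (2/3)*epsilon.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .dynamics import StepperConfig
from .exceptions import ConfigError
from .grid import PeriodicGrid, make_grid
from .model import ConstraintTargets, ModelParams
from .shapes import ShapeSpec, derive_constraint_targets, make_initial_field, smooth_random_field

__all__ = ["RunConfig", "preset", "PRESET_NAMES", "load_config", "save_config", "build_run"]


@dataclass
class RunConfig:
    """Complete, deterministic description of one simulation run."""

    L: float = 1.0
    N: int = 64
    epsilon: float = 0.04
    kappa: float = 1.0
    kappa_ade: float = 1.4
    C: float = 0.0
    D: float | None = None  # default (2/3)*epsilon
    M1: float = 1.0e5
    M2: float = 1.0e4
    scheme: str = "semi_implicit"
    dt: float = 1.0e-6
    max_steps: int = 100_000
    log_every: int = 100
    snapshot_every: int = 10_000
    steady_rate_tol: float = 1.0e-3
    steady_window: int = 100
    shape: ShapeSpec = field(default_factory=ShapeSpec)
    v: float | None = 0.8
    da0: float | None = 1.2
    alpha_from_field: bool = False
    output_dir: str = "output"
    perturbation_seed: int | None = None
    perturbation_amplitude: float = 0.01
    preset: str | None = None

    def model_params(self) -> ModelParams:
        return ModelParams(
            epsilon=self.epsilon, kappa=self.kappa, kappa_ade=self.kappa_ade,
            C=self.C, D=self.D, M1=self.M1, M2=self.M2,
        )

    def stepper_config(self) -> StepperConfig:
        return StepperConfig(
            scheme=self.scheme, dt=self.dt, max_steps=self.max_steps,
            log_every=self.log_every, steady_rate_tol=self.steady_rate_tol,
            steady_window=self.steady_window,
        )


def _ellipsoid(center, denominators, r0) -> ShapeSpec:
    return ShapeSpec(kind="ellipsoid", center=center, denominators=denominators, r0=r0)


_C = (0.5, 0.5, 0.5)
# Initial ellipsoids of the bundled experiments; denominators are the
# values under the squared coordinates, so semi-axes are sqrt(d_i)*r0.
_SHAPE_OBLATE = _ellipsoid(_C, (0.5, 0.5, 0.1), 0.35)
_SHAPE_PROLATE = _ellipsoid(_C, (0.2**2, 0.2**2, 0.35**2), 0.5)
_SHAPE_SPHERE_035 = _ellipsoid(_C, (0.35**2, 0.35**2, 0.35**2), 0.5)
_SHAPE_OBLATE_4ARM = _ellipsoid(_C, (0.35**2, 0.35**2, 0.15**2), 0.5)
_SHAPE_SPHERE_6ARM = _ellipsoid(_C, (0.35**2, 0.35**2, 0.35**2), 0.6)
_SHAPE_NESTED = _ellipsoid((1.0, 1.0, 1.0), (0.16, 0.16, 0.16), 1.0)
_SHAPE_TWO_SPHERES = ShapeSpec(
    kind="two_spheres",
    centers=((0.5, 0.5, 0.4), (0.5, 0.5, 0.7)),
    radii=(0.22, 0.4),
)


def _budding(da0: float) -> dict:
    return dict(epsilon=0.02, dt=5.0e-7, v=0.9, da0=da0, shape=_SHAPE_PROLATE)


_PRESETS: dict[str, dict] = {
    "discocyte": dict(epsilon=0.04, dt=1.0e-6, v=0.8, da0=1.2, shape=_SHAPE_OBLATE),
    "torus": dict(epsilon=0.04, dt=1.0e-6, v=0.8, da0=1.4, shape=_SHAPE_OBLATE),
    "budding_a": _budding(1.1),
    "budding_b": _budding(1.4),
    "budding_c": _budding(1.5),
    "budding_d": _budding(1.6),
    "budding_e": _budding(1.7),
    "budding_f": _budding(1.8),
    # Same parameters as budding_b; the chain-like outcome depends on
    # details beyond these parameters (see docs/methods.md).
    "chain": _budding(1.4),
    "arms3": dict(epsilon=0.02, dt=1.0e-7, v=0.8, da0=1.4, shape=_SHAPE_SPHERE_035),
    "arms4": dict(epsilon=0.02, dt=2.0e-7, v=0.8, da0=1.6, shape=_SHAPE_OBLATE_4ARM),
    "arms6": dict(epsilon=0.02, dt=1.0e-7, v=0.6, da0=1.0, shape=_SHAPE_SPHERE_6ARM),
    "nested": dict(
        L=2.0, N=100, epsilon=0.03, kappa_ade=4.0, M1=1.0e4, M2=1.0e4,
        dt=5.0e-7, v=0.6, da0=1.1, shape=_SHAPE_NESTED,
    ),
    # Pear shapes need user-supplied (v, da0) plus parameter continuation.
    "pear": dict(epsilon=0.02, dt=5.0e-7, v=None, da0=None, shape=_SHAPE_TWO_SPHERES),
    # Temporal-convergence study configuration (discocyte physics).
    "cauchy_table1": dict(epsilon=0.04, dt=2.0e-7, v=0.8, da0=1.2, shape=_SHAPE_OBLATE),
}

PRESET_NAMES = tuple(sorted(_PRESETS))


def preset(name: str, **overrides) -> RunConfig:
    """Return the RunConfig of a named experiment preset."""
    if name not in _PRESETS:
        raise ConfigError(
            f"unknown preset {name!r}; valid presets: {', '.join(PRESET_NAMES)}"
        )
    kwargs = dict(_PRESETS[name])
    kwargs.update(overrides)
    return RunConfig(preset=name, **kwargs)


# ----------------------------------------------------------------------
# (de)serialization
# ----------------------------------------------------------------------
def _to_dict(cfg: RunConfig) -> dict:
    d = dataclasses.asdict(cfg)
    d["shape"] = dataclasses.asdict(cfg.shape)
    return d


def save_config(cfg: RunConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(_to_dict(cfg), sort_keys=False))


def _from_dict(data: dict) -> RunConfig:
    if not isinstance(data, dict):
        raise ConfigError("config root must be a mapping")
    data = dict(data)
    shape_data = data.pop("shape", None)
    allowed = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(data) - allowed
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    if shape_data is not None:
        shape_allowed = {f.name for f in dataclasses.fields(ShapeSpec)}
        unknown = set(shape_data) - shape_allowed
        if unknown:
            raise ConfigError(f"unknown shape keys: {sorted(unknown)}")
        for key in ("center", "denominators", "centers", "radii"):
            if key in shape_data:
                val = shape_data[key]
                if key == "centers":
                    val = tuple(tuple(c) for c in val)
                else:
                    val = tuple(val)
                shape_data[key] = val
        data["shape"] = ShapeSpec(**shape_data)
    return RunConfig(**data)


def load_config(path) -> RunConfig:
    """Load a YAML run configuration; unknown keys are errors."""
    data = yaml.safe_load(Path(path).read_text())
    return _from_dict(data)


def build_run(cfg: RunConfig):
    """Materialize a configuration.

    Returns ``(grid, phi0, params, targets, stepper_cfg)``.  The optional
    seeded perturbation adds small-amplitude band-limited noise to the
    initial field for symmetry breaking.
    """
    if cfg.v is None or cfg.da0 is None:
        raise ConfigError(
            "targets (v, da0) are required for this run (the 'pear' preset "
            "leaves them as user inputs)"
        )
    grid = make_grid(cfg.L, cfg.N)
    params = cfg.model_params()
    phi0 = make_initial_field(grid, cfg.shape, cfg.epsilon)
    targets = derive_constraint_targets(
        grid, phi0, cfg.v, cfg.da0, params, alpha_from_field=cfg.alpha_from_field
    )
    if cfg.perturbation_seed is not None:
        rng = np.random.default_rng(cfg.perturbation_seed)
        phi0 = phi0 + smooth_random_field(
            grid, rng, amplitude=cfg.perturbation_amplitude
        )
    return grid, phi0, params, targets, cfg.stepper_config()
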