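"""Shape diagnostics for steady-state classification.

Morphologies are classified from the voxel mask {phi > 0} (the interior,
per the level-set convention): reduced volume and reduced area difference,
periodic connected-component counts (fission and nested states), arm
counts for starfish-like shapes, and a reflection-asymmetry score for
pear shapes.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import pi, sqrt

import numpy as np
from scipy import ndimage
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from .grid import PeriodicGrid
from .model import ConstraintTargets, ModelParams, area_A, delta_area, volume_V

__all__ = [
    "ShapeMetrics",
    "reduced_parameters",
    "count_regions",
    "count_arms",
    "reflection_asymmetry",
    "shape_metrics",
]


@dataclass(frozen=True)
class ShapeMetrics:
    """Summary diagnostics of one phase-field configuration."""

    v: float
    da: float
    n_interior_components: int
    n_exterior_components: int
    n_membrane_components: int
    n_arms: int
    asymmetry: float
    principal_moments: tuple[float, float, float]


def reduced_parameters(
    grid: PeriodicGrid, phi, params: ModelParams
) -> tuple[float, float]:
    """Reduced volume and reduced area difference of the current field.

    ``v = V / ((4 pi/3) Rs^3)`` and ``da = dA / (8 pi D Rs)`` with
    ``Rs = sqrt(A/(4 pi))`` from the current area; both equal 1 for a
    sphere.
    """
    A = area_A(grid, phi, params)
    if not A > 0:
        raise ValueError("field has no interface (vanishing area)")
    Rs = sqrt(A / (4.0 * pi))
    v = volume_V(grid, phi) / (4.0 * pi / 3.0 * Rs**3)
    da = delta_area(grid, phi, params) / (8.0 * pi * params.D * Rs)
    return v, da


# ----------------------------------------------------------------------
# connected components with periodic wrap
# ----------------------------------------------------------------------
def _label_periodic(mask: np.ndarray, connectivity: int, periodic: bool):
    """Label a voxel mask; optionally merge labels across periodic faces.

    Returns ``(labels, count)``; labels are arbitrary but consistent.
    """
    if connectivity not in (6, 26):
        raise ValueError("connectivity must be 6 or 26")
    structure = ndimage.generate_binary_structure(3, 1 if connectivity == 6 else 3)
    labels, n = ndimage.label(mask, structure=structure)
    if n == 0 or not periodic:
        return labels, n
    # Merge labels adjacent across the wrap: for every half-stencil offset,
    # voxels in the mask adjacent to a shifted copy of the mask belong to
    # the same component.  np.roll wraps, so this covers the periodic faces
    # (and harmlessly revisits interior adjacencies already merged).
    offsets = []
    rng = (-1, 0, 1)
    for dx in rng:
        for dy in rng:
            for dz in rng:
                if (dx, dy, dz) <= (0, 0, 0):
                    continue
                if connectivity == 6 and abs(dx) + abs(dy) + abs(dz) != 1:
                    continue
                offsets.append((dx, dy, dz))
    pairs = []
    for off in offsets:
        rolled = np.roll(labels, shift=off, axis=(0, 1, 2))
        both = (labels > 0) & (rolled > 0)
        if np.any(both):
            pairs.append(np.stack([labels[both], rolled[both]], axis=1))
    if pairs:
        edges = np.unique(np.concatenate(pairs, axis=0), axis=0)
        graph = coo_matrix(
            (np.ones(len(edges)), (edges[:, 0] - 1, edges[:, 1] - 1)),
            shape=(n, n),
        )
        n_merged, comp = connected_components(graph, directed=False)
        out = np.zeros_like(labels)
        nz = labels > 0
        out[nz] = comp[labels[nz] - 1] + 1
        return out, n_merged
    return labels, n


def count_regions(
    grid: PeriodicGrid,
    phi,
    side: str = "interior",
    connectivity: int = 6,
    periodic: bool = True,
) -> int:
    """Number of connected regions of {phi > 0} (interior) or {phi < 0}.

    The membrane sheet count reported by :func:`shape_metrics` is
    ``interior + exterior - 1`` (each additional sheet separates one more
    pair of regions).
    """
    if side == "interior":
        mask = phi > 0.0
    elif side == "exterior":
        mask = phi < 0.0
    else:
        raise ValueError("side must be 'interior' or 'exterior'")
    _, n = _label_periodic(mask, connectivity, periodic)
    return int(n)


# ----------------------------------------------------------------------
# geometry relative to the (periodic) centroid
# ----------------------------------------------------------------------
def _periodic_centroid(grid: PeriodicGrid, mask: np.ndarray) -> np.ndarray:
    """Centroid of a voxel mask on the torus, via the circular mean."""
    if not np.any(mask):
        raise ValueError("empty interior")
    coords = np.nonzero(mask)
    c = np.empty(3)
    for axis in range(3):
        theta = 2.0 * pi * grid.x[coords[axis]] / grid.L
        ang = np.arctan2(np.mean(np.sin(theta)), np.mean(np.cos(theta)))
        c[axis] = (ang % (2.0 * pi)) * grid.L / (2.0 * pi)
    return c


def _minimal_image(r: np.ndarray, L: float) -> np.ndarray:
    return (r + 0.5 * L) % L - 0.5 * L


def _relative_coords(grid: PeriodicGrid, mask: np.ndarray, centroid: np.ndarray):
    coords = np.stack(np.nonzero(mask), axis=1) * grid.h
    return _minimal_image(coords - centroid, grid.L)


def count_arms(grid: PeriodicGrid, phi, core_fraction: float = 0.5) -> int:
    """Number of arm-like protrusions of the interior.

    The interior voxels farther than ``core_fraction`` times the maximum
    centroid distance form the shell; its periodic connected components
    are the candidate arms.  A single shell component wraps around a
    round/compact body rather than marking a protrusion, so counts below
    2 are reported as 0 (a tanh sphere has 0 arms).
    """
    mask = phi > 0.0
    centroid = _periodic_centroid(grid, mask)
    rel = _relative_coords(grid, mask, centroid)
    dist = np.linalg.norm(rel, axis=1)
    r_c = core_fraction * dist.max()
    shell = np.zeros(grid.shape, dtype=bool)
    idx = np.nonzero(mask)
    far = dist > r_c
    shell[idx[0][far], idx[1][far], idx[2][far]] = True
    _, n = _label_periodic(shell, 6, True)
    return int(n) if n >= 2 else 0


def _principal_axes(rel: np.ndarray):
    """Eigen-decomposition of the interior second-moment matrix."""
    cov = rel.T @ rel / len(rel)
    evals, evecs = np.linalg.eigh(cov)
    return evals, evecs  # ascending order


def reflection_asymmetry(grid: PeriodicGrid, phi) -> float:
    """Reflection-asymmetry score in [0, 1]; 0 for mirror-symmetric shapes.

    The field is reflected about the plane through the interior centroid
    normal to the principal (longest) axis of the interior indicator, by
    cubic interpolation with periodic wrap, and the score is
    ``||phi - phi_reflected||_1 / ||phi + 1||_1``.
    """
    mask = phi > 0.0
    centroid = _periodic_centroid(grid, mask)
    rel = _relative_coords(grid, mask, centroid)
    evals, evecs = _principal_axes(rel)
    axis = evecs[:, -1]  # largest spread = elongation axis

    X, Y, Z = grid.meshgrid()
    r = np.stack([X - centroid[0], Y - centroid[1], Z - centroid[2]])
    r = _minimal_image(r, grid.L)
    proj = axis[0] * r[0] + axis[1] * r[1] + axis[2] * r[2]
    refl = [
        (centroid[i] + r[i] - 2.0 * proj * axis[i]) / grid.h for i in range(3)
    ]
    phi_ref = ndimage.map_coordinates(phi, refl, order=3, mode="grid-wrap")
    num = float(np.sum(np.abs(phi - phi_ref)))
    den = float(np.sum(np.abs(phi + 1.0)))
    if den == 0:
        return 0.0
    return float(np.clip(num / den, 0.0, 1.0))


def shape_metrics(
    grid: PeriodicGrid,
    phi,
    params: ModelParams,
    connectivity: int = 6,
    core_fraction: float = 0.5,
) -> ShapeMetrics:
    """All diagnostics in one record."""
    v, da = reduced_parameters(grid, phi, params)
    n_in = count_regions(grid, phi, "interior", connectivity)
    n_ex = count_regions(grid, phi, "exterior", connectivity)
    mask = phi > 0.0
    rel = _relative_coords(grid, mask, _periodic_centroid(grid, mask))
    evals, _ = _principal_axes(rel)
    return ShapeMetrics(
        v=v,
        da=da,
        n_interior_components=n_in,
        n_exterior_components=n_ex,
        n_membrane_components=n_in + n_ex - 1,
        n_arms=count_arms(grid, phi, core_fraction),
        asymmetry=reflection_asymmetry(grid, phi),
        principal_moments=tuple(float(e) for e in evals),
    )
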