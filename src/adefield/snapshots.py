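"""Field snapshot writers/readers and the energy-log CSV.

Two snapshot formats: legacy ASCII VTK STRUCTURED_POINTS (for ParaView
and friends) and an HDF5 container carrying the field plus full metadata
for exact restart; the HDF5 reader is the exact inverse of the writer.
"""

from __future__ import annotations

import csv
from pathlib import Path

import h5py
import numpy as np

from .exceptions import ConfigError
from .grid import PeriodicGrid, make_grid
from .model import EnergyBreakdown

__all__ = ["write_vtk", "write_snapshot", "read_snapshot", "write_energy_csv"]


def write_vtk(path, grid: PeriodicGrid, field: np.ndarray, name: str = "phi") -> None:
    """Write a scalar field as legacy ASCII VTK STRUCTURED_POINTS."""
    N, h = grid.N, grid.h
    lines = [
        "# vtk DataFile Version 3.0",
        f"adefield scalar field {name}",
        "ASCII",
        "DATASET STRUCTURED_POINTS",
        f"DIMENSIONS {N} {N} {N}",
        "ORIGIN 0 0 0",
        f"SPACING {h:.17g} {h:.17g} {h:.17g}",
        f"POINT_DATA {N**3}",
        f"SCALARS {name} double 1",
        "LOOKUP_TABLE default",
    ]
    # VTK structured points vary x fastest; our arrays are indexed [x,y,z].
    flat = np.asarray(field).transpose(2, 1, 0).ravel()
    body = "\n".join(" ".join(f"{v:.9g}" for v in row) for row in flat.reshape(-1, grid.N))
    Path(path).write_text("\n".join(lines) + "\n" + body + "\n")


def write_snapshot(path, grid: PeriodicGrid, field: np.ndarray, metadata: dict) -> None:
    """Write field + metadata to an HDF5 container (bit-exact restart)."""
    with h5py.File(path, "w") as f:
        f.create_dataset("phi", data=np.asarray(field, dtype=np.float64))
        f.attrs["L"] = grid.L
        f.attrs["N"] = grid.N
        for key, val in metadata.items():
            if val is None:
                continue
            f.attrs[key] = val


def read_snapshot(path, expected_grid: PeriodicGrid | None = None):
    """Read an HDF5 snapshot; returns ``(grid, field, metadata)``.

    If ``expected_grid`` is given, a mismatching stored grid is an error
    (guards restarts against the wrong configuration).
    """
    with h5py.File(path, "r") as f:
        phi = f["phi"][...]
        meta = dict(f.attrs)
    L, N = float(meta.pop("L")), int(meta.pop("N"))
    if phi.shape != (N, N, N):
        raise ConfigError(
            f"snapshot {path}: field shape {phi.shape} inconsistent with N={N}"
        )
    grid = make_grid(L, N)
    if expected_grid is not None and grid != expected_grid:
        raise ConfigError(
            f"snapshot {path}: grid (L={L}, N={N}) does not match expected "
            f"(L={expected_grid.L}, N={expected_grid.N})"
        )
    return grid, phi, meta


def write_energy_csv(path, series: list[EnergyBreakdown]) -> None:
    """Write the logged energy/observable series with the standard columns."""
    with open(path, "w", newline="") as f:
        writer = csv.writer(f)
        writer.writerow(EnergyBreakdown.FIELDS)
        for record in series:
            writer.writerow(f"{x:.12g}" for x in record.as_row())
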