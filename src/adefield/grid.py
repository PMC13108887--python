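"""Periodic uniform 3D grid and Fourier-spectral operators.

All simulations live on a cubic box ``[0, L)^3`` with periodic boundary
conditions, discretized by ``N`` collocation nodes per axis at
``x_i = i * h``, ``h = L / N``.  Differential operators are diagonal in
the discrete Fourier basis: the Laplacian acts as multiplication by
``-|k|^2`` with ``k_j = 2*pi*m_j / L``.  Real fields are transformed with
the real-input FFT, so every operator output is real by construction.

The quadrature rule is the periodic trapezoid (= rectangle) rule
``h^3 * sum(u)``, which is spectrally accurate for smooth periodic
integrands.
"""

from __future__ import annotations

import numpy as np

from .exceptions import GridError, StabilityError

__all__ = ["PeriodicGrid", "make_grid"]


class PeriodicGrid:
    """Uniform periodic grid on ``[0, L)^3`` with spectral wavenumbers.

    Parameters
    ----------
    L : float
        Edge length of the cubic domain (dimensionless units).
    N : int
        Number of collocation nodes per axis; must be at least 4.

    Attributes
    ----------
    h : float
        Grid spacing ``L / N`` (``h * N == L`` exactly).
    x : ndarray, shape (N,)
        Node coordinates ``i * h`` along one axis.
    k : ndarray, shape (N,)
        Angular wavenumbers ``2*pi*m/L`` in standard FFT ordering.
    k2 : ndarray, shape (N, N, N//2 + 1)
        ``|k|^2`` on the half-spectrum layout of the real FFT.
    """

    def __init__(self, L: float, N: int):
        if not float(L) > 0:
            raise GridError(f"domain length must be positive, got L={L}")
        N = int(N)
        if N < 4:
            raise GridError(f"need at least 4 nodes per axis, got N={N}")
        self.L = float(L)
        self.N = N
        self.h = self.L / N
        self.shape = (N, N, N)
        self.x = self.h * np.arange(N)
        self.k = 2.0 * np.pi * np.fft.fftfreq(N, d=self.h)
        kr = 2.0 * np.pi * np.fft.rfftfreq(N, d=self.h)
        kx = self.k[:, None, None]
        ky = self.k[None, :, None]
        kz = kr[None, None, :]
        self.k2 = kx**2 + ky**2 + kz**2
        self._mesh = None

    def __repr__(self):  # pragma: no cover - cosmetic
        return f"PeriodicGrid(L={self.L!r}, N={self.N})"

    def __eq__(self, other):
        return (
            isinstance(other, PeriodicGrid)
            and other.L == self.L
            and other.N == self.N
        )

    def __hash__(self):
        return hash((self.L, self.N))

    # ------------------------------------------------------------------
    # transforms and basic calculus
    # ------------------------------------------------------------------
    def meshgrid(self):
        """Return ``(X, Y, Z)`` coordinate arrays (cached, read-only)."""
        if self._mesh is None:
            X, Y, Z = np.meshgrid(self.x, self.x, self.x, indexing="ij")
            for a in (X, Y, Z):
                a.setflags(write=False)
            self._mesh = (X, Y, Z)
        return self._mesh

    def fft(self, u: np.ndarray) -> np.ndarray:
        return np.fft.rfftn(u)

    def ifft(self, u_hat: np.ndarray) -> np.ndarray:
        return np.fft.irfftn(u_hat, s=self.shape, axes=(0, 1, 2))

    def laplacian(self, u: np.ndarray) -> np.ndarray:
        """Spectral Laplacian: multiplication by ``-|k|^2`` in Fourier space."""
        return self.ifft(-self.k2 * self.fft(u))

    def integrate(self, u: np.ndarray) -> float:
        """Periodic trapezoid quadrature ``h^3 * sum(u)``."""
        return float(self.h**3 * np.sum(u))

    def l2_norm(self, u: np.ndarray) -> float:
        """Continuum-normalized L2 norm ``sqrt(h^3 * sum(u^2))``."""
        return float(np.sqrt(self.h**3 * np.sum(np.square(u))))

    # ------------------------------------------------------------------
    # constant-coefficient implicit solves
    # ------------------------------------------------------------------
    def _symbol(self, s0: float, s2: float, s4: float) -> np.ndarray:
        # Laplacian symbol is -k2, biharmonic symbol is +k2^2.
        return s0 - s2 * self.k2 + s4 * self.k2**2

    def apply_implicit_operator(
        self, u: np.ndarray, s0: float, s2: float, s4: float
    ) -> np.ndarray:
        """Apply ``(s0 + s2*Lap + s4*Lap^2)`` to ``u`` spectrally."""
        return self.ifft(self._symbol(s0, s2, s4) * self.fft(u))

    def solve_implicit_operator(
        self, rhs: np.ndarray, s0: float, s2: float, s4: float
    ) -> np.ndarray:
        """Solve ``(s0 + s2*Lap + s4*Lap^2) u = rhs`` diagonally in Fourier space.

        The symbol ``s0 - s2|k|^2 + s4|k|^4`` must be strictly positive at
        every retained mode; a non-positive symbol signals a time step too
        large for the semi-implicit scheme and raises :class:`StabilityError`.
        """
        sym = self._symbol(s0, s2, s4)
        i_min = np.unravel_index(np.argmin(sym), sym.shape)
        if sym[i_min] <= 0.0:
            raise StabilityError(
                f"implicit operator symbol {sym[i_min]:.3e} <= 0 at mode index "
                f"{tuple(int(i) for i in i_min)} (|k|^2={self.k2[i_min]:.4g}); "
                "reduce the time step or check parameters"
            )
        return self.ifft(self.fft(rhs) / sym)


def make_grid(L: float, N: int) -> PeriodicGrid:
    """Construct a :class:`PeriodicGrid` (validates ``L > 0`` and ``N >= 4``)."""
    return PeriodicGrid(L, N)
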