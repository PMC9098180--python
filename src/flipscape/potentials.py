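"""Analytic test potentials with known stationary points.

These surfaces serve as desk-scale targets for the minimizers, saddle
searches and kinetics machinery: every stationary point can be enumerated
independently by grid scans plus Newton refinement, so each pipeline stage
can be validated against a brute-force oracle before it is let loose on the
coarse-grained duplex model.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Potential",
    "DoubleWell",
    "MullerBrown",
    "fd_gradient",
    "fd_hessian",
]


class Potential:
    """Base class for an energy surface.

    Subclasses provide :meth:`energy` and :meth:`gradient`; the Hessian
    defaults to symmetric finite differences of the analytic gradient.

    Attributes
    ----------
    dimension : int
        Number of Cartesian coordinates.
    name : str
        Human-readable label used in databases and logs.
    n_rigid_modes : int
        Number of zero Hessian modes expected at any stationary point
        (6 for a 3-D many-bead system, 0 for point particles on a model
        surface).
    """

    dimension: int = 0
    name: str = "potential"
    n_rigid_modes: int = 0
    #: beads-in-3-D flag: coordinates reshape to (n_beads, 3) and structural
    #: comparisons use rigid-body superposition.
    cartesian_beads: bool = False
    hessian_step: float = 1e-5

    def energy(self, x: np.ndarray) -> float:
        raise NotImplementedError

    def gradient(self, x: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def energy_gradient(self, x: np.ndarray) -> tuple[float, np.ndarray]:
        return self.energy(x), self.gradient(x)

    def hessian(self, x: np.ndarray) -> np.ndarray:
        x = _check_point(x, self.dimension)
        return fd_hessian(self.gradient, x, step=self.hessian_step)

    def rms_gradient(self, x: np.ndarray) -> float:
        g = self.gradient(x)
        return float(np.sqrt(np.mean(g * g)))


def _check_point(x, dimension: int) -> np.ndarray:
    x = np.asarray(x, dtype=float).ravel()
    if dimension and x.size != dimension:
        raise ValueError(f"expected {dimension} coordinates, got {x.size}")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite coordinates")
    return x


def fd_gradient(energy, x: np.ndarray, step: float = 1e-6) -> np.ndarray:
    """Central finite-difference gradient of a scalar function."""
    x = np.asarray(x, dtype=float)
    g = np.empty_like(x)
    for i in range(x.size):
        xp = x.copy()
        xm = x.copy()
        xp[i] += step
        xm[i] -= step
        g[i] = (energy(xp) - energy(xm)) / (2.0 * step)
    return g


def fd_hessian(gradient, x: np.ndarray, step: float = 1e-5) -> np.ndarray:
    """Symmetrized central finite-difference Hessian of a gradient field."""
    x = np.asarray(x, dtype=float)
    n = x.size
    h = np.empty((n, n))
    for i in range(n):
        xp = x.copy()
        xm = x.copy()
        xp[i] += step
        xm[i] -= step
        h[i] = (gradient(xp) - gradient(xm)) / (2.0 * step)
    return 0.5 * (h + h.T)


class DoubleWell(Potential):
    """One-dimensional quartic double well, V(x) = (x^2 - 1)^2.

    Minima at x = -1 and x = +1 with V = 0; a single index-1 point at
    x = 0 with V = 1.
    """

    dimension = 1
    name = "double_well"
    n_rigid_modes = 0

    def energy(self, x) -> float:
        x = _check_point(x, 1)[0]
        return float((x * x - 1.0) ** 2)

    def gradient(self, x) -> np.ndarray:
        x = _check_point(x, 1)[0]
        return np.array([4.0 * x * (x * x - 1.0)])

    def hessian(self, x) -> np.ndarray:
        x = _check_point(x, 1)[0]
        return np.array([[12.0 * x * x - 4.0]])


# Canonical four-Gaussian surface constants.
_MB_A = np.array([-200.0, -100.0, -170.0, 15.0])
_MB_a = np.array([-1.0, -1.0, -6.5, 0.7])
_MB_b = np.array([0.0, 0.0, 11.0, 0.6])
_MB_c = np.array([-10.0, -10.0, -6.5, 0.7])
_MB_x0 = np.array([1.0, 0.0, -0.5, -1.0])
_MB_y0 = np.array([0.0, 0.5, 1.5, 1.0])


class MullerBrown(Potential):
    """The Muller-Brown surface: sum of four anisotropic Gaussians.

    Three minima and two index-1 saddles; the global minimum sits near
    (-0.558, 1.442) with V approximately -146.700.
    """

    dimension = 2
    name = "muller_brown"
    n_rigid_modes = 0

    def _terms(self, x):
        dx = x[0] - _MB_x0
        dy = x[1] - _MB_y0
        expo = _MB_a * dx * dx + _MB_b * dx * dy + _MB_c * dy * dy
        # clip to keep far-field evaluations finite (the A4 term grows)
        return dx, dy, _MB_A * np.exp(np.minimum(expo, 500.0))

    def energy(self, x) -> float:
        x = _check_point(x, 2)
        return float(self._terms(x)[2].sum())

    def gradient(self, x) -> np.ndarray:
        x = _check_point(x, 2)
        dx, dy, t = self._terms(x)
        gx = np.sum(t * (2.0 * _MB_a * dx + _MB_b * dy))
        gy = np.sum(t * (_MB_b * dx + 2.0 * _MB_c * dy))
        return np.array([gx, gy])

    def hessian(self, x) -> np.ndarray:
        x = _check_point(x, 2)
        dx, dy, t = self._terms(x)
        u = 2.0 * _MB_a * dx + _MB_b * dy
        v = _MB_b * dx + 2.0 * _MB_c * dy
        hxx = np.sum(t * (u * u + 2.0 * _MB_a))
        hyy = np.sum(t * (v * v + 2.0 * _MB_c))
        hxy = np.sum(t * (u * v + _MB_b))
        return np.array([[hxx, hxy], [hxy, hyy]])


def muller_brown(point) -> tuple[float, np.ndarray, np.ndarray]:
    """Energy, gradient and Hessian of the Muller-Brown surface at ``point``."""
    pot = MullerBrown()
    x = _check_point(point, 2)
    return pot.energy(x), pot.gradient(x), pot.hessian(x)


def double_well(x) -> tuple[float, float]:
    """Energy and gradient of the 1-D quartic double well at ``x``."""
    pot = DoubleWell()
    return pot.energy(x), float(pot.gradient(x)[0])
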