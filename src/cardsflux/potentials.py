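"""Analytic collective-variable potentials.

These serve as ground-truth free-energy surfaces for the enhanced-sampling
stage: a particle diffusing on one of these potentials stands in for the
projection of a full molecular system onto its collective variables (CVs),
so bias-deposition and path-finding machinery can be validated against
closed-form energies. Energies are in kJ/mol, CV coordinates in abstract
length units.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize

__all__ = [
    "AnalyticPotential",
    "Harmonic",
    "DoubleWell1D",
    "DoubleWell2D",
    "QuadraticBowl",
]


class AnalyticPotential:
    """A smooth potential on d-dimensional CV space.

    Subclasses define :meth:`energy` and :meth:`gradient`; the gradient must
    be the exact derivative of the energy (checked in the test suite against
    central finite differences at 1e-5 relative tolerance).
    """

    name: str = "potential"
    ndim: int = 1
    #: rectangular domain, shape (ndim, 2); trajectories leaving it are truncated
    domain: np.ndarray

    def energy(self, s):
        raise NotImplementedError

    def gradient(self, s):
        raise NotImplementedError

    def minima(self, n_grid: int = 201) -> np.ndarray:
        """Locate local minima by grid scan + local refinement.

        Returns an array of shape (n_minima, ndim), sorted lexicographically.
        """
        axes = [np.linspace(lo, hi, n_grid) for lo, hi in self.domain]
        mesh = np.meshgrid(*axes, indexing="ij")
        pts = np.stack([m.ravel() for m in mesh], axis=-1)
        e = np.asarray([self.energy(p) for p in pts]).reshape(mesh[0].shape)
        # local minima on the grid (interior points below all axis neighbours)
        found = []
        it = np.ndindex(e.shape)
        for idx in it:
            if any(i == 0 or i == n_grid - 1 for i in idx):
                continue
            val = e[idx]
            lower = True
            for ax in range(self.ndim):
                for step in (-1, 1):
                    nb = list(idx)
                    nb[ax] += step
                    if e[tuple(nb)] <= val:
                        lower = False
                        break
                if not lower:
                    break
            if lower:
                found.append(pts[np.ravel_multi_index(idx, e.shape)])
        refined = []
        for x0 in found:
            res = minimize(lambda x: float(self.energy(x)), x0, jac=lambda x: np.atleast_1d(self.gradient(x)).astype(float))
            refined.append(res.x)
        if not refined:
            return np.empty((0, self.ndim))
        uniq: list[np.ndarray] = []
        for x in sorted(refined, key=tuple):
            if not any(np.allclose(x, u, atol=1e-4) for u in uniq):
                uniq.append(x)
        return np.array(uniq)


class Harmonic(AnalyticPotential):
    """U(x) = 1/2 k |x - center|^2 (isotropic, any dimension)."""

    name = "harmonic"

    def __init__(self, k: float = 1.0, center=0.0, ndim: int = 1, halfwidth: float = 10.0):
        self.k = float(k)
        self.ndim = int(ndim)
        self.center = np.broadcast_to(np.asarray(center, dtype=float), (self.ndim,)).copy()
        self.domain = np.array([[c - halfwidth, c + halfwidth] for c in self.center])

    def energy(self, s):
        s = np.asarray(s, dtype=float)
        d = s - self.center
        return 0.5 * self.k * np.sum(d * d, axis=-1)

    def gradient(self, s):
        s = np.asarray(s, dtype=float)
        return self.k * (s - self.center)


class DoubleWell1D(AnalyticPotential):
    """Tilted quartic double well: U(x) = barrier (x^2-1)^2 + tilt * x.

    Wells near x = -1 and x = +1; for tilt = 0 the barrier height at x = 0 is
    exactly `barrier`. A positive tilt lowers the left well relative to the
    right one, giving a nonzero well free-energy difference to recover.
    """

    name = "double_well_1d"
    ndim = 1

    def __init__(self, barrier: float = 25.0, tilt: float = 2.5, halfwidth: float = 1.8):
        self.barrier = float(barrier)
        self.tilt = float(tilt)
        self.domain = np.array([[-halfwidth, halfwidth]])

    def energy(self, s):
        x = np.asarray(s, dtype=float)
        x = x[..., 0] if x.ndim and x.shape[-1:] == (1,) else x
        return self.barrier * (x * x - 1.0) ** 2 + self.tilt * x

    def gradient(self, s):
        x = np.asarray(s, dtype=float)
        squeeze = x.ndim and x.shape[-1:] == (1,)
        if squeeze:
            x = x[..., 0]
        g = 4.0 * self.barrier * x * (x * x - 1.0) + self.tilt
        return g[..., None] if squeeze else g

    def well_positions(self) -> tuple[float, float]:
        """Exact locations of the two well minima (left, right)."""
        m = self.minima()
        xs = sorted(float(x[0]) for x in m)
        if len(xs) != 2:
            raise RuntimeError("double well does not have two minima for these parameters")
        return xs[0], xs[1]

    def delta_f(self) -> float:
        """Ground-truth energy difference U(right well) - U(left well)."""
        lo, hi = self.well_positions()
        return float(self.energy(np.array([hi])) - self.energy(np.array([lo])))


class DoubleWell2D(AnalyticPotential):
    """Two wells at (-1, 0) and (+1, 0) joined by a single saddle at (0, 0).

    U(x, y) = barrier (x^2-1)^2 + 1/2 ky y^2.
    """

    name = "double_well_2d"
    ndim = 2

    def __init__(self, barrier: float = 10.0, ky: float = 8.0, halfwidth: float = 1.8, yhalf: float = 1.5):
        self.barrier = float(barrier)
        self.ky = float(ky)
        self.domain = np.array([[-halfwidth, halfwidth], [-yhalf, yhalf]])

    def energy(self, s):
        s = np.asarray(s, dtype=float)
        x, y = s[..., 0], s[..., 1]
        return self.barrier * (x * x - 1.0) ** 2 + 0.5 * self.ky * y * y

    def gradient(self, s):
        s = np.asarray(s, dtype=float)
        x, y = s[..., 0], s[..., 1]
        g = np.empty_like(s)
        g[..., 0] = 4.0 * self.barrier * x * (x * x - 1.0)
        g[..., 1] = self.ky * y
        return g

    @property
    def saddle(self) -> np.ndarray:
        return np.zeros(2)


class QuadraticBowl(AnalyticPotential):
    """Anisotropic 2-D bowl: U(x, y) = 1/2 (kx x^2 + ky y^2)."""

    name = "quadratic_bowl"
    ndim = 2

    def __init__(self, kx: float = 1.0, ky: float = 4.0, halfwidth: float = 10.0):
        self.kx = float(kx)
        self.ky = float(ky)
        self.domain = np.array([[-halfwidth, halfwidth]] * 2)

    def energy(self, s):
        s = np.asarray(s, dtype=float)
        return 0.5 * (self.kx * s[..., 0] ** 2 + self.ky * s[..., 1] ** 2)

    def gradient(self, s):
        s = np.asarray(s, dtype=float)
        g = np.empty_like(s)
        g[..., 0] = self.kx * s[..., 0]
        g[..., 1] = self.ky * s[..., 1]
        return g
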