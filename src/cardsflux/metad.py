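"""Metadynamics on collective-variable potentials and minimum free-energy
path extraction.

A walker evolves by overdamped Langevin dynamics on an analytic potential
while repulsive Gaussians are deposited at its position every `stride`
steps. The accumulated bias estimates the negative free energy,

    V_G(S, t -> inf) ~ -F(S),

up to an additive constant; :func:`fes_estimate` inverts and anchors it
(optionally time-averaging the bias over the last deposits, which damps the
O(height) oscillation of a constant-height bias). A zero-temperature string
method then relaxes a discretized curve on the reconstructed surface to the
minimum free-energy path, and :func:`seed_along_path` picks trajectory
frames near equally spaced path nodes as seeds for follow-up unbiased
sampling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import RegularGridInterpolator

from .potentials import AnalyticPotential
from .synthetic import CVTrajectory, gen_particle_trajectory

try:
    from numba import njit as _njit
    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a hard dependency
    _HAVE_NUMBA = False

__all__ = [
    "BiasPotential",
    "FreeEnergySurface",
    "StringPath",
    "SeedSet",
    "run_metadynamics",
    "fes_estimate",
    "string_mfep",
    "seed_along_path",
]


@dataclass
class BiasPotential:
    """History of deposited Gaussians: V_G(S) = sum_g h exp(-|S - c_g|^2 / 2 sigma^2).

    centers : (n_gaussians, ndim) deposit positions
    widths : (ndim,) per-CV Gaussian widths sigma_i
    height : Gaussian height (kJ/mol)
    stride : deposition interval (integrator steps); height/stride is the
        energy deposition rate omega
    """

    centers: np.ndarray
    widths: np.ndarray
    height: float
    stride: int

    def __post_init__(self):
        self.centers = np.atleast_2d(np.asarray(self.centers, dtype=float))
        self.widths = np.atleast_1d(np.asarray(self.widths, dtype=float))
        if np.any(self.widths <= 0):
            raise ValueError("Gaussian widths must be positive")
        if self.height <= 0:
            raise ValueError("Gaussian height must be positive")
        if self.stride < 1:
            raise ValueError("deposition stride must be >= 1")

    @property
    def n_gaussians(self) -> int:
        return 0 if self.centers.size == 0 else self.centers.shape[0]

    @property
    def energy_rate(self) -> float:
        return self.height / self.stride

    def energy(self, s) -> np.ndarray | float:
        s = np.asarray(s, dtype=float)
        scalar = s.ndim <= 1
        pts = np.atleast_2d(s)
        if self.n_gaussians == 0:
            out = np.zeros(pts.shape[0])
        else:
            z = (pts[:, None, :] - self.centers[None, :, :]) / self.widths[None, None, :]
            out = self.height * np.exp(-0.5 * np.sum(z * z, axis=-1)).sum(axis=1)
        return float(out[0]) if scalar else out

    def gradient(self, s) -> np.ndarray:
        s = np.atleast_1d(np.asarray(s, dtype=float))
        if self.n_gaussians == 0:
            return np.zeros_like(s)
        z = (s[None, :] - self.centers) / self.widths[None, :]
        w = self.height * np.exp(-0.5 * np.sum(z * z, axis=-1))
        return -np.sum(w[:, None] * z / self.widths[None, :], axis=0)


def run_metadynamics(potential: AnalyticPotential, height: float = 1.5,
                     widths=0.1, stride: int = 500, n_steps: int = 1_000_000,
                     temperature: float = 2.494, step_size: float = 0.002,
                     seed: int = 0, x0=None, friction: float = 1.0,
                     walls=None, wall_k: float = 0.0,
                     record_stride: int = 1) -> tuple[CVTrajectory, BiasPotential]:
    """Metadynamics run on an analytic CV potential.

    Overdamped Langevin dynamics under potential + accumulated bias, with a
    Gaussian of the given height (default 1.5 kJ/mol) deposited at the
    walker's position every `stride` steps. The CVs are the walker's
    coordinates themselves. If the walker leaves the potential's domain the
    run stops there and the trajectory is flagged truncated. Deterministic
    per seed; height = 0 recovers plain Langevin dynamics bit-for-bit (the
    run is then delegated to the unbiased integrator).

    One-dimensional runs use a compiled fast path in which the potential
    gradient and accumulated bias force are tabulated on a fine grid
    (spacing width/5, linear interpolation) — the discretization error is
    O((spacing/width)^2) of a Gaussian height. Higher dimensions use the
    direct Gaussian-sum evaluation.

    `walls` = (lo, hi) with stiffness `wall_k` adds one-sided harmonic
    restraints 1/2 wall_k (S - wall)^2 outside [lo, hi] per CV — the usual
    confinement for a constant-height bias, which otherwise eventually floods
    the walker out of the region of interest. Walls act on the dynamics only;
    the recorded bias (hence the free-energy estimate) is unaffected inside
    them. `record_stride` subsamples the stored trajectory (every step by
    default); deposition and dynamics are unaffected.
    """
    ndim = potential.ndim
    widths = np.broadcast_to(np.atleast_1d(np.asarray(widths, dtype=float)), (ndim,)).copy()
    if np.any(widths <= 0):
        raise ValueError("widths must be positive")
    if stride < 1 or record_stride < 1:
        raise ValueError("stride and record_stride must be >= 1")
    if x0 is None:
        m = potential.minima()
        x0 = m[0] if len(m) else potential.domain.mean(axis=1)
    x = np.atleast_1d(np.asarray(x0, dtype=float)).copy()
    lo, hi = potential.domain[:, 0], potential.domain[:, 1]
    if np.any(x < lo) or np.any(x > hi):
        raise ValueError("starting point outside the potential domain")
    if walls is not None and wall_k <= 0:
        raise ValueError("wall_k must be positive when walls are set")

    if height == 0:
        traj = gen_particle_trajectory(potential, temperature, step_size,
                                       n_steps, seed, x0=x, friction=friction)
        if record_stride > 1:
            traj.positions = traj.positions[::record_stride]
        empty = BiasPotential(centers=np.empty((0, ndim)), widths=widths,
                              height=np.finfo(float).tiny, stride=stride)
        return traj, empty

    if ndim == 1 and _HAVE_NUMBA and walls is None:
        return _run_metad_1d_fast(potential, float(height), float(widths[0]),
                                  stride, n_steps, float(temperature),
                                  float(step_size), seed, float(x[0]),
                                  float(friction), record_stride)

    if walls is not None:
        wall_lo = np.broadcast_to(np.atleast_1d(np.asarray(walls[0], dtype=float)), (ndim,))
        wall_hi = np.broadcast_to(np.atleast_1d(np.asarray(walls[1], dtype=float)), (ndim,))

    rng = np.random.default_rng(seed)
    noise = rng.standard_normal((n_steps, ndim)) if temperature > 0 else np.zeros((n_steps, ndim))
    amp = np.sqrt(2.0 * temperature * step_size / friction)
    dt_over_gamma = step_size / friction

    centers: list[np.ndarray] = []
    cen_arr = np.empty((0, ndim))
    traj = np.empty((n_steps + 1, ndim))
    traj[0] = x
    truncated = False
    n_done = n_steps
    inv_w = 1.0 / widths
    for k in range(n_steps):
        g = np.atleast_1d(np.asarray(potential.gradient(x), dtype=float)).copy()
        if walls is not None:
            g += wall_k * (np.minimum(x - wall_lo, 0.0) + np.maximum(x - wall_hi, 0.0))
        if cen_arr.shape[0]:
            z = (x[None, :] - cen_arr) * inv_w[None, :]
            w = height * np.exp(-0.5 * np.einsum("ij,ij->i", z, z))
            g -= np.einsum("i,ij->j", w, z) * inv_w
        x = x - dt_over_gamma * g + amp * noise[k]
        if np.any(x < lo) or np.any(x > hi):
            truncated = True
            n_done = k
            warnings.warn("walker left the potential domain; run truncated")
            break
        traj[k + 1] = x
        if (k + 1) % stride == 0:
            centers.append(x.copy())
            cen_arr = np.asarray(centers)
    bias = BiasPotential(centers=np.asarray(centers).reshape(-1, ndim),
                         widths=widths, height=height, stride=stride)
    cvtraj = CVTrajectory(positions=traj[: n_done + 1][::record_stride],
                          step_size=step_size, temperature=temperature,
                          truncated=truncated, seed=seed)
    return cvtraj, bias


if _HAVE_NUMBA:

    @_njit(cache=False)
    def _metad_kernel_1d(x, noise, grid_lo, dx, n_grid, ugrad, bias_g,
                         dt, amp, height, inv_sigma, n_win, stride, step0,
                         centers, n_centers, rec, rec_stride, n_rec):
        for k in range(noise.size):
            t = (x - grid_lo) / dx
            i = int(t)
            if i < 0:
                i = 0
            elif i > n_grid - 2:
                i = n_grid - 2
            w = t - i
            g = (ugrad[i] + bias_g[i]) * (1.0 - w) + (ugrad[i + 1] + bias_g[i + 1]) * w
            x = x - dt * g + amp * noise[k]
            step = step0 + k + 1
            if x < grid_lo or x > grid_lo + dx * (n_grid - 1):
                return x, n_centers, n_rec, step, True
            if step % rec_stride == 0:
                rec[n_rec] = x
                n_rec += 1
            if step % stride == 0:
                centers[n_centers] = x
                n_centers += 1
                ic = int((x - grid_lo) / dx)
                j0 = ic - n_win
                if j0 < 0:
                    j0 = 0
                j1 = ic + n_win + 1
                if j1 > n_grid:
                    j1 = n_grid
                for j in range(j0, j1):
                    z = (grid_lo + j * dx - x) * inv_sigma
                    e = height * np.exp(-0.5 * z * z)
                    bias_g[j] -= e * z * inv_sigma
        return x, n_centers, n_rec, step0 + noise.size, False


def _run_metad_1d_fast(potential, height, sigma, stride, n_steps, temperature,
                       step_size, seed, x0, friction, record_stride):
    """Grid-accumulated 1-D metadynamics (compiled inner loop)."""
    lo, hi = float(potential.domain[0, 0]), float(potential.domain[0, 1])
    dx = sigma / 5.0
    n_grid = int(np.ceil((hi - lo) / dx)) + 1
    grid = lo + dx * np.arange(n_grid)
    ugrad = np.asarray(potential.gradient(grid), dtype=float).ravel()
    bias_g = np.zeros(n_grid)
    n_win = int(np.ceil(6.0 * sigma / dx))

    rng = np.random.default_rng(seed)
    amp = np.sqrt(2.0 * temperature * step_size / friction)
    dt = step_size / friction
    max_centers = n_steps // stride + 1
    centers = np.empty(max_centers)
    n_rec_max = n_steps // record_stride + 2
    rec = np.empty(n_rec_max)
    rec[0] = x0
    n_rec = 1
    n_centers = 0
    x = x0
    step0 = 0
    truncated = False
    chunk = 1_000_000
    remaining = n_steps
    while remaining > 0:
        m = min(chunk, remaining)
        noise = rng.standard_normal(m) if temperature > 0 else np.zeros(m)
        x, n_centers, n_rec, step0, escaped = _metad_kernel_1d(
            x, noise, lo, dx, n_grid, ugrad, bias_g, dt, amp, height,
            1.0 / sigma, n_win, stride, step0, centers, n_centers,
            rec, record_stride, n_rec)
        if escaped:
            truncated = True
            warnings.warn("walker left the potential domain; run truncated")
            break
        remaining -= m
    bias = BiasPotential(centers=centers[:n_centers, None].copy(),
                         widths=np.array([sigma]), height=height, stride=stride)
    traj = CVTrajectory(positions=rec[:n_rec, None].copy(), step_size=step_size,
                        temperature=temperature, truncated=truncated, seed=seed)
    return traj, bias


@dataclass
class FreeEnergySurface:
    """Free energy on a regular CV grid, anchored so min F = 0.

    axes : tuple of 1-D coordinate arrays, one per CV
    values : nd array of F (kJ/mol), shape = tuple(len(ax) for ax in axes)
    """

    axes: tuple[np.ndarray, ...]
    values: np.ndarray

    def __post_init__(self):
        self.axes = tuple(np.asarray(ax, dtype=float) for ax in self.axes)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != tuple(ax.size for ax in self.axes):
            raise ValueError("values shape does not match axes")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("free energy values must be finite")

    @property
    def ndim(self) -> int:
        return len(self.axes)

    @property
    def spacing(self) -> np.ndarray:
        return np.array([ax[1] - ax[0] if ax.size > 1 else 1.0 for ax in self.axes])

    def interpolate(self, points) -> np.ndarray:
        """Multilinear interpolation of F at the given CV points."""
        interp = RegularGridInterpolator(self.axes, self.values, method="linear",
                                         bounds_error=True)
        return interp(np.atleast_2d(np.asarray(points, dtype=float)))

    def gradient_interpolator(self):
        grads = np.gradient(self.values, *self.axes, edge_order=2) if self.ndim > 1 \
            else [np.gradient(self.values, self.axes[0], edge_order=2)]
        comps = [RegularGridInterpolator(self.axes, g, method="linear",
                                         bounds_error=True) for g in np.atleast_1d(grads)]

        def grad(points):
            pts = np.atleast_2d(np.asarray(points, dtype=float))
            return np.stack([c(pts) for c in comps], axis=-1)

        return grad


def fes_estimate(bias: BiasPotential, axes, tail_average: float = 0.0) -> FreeEnergySurface:
    """Free-energy surface from the deposited bias: F(S) = -V_G(S), anchored
    to min F = 0 on the grid.

    With `tail_average` = f in (0, 1], F is instead the negative of the bias
    averaged over the last ceil(f * n_gaussians) deposition snapshots, the
    standard time-averaged estimator for a constant-height bias (whose
    instantaneous estimate oscillates by about one Gaussian height).
    """
    if isinstance(axes, np.ndarray) and axes.ndim == 1:
        axes = (axes,)
    axes = tuple(np.asarray(ax, dtype=float) for ax in axes)
    if any(ax.size < 2 for ax in axes):
        raise ValueError("each grid axis needs at least two points")
    if bias.n_gaussians == 0:
        raise ValueError("bias contains no Gaussians")
    mesh = np.meshgrid(*axes, indexing="ij")
    pts = np.stack([m.ravel() for m in mesh], axis=-1)
    n_g = bias.n_gaussians
    if tail_average > 0:
        m = max(1, int(np.ceil(tail_average * n_g)))
        first_tail = n_g - m + 1  # snapshots counted: after deposit k for k in [first_tail, n_g]
        g_idx = np.arange(1, n_g + 1)
        weights = np.minimum(m, n_g - g_idx + 1) / m
        weights[g_idx > n_g] = 0.0
    else:
        weights = np.ones(n_g)
    z = (pts[:, None, :] - bias.centers[None, :, :]) / bias.widths[None, None, :]
    contrib = bias.height * np.exp(-0.5 * np.sum(z * z, axis=-1))
    v = contrib @ weights
    f = -v.reshape(tuple(ax.size for ax in axes))
    f -= f.min()
    return FreeEnergySurface(axes=axes, values=f)


@dataclass
class StringPath:
    """Discretized minimum free-energy path from reactant to product.

    nodes : (n_nodes, ndim) CV-space nodes, equidistant in arc length
    alpha : arc-length parameter in [0, 1] per node
    converged : whether the string relaxation met its tolerance
    """

    nodes: np.ndarray
    alpha: np.ndarray
    converged: bool = True

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    def length(self) -> float:
        return float(np.linalg.norm(np.diff(self.nodes, axis=0), axis=1).sum())


def _reparameterize(nodes: np.ndarray) -> np.ndarray:
    seg = np.linalg.norm(np.diff(nodes, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    if s[-1] == 0:
        return nodes.copy()
    target = np.linspace(0.0, s[-1], nodes.shape[0])
    out = np.empty_like(nodes)
    for d in range(nodes.shape[1]):
        out[:, d] = np.interp(target, s, nodes[:, d])
    return out


def string_mfep(fes: FreeEnergySurface, start, end, n_nodes: int = 25,
                max_iter: int = 2000, tol: float = 1e-4,
                step: float | None = None) -> StringPath:
    """Zero-temperature string method on a gridded free-energy surface.

    A straight line from `start` to `end` is discretized into `n_nodes`
    nodes; interior nodes descend the interpolated gradient of F while the
    endpoints stay anchored, and the string is reparameterized to equal arc
    length after every step. Convergence: maximum node displacement per
    iteration below `tol`. If `start == end` the path is a degenerate single
    node. Non-convergence at `max_iter` emits a warning and returns the last
    string.
    """
    start = np.atleast_1d(np.asarray(start, dtype=float))
    end = np.atleast_1d(np.asarray(end, dtype=float))
    if start.shape != (fes.ndim,) or end.shape != (fes.ndim,):
        raise ValueError("start/end dimensionality does not match the surface")
    for p in (start, end):
        for d, ax in enumerate(fes.axes):
            if not ax[0] <= p[d] <= ax[-1]:
                raise ValueError("start/end must lie inside the grid")
    if np.allclose(start, end):
        return StringPath(nodes=start[None, :].copy(), alpha=np.array([0.0]))
    nodes = np.linspace(start, end, n_nodes)
    grad = fes.gradient_interpolator()
    if step is None:
        gmax = np.abs(np.stack(np.gradient(fes.values, *fes.axes)
                               if fes.ndim > 1 else
                               [np.gradient(fes.values, fes.axes[0])])).max()
        step = 0.1 * float(fes.spacing.min()) / max(gmax, 1e-12)
    converged = False
    for _ in range(max_iter):
        g = grad(nodes)
        new = nodes - step * g
        new[0] = start
        new[-1] = end
        # keep nodes on the grid
        for d, ax in enumerate(fes.axes):
            new[:, d] = np.clip(new[:, d], ax[0], ax[-1])
        new = _reparameterize(new)
        disp = float(np.linalg.norm(new - nodes, axis=1).max())
        nodes = new
        if disp < tol:
            converged = True
            break
    if not converged:
        warnings.warn("string method did not converge within max_iter")
    alpha = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(nodes, axis=0), axis=1))])
    alpha = alpha / alpha[-1] if alpha[-1] > 0 else alpha
    return StringPath(nodes=nodes, alpha=alpha, converged=converged)


@dataclass
class SeedSet:
    """Trajectory frames selected along a string path as restart seeds."""

    frame_indices: np.ndarray
    cv_values: np.ndarray
    path_points: np.ndarray
    skipped: np.ndarray  # indices of path points with no nearby frame


def seed_along_path(path: StringPath, trajectory: CVTrajectory, n: int,
                    max_dist: float | None = None) -> SeedSet:
    """Select n trajectory frames nearest to n equally spaced path points.

    Points are equally spaced in arc length (n = 1 gives the midpoint).
    With `max_dist` set (typically one grid spacing), points whose nearest
    frame is farther away are skipped with a warning; an empty selection
    raises.
    """
    if trajectory.n_frames == 0:
        raise ValueError("trajectory is empty")
    if n < 1:
        raise ValueError("n must be >= 1")
    if path.n_nodes == 1:
        targets = path.nodes.repeat(n, axis=0)
    else:
        alphas = np.array([0.5]) if n == 1 else np.linspace(0.0, 1.0, n)
        targets = np.stack([
            np.interp(alphas, path.alpha, path.nodes[:, d])
            for d in range(path.nodes.shape[1])
        ], axis=-1)
    pos = trajectory.positions
    frames = []
    cvs = []
    kept_pts = []
    skipped = []
    for i, tgt in enumerate(targets):
        d = np.linalg.norm(pos - tgt[None, :], axis=1)
        j = int(np.argmin(d))
        if max_dist is not None and d[j] > max_dist:
            skipped.append(i)
            continue
        frames.append(j)
        cvs.append(pos[j])
        kept_pts.append(tgt)
    if skipped:
        warnings.warn(f"no frame within {max_dist} of {len(skipped)} path point(s); skipped")
    if not frames:
        raise ValueError("no trajectory frame lies near any path point")
    return SeedSet(frame_indices=np.asarray(frames, dtype=int),
                   cv_values=np.asarray(cvs), path_points=np.asarray(kept_pts),
                   skipped=np.asarray(skipped, dtype=int))
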