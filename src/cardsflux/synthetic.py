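"""Synthetic conformational-ensemble generators.

Every input the analysis pipeline needs can be generated here with a known
ground truth, so correlation-network inference, Markov-state-model
estimation, transition-path analysis and enhanced sampling can all be
validated end to end without any molecular simulation data:

* :func:`gen_coupled_rotamers` — ensembles of rotameric dihedral time series
  in which an allosteric network is *planted* as explicit source->target
  couplings between residues;
* :func:`gen_unbinding_chain` — discrete bound->unbound Markov chains with a
  designed rate-limiting (bottleneck) edge and known exact transition matrix;
* :func:`gen_particle_trajectory` — overdamped Langevin dynamics on analytic
  collective-variable potentials, optionally under a metadynamics bias.

All generators are bit-reproducible for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .featurize import DihedralSeries, wrap_degrees
from .potentials import AnalyticPotential

__all__ = [
    "PlantedNetworkSpec",
    "ToyUnbindingSpec",
    "CVTrajectory",
    "gen_coupled_rotamers",
    "gen_unbinding_chain",
    "gen_particle_trajectory",
]

#: rotamer well centers for synthetic side-chain dihedrals: gauche+, trans, gauche-
WELL_CENTERS = np.array([60.0, 180.0, -60.0])
#: wrapped-Gaussian angular noise around each well center (degrees)
WELL_SIGMA = 15.0


@dataclass
class PlantedNetworkSpec:
    """Specification of a coupled-rotamer ensemble with a planted network.

    Each residue carries `dihedrals_per_residue` side-chain-like dihedrals,
    each evolving as a 3-state Markov chain over rotamer wells with
    persistence `stay_prob` and a uniform stationary distribution. A planted
    edge (source, target, epsilon) makes every dihedral of the target residue
    copy the matching dihedral of the source residue with probability epsilon
    per frame (mixing weight), so epsilon=0 gives exactly independent chains
    and epsilon=1 a maximally informative coupling.
    """

    n_residues: int = 10
    dihedrals_per_residue: int = 2
    edges: Sequence[tuple[int, int, float]] = field(default_factory=list)
    frame_count: int = 100_000
    frame_interval: float = 1.0
    seed: int = 0
    stay_prob: float = 0.9

    def validate(self) -> None:
        if self.n_residues < 1 or self.dihedrals_per_residue < 1:
            raise ValueError("need at least one residue and one dihedral per residue")
        if self.frame_count < 1:
            raise ValueError("frame_count must be >= 1")
        if not 0.0 < self.stay_prob < 1.0:
            raise ValueError("stay_prob must be in (0, 1)")
        incoming: dict[int, float] = {}
        for src, tgt, eps in self.edges:
            if not (0 <= src < self.n_residues and 0 <= tgt < self.n_residues):
                raise ValueError(f"edge ({src}, {tgt}) references a residue >= n_residues")
            if src == tgt:
                raise ValueError("self-edges are not allowed")
            if not 0.0 <= eps <= 1.0:
                raise ValueError(f"coupling strength must be in [0, 1], got {eps}")
            incoming[tgt] = incoming.get(tgt, 0.0) + eps
        for tgt, tot in incoming.items():
            if tot > 1.0 + 1e-12:
                raise ValueError(
                    f"total coupling into residue {tgt} exceeds 1 ({tot:.3f})"
                )


def _baseline_rows(stay_prob: float) -> np.ndarray:
    off = (1.0 - stay_prob) / 2.0
    t = np.full((3, 3), off)
    np.fill_diagonal(t, stay_prob)
    return t


def gen_coupled_rotamers(spec: PlantedNetworkSpec) -> DihedralSeries:
    """Generate a dihedral ensemble with the planted coupling network.

    Per frame, every dihedral first takes a baseline Markov step over the
    three wells; then planted edges are applied in their listed order, the
    target residue's dihedral k copying the already-updated state of source
    dihedral (k mod source count) with probability epsilon. Angles are the
    well centers plus wrapped-Gaussian noise (sigma 15 degrees).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n_res, dpr = spec.n_residues, spec.dihedrals_per_residue
    nd = n_res * dpr
    nf = spec.frame_count
    cum = np.cumsum(_baseline_rows(spec.stay_prob), axis=1)

    # dihedral j belongs to residue j // dpr, slot j % dpr
    def dihedrals_of(res: int) -> np.ndarray:
        return np.arange(res * dpr, (res + 1) * dpr)

    states = np.empty((nf, nd), dtype=np.int8)
    cur = rng.integers(0, 3, size=nd).astype(np.int8)
    # pre-drawn randomness: one baseline uniform per dihedral per frame plus
    # one coupling uniform per planted edge per frame
    u_base = rng.random((nf, nd))
    edges = list(spec.edges)
    u_edge = rng.random((nf, len(edges))) if edges else None
    for t in range(nf):
        row_cdf = cum[cur]
        cur = (u_base[t][:, None] > row_cdf).sum(axis=1).astype(np.int8)
        for e, (src, tgt, eps) in enumerate(edges):
            if u_edge[t, e] < eps:
                sd = dihedrals_of(src)
                td = dihedrals_of(tgt)
                cur[td] = cur[sd[np.arange(td.size) % sd.size]]
        states[t] = cur

    noise = rng.normal(0.0, WELL_SIGMA, size=(nf, nd))
    angles = wrap_degrees(WELL_CENTERS[states] + noise)
    residues = np.repeat(np.arange(n_res), dpr)
    classes = [f"chi{(k % 4) + 1}" for _ in range(n_res) for k in range(dpr)]
    return DihedralSeries(angles=angles, residues=residues, classes=classes)


@dataclass
class ToyUnbindingSpec:
    """Linear bound -> intermediates -> unbound chain with a designed bottleneck.

    States are 0 (bound), 1..n_intermediate_states, n+1 (unbound). Edge i is
    the pair (i, i+1) with one-step probabilities forward_rates[i] (i -> i+1)
    and backward_rates[i] (i+1 -> i); the remainder of each row is a
    self-loop. If `bottleneck_edge` is given, both directions of that edge are
    set to `bottleneck_rate`, which must be strictly the smallest rate so the
    designed edge is the unique kinetic bottleneck on the only release path.
    """

    n_intermediate_states: int = 5
    forward_rate: float = 0.1
    backward_rate: float = 0.1
    bottleneck_edge: int | None = None
    bottleneck_rate: float = 0.001
    seed: int = 0

    @property
    def n_states(self) -> int:
        return self.n_intermediate_states + 2

    def rates(self) -> tuple[np.ndarray, np.ndarray]:
        n_edges = self.n_states - 1
        fwd = np.full(n_edges, float(self.forward_rate))
        bwd = np.full(n_edges, float(self.backward_rate))
        if self.bottleneck_edge is not None:
            fwd[self.bottleneck_edge] = self.bottleneck_rate
            bwd[self.bottleneck_edge] = self.bottleneck_rate
        return fwd, bwd

    def validate(self) -> None:
        if self.n_intermediate_states < 1:
            raise ValueError("need at least one intermediate state")
        fwd, bwd = self.rates()
        if np.any(fwd <= 0) or np.any(fwd >= 1) or np.any(bwd <= 0) or np.any(bwd >= 1):
            raise ValueError("all rates must lie in (0, 1)")
        if self.bottleneck_edge is not None:
            if not 0 <= self.bottleneck_edge < self.n_states - 1:
                raise ValueError("bottleneck_edge out of range")
            others = np.concatenate([
                np.delete(fwd, self.bottleneck_edge),
                np.delete(bwd, self.bottleneck_edge),
            ])
            if self.bottleneck_rate >= others.min():
                raise ValueError("bottleneck_rate must be strictly the smallest rate")
        # per-state outgoing probability (excluding self-loop) must stay <= 1
        for i in range(self.n_states):
            out = 0.0
            if i > 0:
                out += bwd[i - 1]
            if i < self.n_states - 1:
                out += fwd[i]
            if out > 1.0:
                raise ValueError(f"outgoing probability of state {i} exceeds 1")


def exact_transition_matrix(spec: ToyUnbindingSpec) -> np.ndarray:
    """The exact row-stochastic (tridiagonal) transition matrix the rates imply."""
    spec.validate()
    n = spec.n_states
    fwd, bwd = spec.rates()
    t = np.zeros((n, n))
    for i in range(n - 1):
        t[i, i + 1] = fwd[i]
        t[i + 1, i] = bwd[i]
    np.fill_diagonal(t, 1.0 - t.sum(axis=1))
    return t


def sample_chain(transition: np.ndarray, n_steps: int, seed: int, start: int = 0) -> np.ndarray:
    """Sample a discrete Markov-chain trajectory of length n_steps + 1."""
    t = np.asarray(transition, dtype=float)
    cdf = np.cumsum(t, axis=1)
    cdf[:, -1] = 1.0
    rng = np.random.default_rng(seed)
    u = rng.random(n_steps)
    traj = np.empty(n_steps + 1, dtype=np.int32)
    traj[0] = start
    s = start
    rows = [cdf[i] for i in range(t.shape[0])]
    for k in range(n_steps):
        s = int(np.searchsorted(rows[s], u[k], side="right"))
        traj[k + 1] = s
    return traj


def gen_unbinding_chain(spec: ToyUnbindingSpec, n_steps: int = 100_000,
                        n_trajectories: int = 1) -> tuple[np.ndarray, list[np.ndarray]]:
    """Exact transition matrix plus sampled discrete trajectories.

    Returns (T, trajectories); trajectory r uses seed spec.seed + r and starts
    in the bound state 0. Deterministic for a fixed spec seed.
    """
    t = exact_transition_matrix(spec)
    trajs = [sample_chain(t, n_steps, seed=spec.seed + r) for r in range(n_trajectories)]
    return t, trajs


@dataclass
class CVTrajectory:
    """A trajectory in collective-variable space.

    positions : (n_frames, ndim) array
    truncated : True if the walker left the potential's domain and the run
        was cut short at that frame
    """

    positions: np.ndarray
    step_size: float
    temperature: float
    truncated: bool = False
    seed: int | None = None

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]


def gen_particle_trajectory(potential: AnalyticPotential, temperature: float,
                            step_size: float, n_steps: int, seed: int,
                            bias=None, x0=None, friction: float = 1.0) -> CVTrajectory:
    """Overdamped Langevin (Euler–Maruyama) trajectory on an analytic potential.

    x_{t+1} = x_t - dt/gamma * grad(U + V_bias)(x_t) + sqrt(2 kT dt / gamma) xi

    `temperature` is k_B T in the potential's energy units (kJ/mol); time
    units are abstract. If the walker leaves the potential's rectangular
    domain the trajectory is truncated there and flagged. Deterministic for
    a fixed seed.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    if step_size <= 0:
        raise ValueError("step_size must be positive")
    if temperature < 0:
        raise ValueError("temperature must be non-negative")
    ndim = potential.ndim
    if x0 is None:
        m = potential.minima()
        x0 = m[0] if len(m) else potential.domain.mean(axis=1)
    x = np.atleast_1d(np.asarray(x0, dtype=float)).copy()
    if x.shape != (ndim,):
        raise ValueError(f"x0 must have shape ({ndim},)")
    lo, hi = potential.domain[:, 0], potential.domain[:, 1]
    if np.any(x < lo) or np.any(x > hi):
        raise ValueError("starting point outside the potential domain")

    rng = np.random.default_rng(seed)
    noise = rng.standard_normal((n_steps, ndim)) if temperature > 0 else np.zeros((n_steps, ndim))
    amp = np.sqrt(2.0 * temperature * step_size / friction)
    dt_over_gamma = step_size / friction

    out = np.empty((n_steps + 1, ndim))
    out[0] = x
    truncated = False
    n_done = n_steps
    for k in range(n_steps):
        g = np.atleast_1d(np.asarray(potential.gradient(x), dtype=float))
        if bias is not None:
            g = g + np.atleast_1d(np.asarray(bias.gradient(x), dtype=float))
        x = x - dt_over_gamma * g + amp * noise[k]
        if np.any(x < lo) or np.any(x > hi):
            truncated = True
            n_done = k  # last valid frame is out[k]
            break
        out[k + 1] = x
    return CVTrajectory(positions=out[: n_done + 1], step_size=step_size,
                        temperature=temperature, truncated=truncated, seed=seed)
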