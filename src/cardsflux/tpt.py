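"""Transition path theory on a Markov state model.

Given bound (source, A) and unbound (sink, B) macrostates, computes forward
committors q+ (probability of reaching B before A), reactive fluxes

    f_ij = pi_i q-_i T_ij q+_j   (i != j, zero on the diagonal),

the highest-flux (widest / maximum-bottleneck) release pathways, and the
rate-limiting step — the minimum-flux edge of those pathways. Path capacity
defaults to the gross directional reactive flux above, which discriminates
edges even on a single linear release path; the net flux
f+_ij = max(f_ij - f_ji, 0) is also available and is the divergence-free
current used for conservation checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .msm import MarkovModel

__all__ = [
    "MacrostateCriteria",
    "FluxNetwork",
    "Pathway",
    "define_macrostates",
    "committors",
    "flux_network",
    "top_paths",
    "rate_limiting_step",
]


@dataclass
class MacrostateCriteria:
    """Geometric bound/unbound macrostate definitions over per-state features.

    Bound states satisfy *all* bound predicates (AND): ligand-site distance
    <= `bound_max_distance` and ligand RMSD to the bound pose <
    `bound_max_rmsd` (skip the RMSD test by leaving it None). Unbound states
    have ligand-site distance > `unbound_min_distance`. Defaults follow the
    transition-path endpoint convention of 6 A + 0.5 A RMSD for bound and
    55 A for unbound; `ensemble_split` gives the single-threshold 8 A
    bound/released split used for comparing ensembles on either side of the
    rate-limiting step.
    """

    bound_max_distance: float = 6.0
    bound_max_rmsd: float | None = 0.5
    unbound_min_distance: float = 55.0

    @classmethod
    def tpt_endpoints(cls) -> "MacrostateCriteria":
        return cls(bound_max_distance=6.0, bound_max_rmsd=0.5, unbound_min_distance=55.0)

    @classmethod
    def ensemble_split(cls) -> "MacrostateCriteria":
        return cls(bound_max_distance=8.0, bound_max_rmsd=None, unbound_min_distance=8.0)


def define_macrostates(features: dict, criteria: MacrostateCriteria) -> tuple[np.ndarray, np.ndarray]:
    """Evaluate macrostate criteria on per-state features.

    `features` maps feature names to per-state arrays; requires
    'ligand_distance' and, when the RMSD predicate is active, 'ligand_rmsd'.
    Returns (A, B) state-index arrays; raises if either is empty (naming the
    failing criterion) or if they overlap.
    """
    dist = np.asarray(features["ligand_distance"], dtype=float)
    bound = dist <= criteria.bound_max_distance
    if criteria.bound_max_rmsd is not None:
        rmsd = np.asarray(features["ligand_rmsd"], dtype=float)
        if rmsd.shape != dist.shape:
            raise ValueError("feature arrays differ in length")
        bound &= rmsd < criteria.bound_max_rmsd
    unbound = dist > criteria.unbound_min_distance
    a = np.flatnonzero(bound)
    b = np.flatnonzero(unbound)
    if a.size == 0:
        raise ValueError(
            f"no state satisfies the bound criteria (distance <= "
            f"{criteria.bound_max_distance}, rmsd < {criteria.bound_max_rmsd})")
    if b.size == 0:
        raise ValueError(
            f"no state satisfies the unbound criterion (distance > "
            f"{criteria.unbound_min_distance})")
    overlap = np.intersect1d(a, b)
    if overlap.size:
        raise ValueError(f"bound and unbound sets overlap on states {overlap.tolist()}")
    return a, b


def committors(model: MarkovModel | np.ndarray, a, b) -> np.ndarray:
    """Forward committor q+ per state: probability of hitting B before A.

    Solves the discrete boundary-value problem q+ = T q+ on intermediate
    states with q+ = 0 on A and q+ = 1 on B. Raises if an intermediate state
    cannot reach either boundary (singular system).
    """
    t = model.transition if isinstance(model, MarkovModel) else np.asarray(model, dtype=float)
    n = t.shape[0]
    a = np.atleast_1d(np.asarray(a, dtype=int))
    b = np.atleast_1d(np.asarray(b, dtype=int))
    if a.size == 0 or b.size == 0:
        raise ValueError("A and B must be non-empty")
    if np.intersect1d(a, b).size:
        raise ValueError("A and B must be disjoint")
    q = np.zeros(n)
    q[b] = 1.0
    inter = np.setdiff1d(np.arange(n), np.concatenate([a, b]))
    if inter.size:
        tii = t[np.ix_(inter, inter)]
        rhs = t[np.ix_(inter, b)].sum(axis=1)
        m = np.eye(inter.size) - tii
        try:
            q_i = np.linalg.solve(m, rhs)
        except np.linalg.LinAlgError as err:
            raise ValueError("singular committor system: some intermediate "
                             "states cannot reach A or B") from err
        resid = np.abs(m @ q_i - rhs).max()
        if resid > 1e-10:
            raise ValueError(f"committor solve residual too large: {resid}")
        q[inter] = q_i
    return np.clip(q, 0.0, 1.0)


@dataclass
class FluxNetwork:
    """Committors and reactive fluxes of an A -> B transition.

    gross[i, j] = pi_i q-_i T_ij q+_j (zero diagonal); net is its
    antisymmetrized positive part. total_flux is the reactive current
    leaving A per lag time.
    """

    committor: np.ndarray
    gross: np.ndarray
    net: np.ndarray
    a: np.ndarray
    b: np.ndarray
    total_flux: float
    stationary: np.ndarray

    @property
    def backward_committor(self) -> np.ndarray:
        return 1.0 - self.committor


def flux_network(model: MarkovModel, a, b) -> FluxNetwork:
    """Reactive flux network for the A -> B (bound -> unbound) transition."""
    a = np.atleast_1d(np.asarray(a, dtype=int))
    b = np.atleast_1d(np.asarray(b, dtype=int))
    q = committors(model, a, b)
    qm = 1.0 - q
    pi = model.stationary
    t = model.transition
    gross = pi[:, None] * qm[:, None] * t * q[None, :]
    np.fill_diagonal(gross, 0.0)
    net = np.maximum(gross - gross.T, 0.0)
    not_a = np.setdiff1d(np.arange(t.shape[0]), a)
    total = float(net[np.ix_(a, not_a)].sum())
    return FluxNetwork(committor=q, gross=gross, net=net, a=a, b=b,
                       total_flux=total, stationary=pi)


@dataclass
class Pathway:
    """One A -> B release pathway from the flux decomposition."""

    states: list[int]
    capacity: float
    bottleneck: tuple[int, int]
    rank: int
    edge_fluxes: list[float] = field(default_factory=list)


def _widest_capacity(cap: np.ndarray, a: np.ndarray, b: np.ndarray) -> float:
    """Maximum bottleneck capacity of any A -> B path: binary search over the
    distinct edge capacities with BFS reachability at each threshold."""
    values = np.unique(cap[cap > 0])
    if values.size == 0:
        return 0.0

    def reachable(threshold: float) -> bool:
        adj = cap >= threshold
        seen = np.zeros(cap.shape[0], dtype=bool)
        stack = list(a)
        seen[a] = True
        bset = set(b.tolist())
        while stack:
            i = stack.pop()
            if i in bset:
                return True
            nxt = np.flatnonzero(adj[i] & ~seen)
            seen[nxt] = True
            stack.extend(nxt.tolist())
        return False

    lo, hi = 0, values.size - 1  # invariant: reachable(values[lo])
    if not reachable(values[lo]):
        return 0.0
    while lo < hi:
        mid = (lo + hi + 1) // 2
        if reachable(values[mid]):
            lo = mid
        else:
            hi = mid - 1
    return float(values[lo])


def _min_hop_path(cap: np.ndarray, a: np.ndarray, b: np.ndarray,
                  threshold: float) -> list[int] | None:
    """Fewest-hop A -> B path using only edges with capacity >= threshold;
    ties broken lexicographically by exploring neighbors in index order."""
    n = cap.shape[0]
    parent = np.full(n, -1)
    seen = np.zeros(n, dtype=bool)
    frontier = sorted(a.tolist())
    seen[frontier] = True
    bset = set(b.tolist())
    while frontier:
        nxt = []
        for i in frontier:
            if i in bset:
                path = [i]
                while parent[path[-1]] != -1:
                    path.append(int(parent[path[-1]]))
                return path[::-1]
            for j in np.flatnonzero(cap[i] >= threshold):
                if not seen[j]:
                    seen[j] = True
                    parent[j] = i
                    nxt.append(int(j))
        frontier = sorted(set(nxt))
    # a sink may sit in the frontier exactly at the last level
    for i in sorted(bset):
        if seen[i]:
            path = [i]
            while parent[path[-1]] != -1:
                path.append(int(parent[path[-1]]))
            return path[::-1]
    return None


def top_paths(net: FluxNetwork, k: int, flux: str = "gross") -> list[Pathway]:
    """The k highest-flux A -> B pathways by iterative bottleneck decomposition.

    Repeatedly finds the widest (maximum-bottleneck) path through the
    remaining capacities, records it, and subtracts its capacity from every
    edge on it; stops after k paths or when the flux is exhausted. Edge
    capacity is the gross directional reactive flux by default ('net'
    selects the net flux). Ties in path choice are broken by fewest hops,
    then lexicographic state order.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if flux not in ("gross", "net"):
        raise ValueError("flux must be 'gross' or 'net'")
    cap = (net.gross if flux == "gross" else net.net).copy()
    paths: list[Pathway] = []
    for rank in range(k):
        c_star = _widest_capacity(cap, net.a, net.b)
        if c_star <= 0:
            break
        states = _min_hop_path(cap, net.a, net.b, c_star)
        if states is None:
            break
        edge_fluxes = [float(cap[states[i], states[i + 1]]) for i in range(len(states) - 1)]
        capacity = float(min(edge_fluxes))
        # Bottleneck search over steps between intermediates: the first edge
        # (out of A) and last edge (into B) carry exactly the path's net
        # current by construction (their backward reactive flux vanishes
        # identically), so they tie the minimum on any path and say nothing
        # about where the current is throttled. Fall back to all edges when
        # the path has no interior step.
        if len(edge_fluxes) >= 3:
            bn_idx = 1 + int(np.argmin(edge_fluxes[1:-1]))
        else:
            bn_idx = int(np.argmin(edge_fluxes))
        for i in range(len(states) - 1):
            cap[states[i], states[i + 1]] -= capacity
        paths.append(Pathway(states=[int(s) for s in states], capacity=capacity,
                             bottleneck=(states[bn_idx], states[bn_idx + 1]),
                             rank=rank, edge_fluxes=edge_fluxes))
    return paths


def rate_limiting_step(paths: Sequence[Pathway]) -> tuple[tuple[int, int], list[tuple[int, int]]]:
    """The rate-limiting step across a set of highest-flux pathways.

    Each path's bottleneck is the argmin-flux edge along it (first minimal
    edge on ties). The consensus rate-limiting step is the most frequent
    bottleneck; frequency ties go to the edge with the smallest flux.
    Returns (consensus edge, per-path bottleneck edges).
    """
    if not paths:
        raise ValueError("need at least one pathway")
    bottlenecks = [p.bottleneck for p in paths]
    min_flux: dict[tuple[int, int], float] = {}
    freq: dict[tuple[int, int], int] = {}
    for p in paths:
        e = p.bottleneck
        freq[e] = freq.get(e, 0) + 1
        f = min(p.edge_fluxes) if p.edge_fluxes else p.capacity
        min_flux[e] = min(min_flux.get(e, np.inf), f)
    consensus = min(freq, key=lambda e: (-freq[e], min_flux[e], e))
    return consensus, bottlenecks
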