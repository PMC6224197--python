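"""Markov-state-model construction.

Geometric clustering (hybrid k-centers / k-medoids), protein x ligand
product states, transition-matrix estimation at a lag time, stationary
distributions, and implied-timescale validation of Markovian behavior.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence
import warnings

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

__all__ = [
    "ClusterModel",
    "MarkovModel",
    "kcenters",
    "kmedoids_refine",
    "merge_short_lived_states",
    "product_states",
    "transition_matrix",
    "timescales_from_transition",
    "implied_timescales",
]


@dataclass
class ClusterModel:
    """Geometric clustering of trajectory frames.

    Centers are indices of actual frames; after the k-centers stage every
    frame lies within `cutoff` of its assigned center.
    """

    centers: np.ndarray          # frame indices of cluster centers
    assignments: np.ndarray      # cluster index per frame
    distances: np.ndarray        # distance of each frame to its center
    cutoff: float
    metric: str = "euclidean"

    @property
    def n_clusters(self) -> int:
        return self.centers.size


def _pairwise_to_point(features: np.ndarray, idx: int,
                       metric: Callable | None) -> np.ndarray:
    if metric is None:
        diff = features - features[idx]
        return np.sqrt(np.einsum("ij,ij->i", diff, diff))
    return np.asarray([metric(features[k], features[idx]) for k in range(len(features))])


def kcenters(features, cutoff: float, metric: str | Callable = "euclidean") -> ClusterModel:
    """Greedy farthest-point k-centers clustering down to a distance cutoff.

    Starts from frame 0, repeatedly adds the frame farthest from all current
    centers, and stops once every frame is within `cutoff` of a center —
    deterministic. `metric` is 'euclidean' or any callable d(a, b) (e.g. an
    RMSD-like rigid-alignment distance).
    """
    features = np.asarray(features, dtype=float)
    if features.ndim == 1:
        features = features[:, None]
    if features.shape[0] < 1:
        raise ValueError("need at least one frame")
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    metric_fn = None if metric == "euclidean" else metric
    metric_name = "euclidean" if metric_fn is None else getattr(metric, "__name__", "custom")
    n = features.shape[0]
    centers = [0]
    dist = _pairwise_to_point(features, 0, metric_fn)
    assign = np.zeros(n, dtype=int)
    while dist.max() > cutoff:
        new = int(np.argmax(dist))
        centers.append(new)
        d_new = _pairwise_to_point(features, new, metric_fn)
        closer = d_new < dist
        assign[closer] = len(centers) - 1
        dist = np.minimum(dist, d_new)
    return ClusterModel(centers=np.asarray(centers), assignments=assign,
                        distances=dist, cutoff=float(cutoff), metric=metric_name)


def _objective(features, centers, assign, metric_fn) -> float:
    d = np.empty(len(features))
    for c_idx, frame in enumerate(centers):
        m = assign == c_idx
        if not m.any():
            continue
        if metric_fn is None:
            diff = features[m] - features[frame]
            d[m] = np.sqrt(np.einsum("ij,ij->i", diff, diff))
        else:
            d[m] = [metric_fn(features[k], features[frame]) for k in np.flatnonzero(m)]
    return float(d.mean())


def kmedoids_refine(model: ClusterModel, features, n_sweeps: int = 5, seed: int = 0,
                    metric: str | Callable = "euclidean") -> ClusterModel:
    """Stochastic k-medoids refinement of a k-centers model.

    Per sweep, each cluster proposes a random member as its new medoid; the
    proposal is accepted if the mean frame-to-medoid distance (with frames
    reassigned to their nearest medoid) decreases. The objective never
    increases; n_sweeps=0 returns the model unchanged.
    """
    features = np.asarray(features, dtype=float)
    if features.ndim == 1:
        features = features[:, None]
    metric_fn = None if metric == "euclidean" else metric
    rng = np.random.default_rng(seed)
    centers = model.centers.copy()
    assign = model.assignments.copy()
    best = _objective(features, centers, assign, metric_fn)
    for _ in range(n_sweeps):
        for c_idx in range(centers.size):
            members = np.flatnonzero(assign == c_idx)
            if members.size <= 1:
                continue
            proposal = int(rng.choice(members))
            if proposal == centers[c_idx]:
                continue
            trial_centers = centers.copy()
            trial_centers[c_idx] = proposal
            trial_assign, trial_dist = _assign_to_centers(features, trial_centers, metric_fn)
            trial_obj = float(trial_dist.mean())
            if trial_obj < best:
                centers, assign, best = trial_centers, trial_assign, trial_obj
    assign, dist = _assign_to_centers(features, centers, metric_fn)
    return ClusterModel(centers=centers, assignments=assign, distances=dist,
                        cutoff=model.cutoff, metric=model.metric)


def _assign_to_centers(features, centers, metric_fn):
    d = np.stack([_pairwise_to_point(features, int(f), metric_fn) for f in centers])
    assign = np.argmin(d, axis=0)
    return assign, d[assign, np.arange(features.shape[0])]


def merge_short_lived_states(dtrajs, min_residence: float) -> list[np.ndarray]:
    """Merge states whose mean residence time is below a threshold into
    their most-connected neighbor.

    Residence time is the mean run length (frames) of each state's visits
    across the trajectories; a short-lived state's frames are relabeled to
    the state it exchanges the most transitions with. One pass, processed in
    order of increasing residence time; labels are then compacted to
    0..n-1. A coarse stand-in for residence-time-aware partitioning of
    ligand poses.
    """
    if isinstance(dtrajs, np.ndarray) and dtrajs.ndim == 1:
        dtrajs = [dtrajs]
    dtrajs = [np.asarray(d, dtype=int).copy() for d in dtrajs]
    n_states = int(max(d.max() for d in dtrajs if d.size)) + 1
    visits = np.zeros(n_states)
    frames = np.zeros(n_states)
    for d in dtrajs:
        change = np.flatnonzero(d[1:] != d[:-1]) + 1
        starts = np.concatenate([[0], change])
        ends = np.concatenate([change, [d.size]])
        for s, e in zip(starts, ends):
            visits[d[s]] += 1
            frames[d[s]] += e - s
    residence = np.where(visits > 0, frames / np.maximum(visits, 1), np.inf)
    c = _count_matrix(dtrajs, lag=1, n_states=n_states)
    connectivity = c + c.T
    mapping = np.arange(n_states)
    for s in np.argsort(residence):
        if residence[s] >= min_residence or visits[s] == 0:
            continue
        neighbors = connectivity[s].copy()
        neighbors[s] = 0
        if neighbors.sum() == 0:
            continue
        target = int(np.argmax(neighbors))
        while mapping[target] != target:  # follow earlier merges
            target = int(mapping[target])
        if target == s:
            continue
        mapping[s] = target
        connectivity[target] += connectivity[s]
        connectivity[:, target] += connectivity[:, s]
        connectivity[s] = 0
        connectivity[:, s] = 0
    final = np.array([mapping[mapping[s]] for s in range(n_states)])
    kept = np.unique(final[visits > 0])
    compact = {int(old): k for k, old in enumerate(kept)}
    return [np.array([compact[int(final[x])] for x in d]) for d in dtrajs]


def product_states(protein_assignments, ligand_assignments) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Combine protein-conformation and ligand-pose assignments into product
    states, indexed over the (protein, ligand) pairs that actually occur.

    Returns (combined assignments, pair label per combined state).
    """
    p = np.asarray(protein_assignments, dtype=int)
    l = np.asarray(ligand_assignments, dtype=int)
    if p.shape != l.shape:
        raise ValueError("protein and ligand assignments differ in length")
    pairs = np.stack([p, l], axis=1)
    uniq, inverse = np.unique(pairs, axis=0, return_inverse=True)
    labels = [(int(a), int(b)) for a, b in uniq]
    return inverse.astype(int), labels


@dataclass
class MarkovModel:
    """Discrete-state kinetic model at a fixed lag time.

    Estimated on the largest strongly connected set of states; `active` maps
    model state -> original assignment label. T is row-stochastic; pi is the
    stationary distribution (pi T = pi).
    """

    transition: np.ndarray
    stationary: np.ndarray
    counts: np.ndarray
    lag: int
    active: np.ndarray
    estimator: str = "symmetric"
    state_labels: list = field(default_factory=list)

    @property
    def n_states(self) -> int:
        return self.transition.shape[0]


def _count_matrix(dtrajs: Sequence[np.ndarray], lag: int, n_states: int) -> np.ndarray:
    c = np.zeros((n_states, n_states))
    for dt in dtrajs:
        dt = np.asarray(dt, dtype=int)
        if dt.size <= lag:
            continue
        i, j = dt[:-lag], dt[lag:]  # sliding window, never across trajectories
        np.add.at(c, (i, j), 1.0)
    return c


def transition_matrix(dtrajs, lag: int, estimator: str = "symmetric") -> MarkovModel:
    """Estimate a Markov state model from discrete trajectories.

    Counts use a sliding window at lag `lag` within each trajectory. The
    default 'symmetric' estimator row-normalizes (C + C^T)/2, which enforces
    detailed balance (pi proportional to symmetrized row sums) and keeps
    committors and reactive fluxes well defined; 'raw' row-normalizes C and
    takes pi from the leading left eigenvector. Estimation is restricted to
    the largest strongly connected component; dropped states are reported in
    a warning.
    """
    if lag < 1:
        raise ValueError("lag must be >= 1 frame")
    if estimator not in ("symmetric", "raw"):
        raise ValueError("estimator must be 'symmetric' or 'raw'")
    if isinstance(dtrajs, np.ndarray) and dtrajs.ndim == 1:
        dtrajs = [dtrajs]
    dtrajs = [np.asarray(d, dtype=int) for d in dtrajs]
    n_states = int(max(d.max() for d in dtrajs if d.size)) + 1
    c = _count_matrix(dtrajs, lag, n_states)
    if c.sum() == 0:
        raise ValueError("no transition pairs at this lag")
    # ergodic trimming: largest strongly connected component of the count graph
    n_comp, labels = connected_components(csr_matrix(c > 0), directed=True,
                                          connection="strong")
    observed = np.flatnonzero(c.sum(axis=0) + c.sum(axis=1) > 0)
    comp_sizes = np.bincount(labels[observed], minlength=n_comp)
    keep_label = int(np.argmax(comp_sizes))
    active = np.flatnonzero(labels == keep_label)
    active = np.intersect1d(active, observed)
    dropped = np.setdiff1d(observed, active)
    if dropped.size:
        warnings.warn(f"dropped disconnected states: {dropped.tolist()}")
    c_active = c[np.ix_(active, active)]
    if estimator == "symmetric":
        cs = 0.5 * (c_active + c_active.T)
        rows = cs.sum(axis=1)
        t = cs / rows[:, None]
        pi = rows / rows.sum()
    else:
        rows = c_active.sum(axis=1)
        t = c_active / rows[:, None]
        vals, vecs = np.linalg.eig(t.T)
        k = int(np.argmax(vals.real))
        pi = np.abs(vecs[:, k].real)
        pi = pi / pi.sum()
    return MarkovModel(transition=t, stationary=pi, counts=c_active, lag=int(lag),
                       active=active, estimator=estimator)


def timescales_from_transition(transition: np.ndarray, lag: int = 1,
                               n_timescales: int = 1) -> np.ndarray:
    """Relaxation timescales t_i = -lag / ln lambda_i from the largest
    non-unit eigenvalues of a transition matrix.

    Eigenvalues that are complex (beyond round-off) or non-positive have no
    real timescale and come back as NaN; a repeated unit eigenvalue
    (disconnected or deterministic mode) gives +inf.
    """
    ev = np.linalg.eigvals(np.asarray(transition, dtype=float))
    ev = ev[np.argsort(-np.abs(ev))]
    out = np.full(n_timescales, np.nan)
    for k in range(1, n_timescales + 1):
        if k >= ev.size:
            continue
        lam = ev[k]
        if abs(lam.imag) > 1e-10 or lam.real <= 0:
            continue
        out[k - 1] = np.inf if lam.real >= 1.0 else -lag / np.log(lam.real)
    return out


def implied_timescales(dtrajs, lags, n_timescales: int = 1,
                       estimator: str = "symmetric") -> pd.DataFrame:
    """Implied relaxation timescales t_i(tau) = -tau / ln lambda_i(tau).

    Lag-independence of the timescales indicates Markovian behavior at that
    lag. Undefined timescales are reported as NaN (see
    :func:`timescales_from_transition`).
    """
    rows = []
    for lag in lags:
        model = transition_matrix(dtrajs, lag=int(lag), estimator=estimator)
        ts = timescales_from_transition(model.transition, lag=int(lag),
                                        n_timescales=n_timescales)
        row = {"lag": int(lag)}
        for k, val in enumerate(ts, start=2):
            row[f"t{k}"] = val
        rows.append(row)
    return pd.DataFrame(rows).set_index("lag")
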