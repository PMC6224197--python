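"""Correlation of structural and dynamical dihedral states (CARDS) and
Shannon-entropy disorder mapping.

Every dihedral contributes two discrete channels: its *structural* state
(the rotamer it occupies) and its *dynamical* state (whether it is stably
ordered in one rotamer or rapidly hopping, i.e. disordered). Communication
between dihedrals X and Y is the sum of four normalized mutual-information
channels:

    I_H(X, Y) = I_ss + I_sd + I_ds + I_dd   (each channel / its capacity)

where s/d index the structural/dynamical channel of each partner and the
capacity is the maximum MI the two alphabets allow. Residue-level scores
aggregate dihedral pairs; iterating "score everything against the current
target, recruit the strongest group, make it the new target" traces an
allosteric pathway from a seed site toward a sink site.

Disorder of a residue is the summed Shannon entropy of its dihedrals'
rotamer occupancies, normalized by the summed channel capacities, giving a
value in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .featurize import StateSeries

__all__ = [
    "DynamicalSeries",
    "JointDistribution",
    "CorrelationMatrix",
    "ResidueCommunication",
    "AllostericNetwork",
    "DisorderProfile",
    "assign_dynamical_states",
    "mutual_information",
    "channel_capacity",
    "holistic_matrix",
    "residue_matrix",
    "communication_to_target",
    "trace_network",
    "global_communication",
    "residue_disorder",
    "delta_disorder",
]

ORDERED, DISORDERED = 0, 1


@dataclass
class DynamicalSeries:
    """Binary ordered(0)/disordered(1) code per frame per dihedral, plus each
    dihedral's characteristic ordered and disordered timescales (frames;
    NaN where undefined, e.g. a dihedral that never transitions)."""

    codes: np.ndarray
    ordered_timescale: np.ndarray
    disordered_timescale: np.ndarray
    residues: np.ndarray
    ids: list[str] = field(default_factory=list)

    @property
    def n_frames(self) -> int:
        return self.codes.shape[0]

    @property
    def n_dihedrals(self) -> int:
        return self.codes.shape[1]


def _segments(states_1d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Run-length encode a 1-D state series -> (start indices, durations)."""
    n = states_1d.size
    change = np.flatnonzero(states_1d[1:] != states_1d[:-1]) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [n]])
    return starts, ends - starts


def assign_dynamical_states(series: StateSeries) -> DynamicalSeries:
    """Parse each dihedral's structural-state series into ordered/disordered
    dynamical states.

    Two-step rule, per dihedral:

    1. Run-length encode the series into segments (periods between
       consecutive rotamer transitions) and split their durations at the
       overall median: the *ordered* timescale is the mean duration of
       segments above the median, the *disordered* timescale the mean of
       those at or below it.
    2. Assign each segment to whichever timescale its duration is closer to
       in log space (ties -> disordered); every frame inherits its segment's
       label.

    Dihedrals with fewer than two transitions carry no usable duration
    statistics and are marked all-ordered. If the median split leaves the
    upper group empty (all segments equally short, e.g. strict alternation)
    every segment is disordered.
    """
    if series.n_frames < 2:
        raise ValueError("need at least two frames to parse dynamical states")
    nf, nd = series.states.shape
    codes = np.zeros((nf, nd), dtype=np.int8)
    t_ord = np.full(nd, np.nan)
    t_dis = np.full(nd, np.nan)
    for j in range(nd):
        starts, durs = _segments(series.states[:, j])
        n_transitions = starts.size - 1
        if n_transitions < 2:
            continue  # all-ordered
        med = np.median(durs)
        upper = durs[durs > med]
        lower = durs[durs <= med]
        if upper.size == 0:
            t_dis[j] = lower.mean()
            codes[:, j] = DISORDERED
            continue
        to, td = upper.mean(), lower.mean()
        t_ord[j], t_dis[j] = to, td
        d_ord = np.abs(np.log(durs) - np.log(to))
        d_dis = np.abs(np.log(durs) - np.log(td))
        seg_code = np.where(d_dis <= d_ord, DISORDERED, ORDERED).astype(np.int8)
        codes[:, j] = np.repeat(seg_code, durs)
    return DynamicalSeries(codes=codes, ordered_timescale=t_ord,
                           disordered_timescale=t_dis,
                           residues=series.residues.copy(), ids=list(series.ids))


@dataclass
class JointDistribution:
    """Counts table over states of X (rows) x states of Y (columns)."""

    counts: np.ndarray

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D table")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if self.counts.sum() <= 0:
            raise ValueError("total count must be positive")

    @classmethod
    def from_series(cls, x: np.ndarray, y: np.ndarray, nx: int, ny: int) -> "JointDistribution":
        if x.shape != y.shape:
            raise ValueError("series must have equal length")
        counts = np.bincount(
            x.astype(np.int64) * ny + y.astype(np.int64), minlength=nx * ny
        ).reshape(nx, ny)
        return cls(counts=counts)

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    @property
    def marginal_x(self) -> np.ndarray:
        return self.counts.sum(axis=1) / self.total

    @property
    def marginal_y(self) -> np.ndarray:
        return self.counts.sum(axis=0) / self.total


def mutual_information(joint: JointDistribution) -> float:
    """Plug-in mutual information in bits.

    I = sum_xy p(x,y) log2[ p(x,y) / (p(x) p(y)) ], empty cells contributing
    zero. Non-negative up to floating-point round-off (clipped at -1e-12).
    """
    p = joint.counts / joint.total
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mask = p > 0
    outer = px[:, None] * py[None, :]
    val = float(np.sum(p[mask] * np.log2(p[mask] / outer[mask])))
    if val < -1e-12:
        raise AssertionError(f"MI came out negative beyond round-off: {val}")
    return max(val, 0.0)


def channel_capacity(n_x: int, n_y: int) -> float:
    """Maximum possible MI (bits) between alphabets of sizes n_x and n_y."""
    if n_x < 2 or n_y < 2:
        raise ValueError("alphabet sizes must be >= 2")
    return float(np.log2(min(n_x, n_y)))


@dataclass
class CorrelationMatrix:
    """Four normalized dihedral x dihedral MI channels and their holistic sum.

    i_ss[i, j] couples structure of i with structure of j; i_sd[i, j] couples
    structure of i with dynamics of j (so i_sd[i, j] == i_ds[j, i]); i_dd the
    two dynamical channels. Each entry is MI / channel capacity, in [0, 1];
    i_h is the element-wise sum of the four, hence in [0, 4] and symmetric.
    Diagonals are zero and excluded from all network analyses.
    """

    i_ss: np.ndarray
    i_sd: np.ndarray
    i_ds: np.ndarray
    i_dd: np.ndarray
    residues: np.ndarray
    ids: list[str]

    @property
    def i_h(self) -> np.ndarray:
        return self.i_ss + self.i_sd + self.i_ds + self.i_dd

    @property
    def n_dihedrals(self) -> int:
        return self.i_ss.shape[0]


def _mi_bits(x: np.ndarray, y: np.ndarray, nx: int, ny: int) -> float:
    counts = np.bincount(x.astype(np.int64) * ny + y.astype(np.int64),
                         minlength=nx * ny).astype(float)
    n = counts.sum()
    p = counts.reshape(nx, ny) / n
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mask = p > 0
    outer = px[:, None] * py[None, :]
    return max(float(np.sum(p[mask] * np.log2(p[mask] / outer[mask]))), 0.0)


def holistic_matrix(structural: StateSeries, dynamical: DynamicalSeries | None = None,
                    pairs: np.ndarray | None = None) -> CorrelationMatrix:
    """All four normalized MI channels for every dihedral pair.

    `dynamical` defaults to :func:`assign_dynamical_states` of the structural
    series. `pairs` optionally restricts computation to the given (i, j)
    index pairs (everything else stays zero) — used by the bootstrap scoring
    paths where only dihedral-to-target-site pairs are needed.
    """
    if dynamical is None:
        dynamical = assign_dynamical_states(structural)
    if structural.n_frames != dynamical.n_frames:
        raise ValueError("structural and dynamical series frame counts differ")
    nd = structural.n_dihedrals
    s = structural.states
    d = dynamical.codes
    alpha = structural.alphabet
    i_ss = np.zeros((nd, nd))
    i_sd = np.zeros((nd, nd))
    i_ds = np.zeros((nd, nd))
    i_dd = np.zeros((nd, nd))
    if pairs is None:
        pairs = np.array([(i, j) for i in range(nd) for j in range(i + 1, nd)])
    for i, j in pairs:
        if i == j:
            continue
        ai, aj = int(alpha[i]), int(alpha[j])
        i_ss[i, j] = i_ss[j, i] = _mi_bits(s[:, i], s[:, j], ai, aj) / channel_capacity(ai, aj)
        sd = _mi_bits(s[:, i], d[:, j], ai, 2) / channel_capacity(ai, 2)
        ds = _mi_bits(d[:, i], s[:, j], 2, aj) / channel_capacity(2, aj)
        i_sd[i, j] = sd
        i_ds[j, i] = sd
        i_ds[i, j] = ds
        i_sd[j, i] = ds
        i_dd[i, j] = i_dd[j, i] = _mi_bits(d[:, i], d[:, j], 2, 2)  # capacity 1 bit
    return CorrelationMatrix(i_ss=i_ss, i_sd=i_sd, i_ds=i_ds, i_dd=i_dd,
                             residues=structural.residues.copy(),
                             ids=list(structural.ids))


def residue_matrix(matrix: CorrelationMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Residue x residue communication: sum of I_H over member-dihedral pairs.

    Returns (residue ids, symmetric matrix with zero diagonal); intra-residue
    pairs are excluded.
    """
    res_ids = np.unique(matrix.residues)
    idx = {r: np.flatnonzero(matrix.residues == r) for r in res_ids}
    ih = matrix.i_h
    n = res_ids.size
    out = np.zeros((n, n))
    for a in range(n):
        for b in range(a + 1, n):
            block = ih[np.ix_(idx[res_ids[a]], idx[res_ids[b]])]
            out[a, b] = out[b, a] = float(block.sum())
    return res_ids, out


@dataclass
class ResidueCommunication:
    """Per-residue communication to a target site with bootstrap spread."""

    residues: np.ndarray          # candidate residues (target excluded)
    score: np.ndarray             # full-data score per residue
    spread: np.ndarray            # bootstrap standard deviation per residue
    boot_scores: np.ndarray       # (n_boot, n_residues) replicate scores
    target: np.ndarray


def _site_scores(structural: StateSeries, dynamical: DynamicalSeries,
                 target: np.ndarray, candidates: np.ndarray,
                 frame_idx: np.ndarray | None = None) -> np.ndarray:
    """Sum of I_H(d, d') over d in each candidate residue, d' in the target
    site, optionally on a frame resample."""
    residues = structural.residues
    tgt_d = np.flatnonzero(np.isin(residues, target))
    if frame_idx is not None:
        structural = StateSeries(states=structural.states[frame_idx],
                                 alphabet=structural.alphabet,
                                 residues=residues, classes=list(structural.classes),
                                 ids=list(structural.ids))
        dynamical = DynamicalSeries(codes=dynamical.codes[frame_idx],
                                    ordered_timescale=dynamical.ordered_timescale,
                                    disordered_timescale=dynamical.disordered_timescale,
                                    residues=residues, ids=list(dynamical.ids))
    scores = np.zeros(candidates.size)
    for k, r in enumerate(candidates):
        cand_d = np.flatnonzero(residues == r)
        pairs = np.array([(i, j) for i in cand_d for j in tgt_d])
        m = holistic_matrix(structural, dynamical, pairs=pairs)
        scores[k] = float(m.i_h[np.ix_(cand_d, tgt_d)].sum())
    return scores


def communication_to_target(structural: StateSeries, target_residues,
                            dynamical: DynamicalSeries | None = None,
                            n_boot: int = 10, seed: int = 0,
                            exclude=None) -> ResidueCommunication:
    """How much each residue communicates with a target site.

    A residue's score is the summed holistic communication I_H over all
    dihedral pairs linking it to the target site's dihedrals. Uncertainty
    comes from `n_boot` bootstrap resamples of the frames (with replacement),
    recomputing the relevant MI channels per resample. Target residues (and
    any in `exclude`) are left out of the ranking.
    """
    target = np.atleast_1d(np.asarray(target_residues, dtype=int))
    if target.size == 0:
        raise ValueError("target site must be non-empty")
    all_res = np.unique(structural.residues)
    unknown = np.setdiff1d(target, all_res)
    if unknown.size:
        raise ValueError(f"unknown residues in target: {unknown.tolist()}")
    if dynamical is None:
        dynamical = assign_dynamical_states(structural)
    skip = set(target.tolist()) | set([] if exclude is None else list(exclude))
    candidates = np.array([r for r in all_res if r not in skip], dtype=int)
    score = _site_scores(structural, dynamical, target, candidates)
    rng = np.random.default_rng(seed)
    boot = np.empty((n_boot, candidates.size))
    nf = structural.n_frames
    for b in range(n_boot):
        idx = rng.integers(0, nf, size=nf)
        boot[b] = _site_scores(structural, dynamical, target, candidates, frame_idx=idx)
    return ResidueCommunication(residues=candidates, score=score,
                                spread=boot.std(axis=0), boot_scores=boot,
                                target=target)


@dataclass
class AllostericNetwork:
    """Result of an iterative communication trace from a seed site.

    frontiers : residues recruited at each iteration, in order
    edges : (source residue, recruited residue, weight) for the strongest
        link that recruited each frontier residue
    reached_sink : whether the trace reached the sink site before the
        frontier emptied
    """

    seed_site: np.ndarray
    sink_site: np.ndarray
    frontiers: list[np.ndarray]
    edges: list[tuple[int, int, float]]
    reached_sink: bool


def shift_null_scores(structural: StateSeries, target_residues, candidates,
                      dynamical: DynamicalSeries | None = None,
                      shifts=None) -> np.ndarray:
    """Circular-shift null for target-site communication scores.

    Rolling the target site's series by a large offset destroys any real
    cross-correlation while preserving each dihedral's occupancies and
    autocorrelation — which set the finite-sample floor of the plug-in MI
    estimator. Returns the maximum null score per candidate over the shifts
    (defaults: 1/4, 1/2 and 3/4 of the trajectory).
    """
    target = np.atleast_1d(np.asarray(target_residues, dtype=int))
    candidates = np.atleast_1d(np.asarray(candidates, dtype=int))
    if dynamical is None:
        dynamical = assign_dynamical_states(structural)
    nf = structural.n_frames
    if shifts is None:
        shifts = (nf // 4, nf // 2, (3 * nf) // 4)
    tgt_d = np.flatnonzero(np.isin(structural.residues, target))
    out = np.zeros(candidates.size)
    for shift in shifts:
        s = structural.states.copy()
        d = dynamical.codes.copy()
        s[:, tgt_d] = np.roll(s[:, tgt_d], int(shift), axis=0)
        d[:, tgt_d] = np.roll(d[:, tgt_d], int(shift), axis=0)
        shifted_struct = StateSeries(states=s, alphabet=structural.alphabet,
                                     residues=structural.residues,
                                     classes=list(structural.classes),
                                     ids=list(structural.ids))
        shifted_dyn = DynamicalSeries(codes=d,
                                      ordered_timescale=dynamical.ordered_timescale,
                                      disordered_timescale=dynamical.disordered_timescale,
                                      residues=structural.residues,
                                      ids=list(dynamical.ids))
        out = np.maximum(out, _site_scores(shifted_struct, shifted_dyn, target, candidates))
    return out


def trace_network(structural: StateSeries, seed_site, sink_site,
                  dynamical: DynamicalSeries | None = None, n_boot: int = 10,
                  seed: int = 0, null_factor: float = 2.0, n_sigma: float = 2.0,
                  max_iter: int = 50) -> AllostericNetwork:
    """Iteratively trace the allosteric network from a seed site to a sink.

    Each iteration scores every unvisited residue against the current target
    site (with bootstrap spreads), then recruits the most strongly
    communicating group as the frontier:

    1. significance gate — a candidate's score must exceed `null_factor`
       times its circular-shift null (:func:`shift_null_scores`), separating
       real communication from the finite-sample MI floor;
    2. top group — among significant candidates, those within `n_sigma`
       combined bootstrap spreads of the top scorer. Transitive correlations
       (A couples C through B) also score highly against a target, so the
       frontier is the statistically strongest group, not everything above
       the noise floor.

    The frontier becomes the next target. The trace stops when the sink is
    recruited, the frontier is empty, or `max_iter` is hit.
    """
    seed_site = np.atleast_1d(np.asarray(seed_site, dtype=int))
    sink_site = np.atleast_1d(np.asarray(sink_site, dtype=int))
    if seed_site.size == 0 or sink_site.size == 0:
        raise ValueError("seed and sink sites must be non-empty")
    if np.intersect1d(seed_site, sink_site).size:
        raise ValueError("seed and sink sites must be disjoint")
    if dynamical is None:
        dynamical = assign_dynamical_states(structural)
    rng = np.random.default_rng(seed)
    visited = set(seed_site.tolist())
    target = seed_site
    frontiers: list[np.ndarray] = []
    edges: list[tuple[int, int, float]] = []
    reached = False
    full_matrix = holistic_matrix(structural, dynamical)
    _, res_mat = residue_matrix(full_matrix)
    res_index = {r: k for k, r in enumerate(np.unique(structural.residues))}
    for _ in range(max_iter):
        comm = communication_to_target(structural, target, dynamical=dynamical,
                                       n_boot=n_boot, seed=int(rng.integers(2**31)),
                                       exclude=sorted(visited - set(target.tolist())))
        if comm.residues.size == 0:
            break
        null = shift_null_scores(structural, target, comm.residues, dynamical=dynamical)
        significant = comm.score > null_factor * null
        if not significant.any():
            break
        k_top = int(np.argmax(np.where(significant, comm.score, -np.inf)))
        s_top, sd_top = comm.score[k_top], comm.spread[k_top]
        in_top_group = significant & (
            comm.score >= s_top - n_sigma * (comm.spread + sd_top))
        frontier = comm.residues[in_top_group]
        for r in frontier:
            weights = [(res_mat[res_index[t], res_index[r]], t) for t in target]
            w, t = max(weights)
            edges.append((int(t), int(r), float(w)))
        frontiers.append(frontier)
        visited |= set(frontier.tolist())
        if np.intersect1d(frontier, sink_site).size:
            reached = True
            break
        target = frontier
    return AllostericNetwork(seed_site=seed_site, sink_site=sink_site,
                             frontiers=frontiers, edges=edges, reached_sink=reached)


def global_communication(matrix: CorrelationMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Total communication of each residue to all other residues.

    Residue r's value is the sum of I_H over all dihedral pairs (d in r,
    d' not in r) — high values mark communication hubs. Returns
    (residue ids, values).
    """
    res_ids, mat = residue_matrix(matrix)
    return res_ids, mat.sum(axis=1)


@dataclass
class DisorderProfile:
    """Per-residue normalized conformational disorder in [0, 1]."""

    residues: np.ndarray
    value: np.ndarray


def residue_disorder(structural: StateSeries) -> DisorderProfile:
    """Per-residue Shannon-entropy disorder.

    Each dihedral's rotamer occupancy entropy H = -sum p log2 p (bits); a
    residue's disorder is the sum of its member-dihedral entropies divided
    by the summed channel capacities (log2 alphabet size), so 0 means every
    member dihedral is frozen in one rotamer and 1 means all are uniformly
    occupied.
    """
    nd = structural.n_dihedrals
    nf = structural.n_frames
    ent = np.empty(nd)
    cap = np.empty(nd)
    for j in range(nd):
        counts = np.bincount(structural.states[:, j], minlength=int(structural.alphabet[j]))
        p = counts / nf
        nz = p[p > 0]
        ent[j] = float(-(nz * np.log2(nz)).sum())
        cap[j] = np.log2(structural.alphabet[j])
    res_ids = np.unique(structural.residues)
    vals = np.empty(res_ids.size)
    for k, r in enumerate(res_ids):
        m = structural.residues == r
        vals[k] = ent[m].sum() / cap[m].sum()
    return DisorderProfile(residues=res_ids, value=vals)


def delta_disorder(ensemble_a: StateSeries, ensemble_b: StateSeries) -> DisorderProfile:
    """Per-residue disorder change B - A (e.g. across a rate-limiting step).

    Both ensembles must cover the same residues; antisymmetric under swapping
    the arguments.
    """
    da = residue_disorder(ensemble_a)
    db = residue_disorder(ensemble_b)
    if da.residues.shape != db.residues.shape or np.any(da.residues != db.residues):
        raise ValueError("ensembles cover different residues")
    return DisorderProfile(residues=da.residues.copy(), value=db.value - da.value)
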