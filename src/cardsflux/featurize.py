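"""Geometric observables and dihedral-state discretization.

Turns conformational ensembles into the features the downstream analyses
consume: dihedral angles, discrete rotamer states, inter-atom /
inter-domain distances and angles, helix-tilt measures, and bootstrap
histograms of any scalar observable.

Conventions
-----------
Angles are degrees in the half-open interval [-180, 180), IUPAC sign
convention for torsions. Rotamer alphabets: backbone phi/psi dihedrals take
two states (cis, trans); side-chain chi dihedrals take three staggered
states (gauche+, trans, gauche-).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DihedralSeries",
    "StateSeries",
    "BootHistogram",
    "BACKBONE_CLASSES",
    "SIDECHAIN_CLASSES",
    "dihedral_angle",
    "assign_rotamers",
    "atom_pair_distance_series",
    "interdomain_angle",
    "helix_tilt",
    "bootstrap_histogram",
]

BACKBONE_CLASSES = frozenset({"phi", "psi"})
SIDECHAIN_CLASSES = frozenset({"chi1", "chi2", "chi3", "chi4"})

#: state code -> label for the 3-state side-chain alphabet
SIDECHAIN_STATE_LABELS = ("gauche+", "trans", "gauche-")
#: state code -> label for the 2-state backbone alphabet
BACKBONE_STATE_LABELS = ("cis", "trans")


def alphabet_size(dihedral_class: str) -> int:
    """Number of rotameric states for a dihedral class (2 backbone, 3 side chain)."""
    if dihedral_class in BACKBONE_CLASSES:
        return 2
    if dihedral_class in SIDECHAIN_CLASSES:
        return 3
    raise ValueError(f"unknown dihedral class: {dihedral_class!r}")


def wrap_degrees(a):
    """Map angles onto [-180, 180)."""
    return (np.asarray(a, dtype=float) + 180.0) % 360.0 - 180.0


@dataclass
class DihedralSeries:
    """Per-frame dihedral angles with residue/class metadata.

    angles : (n_frames, n_dihedrals) float array, degrees in [-180, 180)
    residues : (n_dihedrals,) int array, residue index per dihedral
    classes : list of class labels ('phi', 'psi', 'chi1'..'chi4')
    ids : dihedral identifiers (auto-generated when omitted)
    """

    angles: np.ndarray
    residues: np.ndarray
    classes: list[str]
    ids: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.angles = np.asarray(self.angles, dtype=float)
        if self.angles.ndim != 2:
            raise ValueError("angles must be (n_frames, n_dihedrals)")
        self.residues = np.asarray(self.residues, dtype=int)
        if self.residues.shape != (self.angles.shape[1],):
            raise ValueError("residues must have one entry per dihedral")
        if len(self.classes) != self.angles.shape[1]:
            raise ValueError("classes must have one entry per dihedral")
        for c in self.classes:
            alphabet_size(c)  # validates
        if np.any(self.angles < -180.0) or np.any(self.angles >= 180.0):
            raise ValueError("angles must lie in [-180, 180)")
        if not self.ids:
            self.ids = [
                f"r{r}_{c}" for r, c in zip(self.residues, self.classes)
            ]
        elif len(self.ids) != self.angles.shape[1]:
            raise ValueError("ids must have one entry per dihedral")

    @property
    def n_frames(self) -> int:
        return self.angles.shape[0]

    @property
    def n_dihedrals(self) -> int:
        return self.angles.shape[1]


@dataclass
class StateSeries:
    """Discrete rotamer codes per frame per dihedral.

    states : (n_frames, n_dihedrals) small-int array
    alphabet : (n_dihedrals,) alphabet size per dihedral (2 or 3)
    """

    states: np.ndarray
    alphabet: np.ndarray
    residues: np.ndarray
    classes: list[str]
    ids: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.states = np.asarray(self.states)
        self.alphabet = np.asarray(self.alphabet, dtype=int)
        self.residues = np.asarray(self.residues, dtype=int)
        if self.states.ndim != 2:
            raise ValueError("states must be (n_frames, n_dihedrals)")
        nd = self.states.shape[1]
        if self.alphabet.shape != (nd,) or self.residues.shape != (nd,):
            raise ValueError("metadata length mismatch")
        if np.any(self.states < 0) or np.any(self.states >= self.alphabet[None, :]):
            raise ValueError("state codes must be < alphabet size")
        if not self.ids:
            self.ids = [f"r{r}_{c}" for r, c in zip(self.residues, self.classes)]

    @property
    def n_frames(self) -> int:
        return self.states.shape[0]

    @property
    def n_dihedrals(self) -> int:
        return self.states.shape[1]


@dataclass
class BootHistogram:
    """Bootstrap histogram: mean density and per-bin spread over replicates."""

    edges: np.ndarray
    mean: np.ndarray
    spread: np.ndarray
    n_boot: int


def dihedral_angle(p1, p2, p3, p4) -> float:
    """Signed torsion angle (degrees, [-180, 180)) of four points.

    Uses the standard atan2 formulation; positive when, looking down the
    p2->p3 axis, the far bond rotates clockwise from the near bond. A torsion
    of exactly 180 deg is reported as -180 per the half-open range. Raises
    ``ValueError`` if three consecutive points are collinear (the torsion is
    then undefined).
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    scale = max(np.linalg.norm(b1), np.linalg.norm(b2), np.linalg.norm(b3))
    if np.linalg.norm(n1) <= 1e-10 * scale**2 or np.linalg.norm(n2) <= 1e-10 * scale**2:
        raise ValueError("dihedral undefined: three consecutive points are collinear")
    b2n = b2 / np.linalg.norm(b2)
    x = float(np.dot(n1, n2))
    y = float(np.dot(np.cross(n1, n2), b2n))
    ang = np.degrees(np.arctan2(y, x))
    return float(wrap_degrees(ang))


def assign_rotamers(series: DihedralSeries) -> StateSeries:
    """Discretize dihedral angles into rotameric states.

    Side chains (3 states, half-open 120-degree sectors on the angle mod 360):
    gauche+ = [0, 120), trans = [120, 240), gauche- = [240, 360).
    Backbone (2 states): cis if \\|angle\\| < 90, else trans.
    """
    nd = series.n_dihedrals
    states = np.empty(series.angles.shape, dtype=np.int8)
    alphabet = np.empty(nd, dtype=int)
    for j, cls in enumerate(series.classes):
        a = series.angles[:, j]
        if cls in BACKBONE_CLASSES:
            states[:, j] = (np.abs(a) >= 90.0).astype(np.int8)
            alphabet[j] = 2
        else:
            states[:, j] = (np.mod(a, 360.0) // 120).astype(np.int8)
            alphabet[j] = 3
    return StateSeries(
        states=states,
        alphabet=alphabet,
        residues=series.residues.copy(),
        classes=list(series.classes),
        ids=list(series.ids),
    )


def reconstruct_well_angles(states: StateSeries) -> DihedralSeries:
    """Map state codes back to their well-center angles (inverse of discretization
    up to within-well noise); used for idempotence checks."""
    side_centers = np.array([60.0, 180.0, -60.0])
    back_centers = np.array([0.0, 179.0])  # trans center kept inside [-180, 180)
    angles = np.empty(states.states.shape, dtype=float)
    for j, cls in enumerate(states.classes):
        centers = back_centers if cls in BACKBONE_CLASSES else side_centers
        angles[:, j] = centers[states.states[:, j]]
    return DihedralSeries(
        angles=wrap_degrees(angles),
        residues=states.residues.copy(),
        classes=list(states.classes),
        ids=list(states.ids),
    )


def _com(coords: np.ndarray, idx: np.ndarray, masses: np.ndarray | None) -> np.ndarray:
    sub = coords[:, idx, :]
    if masses is None:
        return sub.mean(axis=1)
    w = masses[idx]
    return (sub * w[None, :, None]).sum(axis=1) / w.sum()


def atom_pair_distance_series(coords, selection_a, selection_b, masses=None) -> np.ndarray:
    """Per-frame distance between the centers of mass of two atom selections.

    coords : (n_frames, n_atoms, 3) array
    selection_a, selection_b : integer index arrays (>= 1 atom each)
    masses : optional per-atom weights; equal weights when omitted
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 3 or coords.shape[2] != 3:
        raise ValueError("coords must be (n_frames, n_atoms, 3)")
    out = []
    for name, sel in (("selection_a", selection_a), ("selection_b", selection_b)):
        sel = np.atleast_1d(np.asarray(sel, dtype=int))
        if sel.size == 0:
            raise ValueError(f"empty selection: {name}")
        out.append(sel)
    sel_a, sel_b = out
    m = None if masses is None else np.asarray(masses, dtype=float)
    da = _com(coords, sel_a, m)
    db = _com(coords, sel_b, m)
    return np.linalg.norm(da - db, axis=1)


def interdomain_angle(ca1, ca2, ca3, ca4) -> float:
    """Signed inter-domain angle of four alpha-carbons, as the torsion of the
    four points (degrees). Four points define an 'angle' unambiguously only as
    a torsion; the signed range mirrors how domain-opening angles are reported
    (e.g. -30 to 0 degrees for a closed-to-open hinge)."""
    return dihedral_angle(ca1, ca2, ca3, ca4)


def _principal_axis(coords: np.ndarray) -> np.ndarray:
    c = coords - coords.mean(axis=0)
    _, _, vt = np.linalg.svd(c, full_matrices=False)
    return vt[0]


def helix_tilt(ref_coords, query_coords) -> float:
    """Angle (degrees, folded to [0, 90]) between the least-squares axes of two
    helices, each axis being the first principal component of its alpha-carbon
    coordinates. Needs >= 4 points per helix."""
    ref = np.asarray(ref_coords, dtype=float)
    qry = np.asarray(query_coords, dtype=float)
    for name, arr in (("ref", ref), ("query", qry)):
        if arr.ndim != 2 or arr.shape[1] != 3 or arr.shape[0] < 4:
            raise ValueError(f"{name} helix needs >= 4 alpha-carbon coordinates")
    a = _principal_axis(ref)
    b = _principal_axis(qry)
    cosang = abs(float(np.dot(a, b)))  # PCA axis sign is arbitrary -> fold to <= 90
    cosang = min(1.0, cosang)
    return float(np.degrees(np.arccos(cosang)))


def bootstrap_histogram(values, n_boot: int = 10, bins: int = 100, seed: int = 0,
                        range_: tuple[float, float] | None = None) -> BootHistogram:
    """Histogram with bootstrap error bars.

    Resamples the values with replacement `n_boot` times; reports the mean
    density per bin and the standard deviation over replicates. Defaults (10
    resamples, 100 bins) follow common practice for MSM-weighted observable
    distributions. Deterministic for a fixed seed.
    """
    values = np.asarray(values, dtype=float).ravel()
    if values.size == 0:
        raise ValueError("bootstrap_histogram requires at least one value")
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    if range_ is None:
        lo, hi = float(values.min()), float(values.max())
        if lo == hi:  # degenerate constant input: one occupied central bin
            lo, hi = lo - 0.5, hi + 0.5
        range_ = (lo, hi)
    edges = np.linspace(range_[0], range_[1], bins + 1)
    rng = np.random.default_rng(seed)
    dens = np.empty((n_boot, bins))
    for b in range(n_boot):
        resample = rng.choice(values, size=values.size, replace=True)
        dens[b], _ = np.histogram(resample, bins=edges, density=True)
    return BootHistogram(edges=edges, mean=dens.mean(axis=0),
                         spread=dens.std(axis=0), n_boot=n_boot)
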