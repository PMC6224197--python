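"""Format plumbing: delimited-text dialects for dihedral tables, matrices,
histograms, flux networks and bias histories, a binary array container with
a JSON sidecar for correlation matrices, and a thin structure/trajectory
reader adapter.

The dihedral-table dialect is tab-separated with three commented header
lines (dihedral id, residue index, class) followed by one row of angles
(degrees, [-180, 180)) per frame.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .cards import CorrelationMatrix
from .featurize import BootHistogram, DihedralSeries

__all__ = [
    "write_dihedral_table",
    "read_dihedral_table",
    "write_matrix_tsv",
    "read_matrix_tsv",
    "save_correlation",
    "load_correlation",
    "write_histogram_tsv",
    "write_edges_tsv",
    "write_bias_tsv",
    "write_fes_tsv",
    "write_string_tsv",
    "load_structure_coords",
]


def write_dihedral_table(path, series: DihedralSeries) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("#dihedral_id\t" + "\t".join(series.ids) + "\n")
        fh.write("#residue\t" + "\t".join(str(r) for r in series.residues) + "\n")
        fh.write("#class\t" + "\t".join(series.classes) + "\n")
        np.savetxt(fh, series.angles, fmt="%.6f", delimiter="\t")


def read_dihedral_table(path) -> DihedralSeries:
    path = Path(path)
    with path.open() as fh:
        header = [fh.readline() for _ in range(3)]
        meta = {}
        for line in header:
            if not line.startswith("#"):
                raise ValueError(f"{path}: missing dihedral-table header line")
            key, *vals = line[1:].rstrip("\n").split("\t")
            meta[key] = vals
        for key in ("dihedral_id", "residue", "class"):
            if key not in meta:
                raise ValueError(f"{path}: header lacks '{key}' line")
        angles = np.loadtxt(fh, delimiter="\t", ndmin=2)
    return DihedralSeries(angles=angles,
                          residues=np.asarray(meta["residue"], dtype=int),
                          classes=meta["class"], ids=meta["dihedral_id"])


def write_matrix_tsv(path, matrix, labels=None) -> None:
    matrix = np.asarray(matrix)
    with Path(path).open("w") as fh:
        if labels is not None:
            fh.write("#labels\t" + "\t".join(str(x) for x in labels) + "\n")
        np.savetxt(fh, np.atleast_2d(matrix), fmt="%.12g", delimiter="\t")


def read_matrix_tsv(path):
    path = Path(path)
    labels = None
    with path.open() as fh:
        first = fh.readline()
        if first.startswith("#labels"):
            labels = first.rstrip("\n").split("\t")[1:]
        else:
            fh.seek(0)
        matrix = np.loadtxt(fh, delimiter="\t", ndmin=2)
    return matrix, labels


def save_correlation(prefix, matrix: CorrelationMatrix) -> None:
    """Correlation channels as a binary array container (.npz) with a JSON
    sidecar carrying the dihedral metadata."""
    prefix = Path(prefix)
    np.savez(prefix.with_suffix(".npz"), i_ss=matrix.i_ss, i_sd=matrix.i_sd,
             i_ds=matrix.i_ds, i_dd=matrix.i_dd)
    sidecar = {"ids": list(matrix.ids), "residues": [int(r) for r in matrix.residues]}
    prefix.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def load_correlation(prefix) -> CorrelationMatrix:
    prefix = Path(prefix)
    arrays = np.load(prefix.with_suffix(".npz"))
    sidecar = json.loads(prefix.with_suffix(".json").read_text())
    return CorrelationMatrix(i_ss=arrays["i_ss"], i_sd=arrays["i_sd"],
                             i_ds=arrays["i_ds"], i_dd=arrays["i_dd"],
                             residues=np.asarray(sidecar["residues"], dtype=int),
                             ids=sidecar["ids"])


def write_histogram_tsv(path, hist: BootHistogram) -> None:
    table = np.column_stack([hist.edges[:-1], hist.edges[1:], hist.mean, hist.spread])
    with Path(path).open("w") as fh:
        fh.write("#bin_left\tbin_right\tmean\tspread\n")
        np.savetxt(fh, table, fmt="%.8g", delimiter="\t")


def write_edges_tsv(path, edges, header=("source", "target", "weight", "iteration")) -> None:
    with Path(path).open("w") as fh:
        fh.write("#" + "\t".join(header) + "\n")
        for row in edges:
            fh.write("\t".join(str(x) for x in row) + "\n")


def write_bias_tsv(path, bias) -> None:
    nd = bias.centers.shape[1] if bias.n_gaussians else len(bias.widths)
    with Path(path).open("w") as fh:
        cols = ["step"] + [f"center{d}" for d in range(nd)] \
            + [f"width{d}" for d in range(nd)] + ["height"]
        fh.write("#" + "\t".join(cols) + "\n")
        for g in range(bias.n_gaussians):
            row = [str((g + 1) * bias.stride)] \
                + [f"{c:.8g}" for c in bias.centers[g]] \
                + [f"{w:.8g}" for w in bias.widths] + [f"{bias.height:.8g}"]
            fh.write("\t".join(row) + "\n")


def write_fes_tsv(path, fes) -> None:
    mesh = np.meshgrid(*fes.axes, indexing="ij")
    cols = [m.ravel() for m in mesh] + [fes.values.ravel()]
    with Path(path).open("w") as fh:
        fh.write("#" + "\t".join([f"cv{d}" for d in range(fes.ndim)] + ["free_energy"]) + "\n")
        np.savetxt(fh, np.column_stack(cols), fmt="%.8g", delimiter="\t")


def write_string_tsv(path, string_path) -> None:
    with Path(path).open("w") as fh:
        nd = string_path.nodes.shape[1]
        fh.write("#" + "\t".join(["alpha"] + [f"cv{d}" for d in range(nd)]) + "\n")
        np.savetxt(fh, np.column_stack([string_path.alpha, string_path.nodes]),
                   fmt="%.8g", delimiter="\t")


def load_structure_coords(path):
    """Read a structure/trajectory file into (coords (n_frames, n_atoms, 3),
    topology) through mdtraj; a thin adapter so callers needing atom
    selections can stay format-agnostic. Requires the optional mdtraj
    dependency."""
    try:
        import mdtraj
    except ImportError as err:  # pragma: no cover - depends on extras
        raise ImportError("reading structure files requires mdtraj "
                          "(install the 'traj' extra)") from err
    traj = mdtraj.load(str(path))
    return np.asarray(traj.xyz, dtype=float) * 10.0, traj.topology  # nm -> Angstrom
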