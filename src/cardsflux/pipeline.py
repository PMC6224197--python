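"""End-to-end pipeline driver.

Runs the synthetic -> discretize -> correlation/disorder -> MSM -> TPT
stages in dependency order from a single declarative configuration,
deriving one deterministic sub-seed per stage from the top-level seed, and
writes a manifest with per-stage output checksums so a rerun with the same
configuration is verifiably identical.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from . import cards, featurize, io, msm, synthetic, tpt

__all__ = ["PipelineConfig", "RunManifest", "run_pipeline", "validate_inputs"]

_VALID_KEYS = {
    "outdir", "seed", "n_residues", "dihedrals_per_residue", "frame_count",
    "edges", "stay_prob", "lag", "estimator", "n_boot", "toy_n_intermediate",
    "toy_forward_rate", "toy_backward_rate", "toy_bottleneck_edge",
    "toy_bottleneck_rate", "toy_n_steps", "k_paths", "stages",
}
_ALL_STAGES = ("simulate", "cards", "msm", "tpt")


@dataclass
class PipelineConfig:
    """Declarative configuration for a full synthetic pipeline run."""

    outdir: str = "pipeline_out"
    seed: int = 0
    # planted-network ensemble
    n_residues: int = 6
    dihedrals_per_residue: int = 2
    frame_count: int = 20_000
    edges: list = field(default_factory=lambda: [[0, 1, 0.8], [1, 2, 0.8]])
    stay_prob: float = 0.9
    # correlation analysis
    n_boot: int = 10
    # toy unbinding chain + MSM + TPT
    toy_n_intermediate: int = 5
    toy_forward_rate: float = 0.1
    toy_backward_rate: float = 0.1
    toy_bottleneck_edge: int = 3
    toy_bottleneck_rate: float = 0.001
    toy_n_steps: int = 200_000
    lag: int = 1
    estimator: str = "symmetric"
    k_paths: int = 10
    stages: list = field(default_factory=lambda: list(_ALL_STAGES))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        unknown = set(data) - _VALID_KEYS
        if unknown:
            raise ValueError(f"invalid config keys: {sorted(unknown)}")
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if self.lag < 1:
            raise ValueError("lag must be >= 1")
        if self.frame_count < 2:
            raise ValueError("frame_count must be >= 2")
        if self.k_paths < 1:
            raise ValueError("k_paths must be >= 1")
        if self.estimator not in ("symmetric", "raw"):
            raise ValueError("estimator must be 'symmetric' or 'raw'")
        for s in self.stages:
            if s not in _ALL_STAGES:
                raise ValueError(f"unknown stage: {s}")
        synthetic.PlantedNetworkSpec(
            n_residues=self.n_residues,
            dihedrals_per_residue=self.dihedrals_per_residue,
            edges=[tuple(e) for e in self.edges],
            frame_count=self.frame_count, stay_prob=self.stay_prob,
        ).validate()

    def stage_seed(self, stage: str) -> int:
        idx = _ALL_STAGES.index(stage)
        return int((self.seed * 1_000_003 + idx * 7919 + 17) % (2**31))


@dataclass
class RunManifest:
    """Record of a pipeline run: config hash, per-stage outputs and checksums."""

    config_hash: str
    seed: int
    stages: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1, sort_keys=True))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _config_hash(cfg: PipelineConfig) -> str:
    blob = json.dumps(asdict(cfg), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute the configured stages in dependency order.

    simulate: planted-network ensemble -> dihedral table; toy unbinding
    chain -> exact T + sampled trajectory. cards: discretize, correlation
    matrix, disorder profile. msm: estimate T from the sampled chain.
    tpt: committors, fluxes, highest-flux paths, rate-limiting step.
    Failures abort with the failing stage named; outputs and checksums land
    in the manifest.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config_hash=_config_hash(config), seed=config.seed)
    state: dict = {}
    for stage in _ALL_STAGES:
        if stage not in config.stages:
            continue
        t0 = time.perf_counter()
        try:
            outputs = _STAGE_FN[stage](config, outdir, state)
        except Exception as err:
            raise RuntimeError(f"pipeline stage '{stage}' failed: {err}") from err
        manifest.stages[stage] = {
            "outputs": {name: _sha256(Path(p)) for name, p in outputs.items()},
            "paths": {name: str(p) for name, p in outputs.items()},
            "seed": config.stage_seed(stage),
            "wall_time_s": round(time.perf_counter() - t0, 3),
        }
    manifest.to_json(outdir / "manifest.json")
    return manifest


def _stage_simulate(cfg: PipelineConfig, outdir: Path, state: dict) -> dict:
    spec = synthetic.PlantedNetworkSpec(
        n_residues=cfg.n_residues, dihedrals_per_residue=cfg.dihedrals_per_residue,
        edges=[tuple(e) for e in cfg.edges], frame_count=cfg.frame_count,
        stay_prob=cfg.stay_prob, seed=cfg.stage_seed("simulate"))
    series = synthetic.gen_coupled_rotamers(spec)
    state["series"] = series
    table = outdir / "dihedrals.tsv"
    io.write_dihedral_table(table, series)

    toy = synthetic.ToyUnbindingSpec(
        n_intermediate_states=cfg.toy_n_intermediate,
        forward_rate=cfg.toy_forward_rate, backward_rate=cfg.toy_backward_rate,
        bottleneck_edge=cfg.toy_bottleneck_edge,
        bottleneck_rate=cfg.toy_bottleneck_rate,
        seed=cfg.stage_seed("simulate") + 1)
    t_exact, trajs = synthetic.gen_unbinding_chain(toy, n_steps=cfg.toy_n_steps)
    state["toy_spec"] = toy
    state["toy_trajs"] = trajs
    t_path = outdir / "toy_transition_matrix.tsv"
    io.write_matrix_tsv(t_path, t_exact)
    d_path = outdir / "toy_dtraj.tsv"
    np.savetxt(d_path, trajs[0], fmt="%d")
    return {"dihedrals": table, "toy_transition_matrix": t_path, "toy_dtraj": d_path}


def _stage_cards(cfg: PipelineConfig, outdir: Path, state: dict) -> dict:
    if "series" not in state:
        raise RuntimeError("missing upstream output: run the simulate stage first")
    states = featurize.assign_rotamers(state["series"])
    matrix = cards.holistic_matrix(states)
    prefix = outdir / "correlation"
    io.save_correlation(prefix, matrix)
    res_ids, res_mat = cards.residue_matrix(matrix)
    rm_path = outdir / "residue_communication.tsv"
    io.write_matrix_tsv(rm_path, res_mat, labels=res_ids)
    disorder = cards.residue_disorder(states)
    dis_path = outdir / "disorder.tsv"
    io.write_matrix_tsv(dis_path, np.column_stack([disorder.residues, disorder.value]))
    state["correlation"] = matrix
    return {"correlation": prefix.with_suffix(".npz"),
            "correlation_meta": prefix.with_suffix(".json"),
            "residue_communication": rm_path, "disorder": dis_path}


def _stage_msm(cfg: PipelineConfig, outdir: Path, state: dict) -> dict:
    if "toy_trajs" not in state:
        raise RuntimeError("missing upstream output: run the simulate stage first")
    model = msm.transition_matrix(state["toy_trajs"], lag=cfg.lag,
                                  estimator=cfg.estimator)
    state["model"] = model
    t_path = outdir / "msm_transition_matrix.tsv"
    io.write_matrix_tsv(t_path, model.transition, labels=model.active)
    pi_path = outdir / "msm_stationary.tsv"
    io.write_matrix_tsv(pi_path, model.stationary[None, :], labels=model.active)
    return {"transition_matrix": t_path, "stationary": pi_path}


def _stage_tpt(cfg: PipelineConfig, outdir: Path, state: dict) -> dict:
    if "model" not in state:
        raise RuntimeError("missing upstream output: run the msm stage first")
    model = state["model"]
    n = model.n_states
    a = np.array([0])
    b = np.array([n - 1])
    net = tpt.flux_network(model, a, b)
    paths = tpt.top_paths(net, k=cfg.k_paths)
    consensus, bottlenecks = tpt.rate_limiting_step(paths)
    q_path = outdir / "committors.tsv"
    io.write_matrix_tsv(q_path, net.committor[None, :], labels=model.active)
    f_path = outdir / "net_flux.tsv"
    io.write_matrix_tsv(f_path, net.net, labels=model.active)
    p_path = outdir / "pathways.json"
    p_path.write_text(json.dumps({
        "total_flux": net.total_flux,
        "consensus_bottleneck": list(consensus),
        "paths": [{"states": p.states, "capacity": p.capacity,
                   "bottleneck": list(p.bottleneck)} for p in paths],
    }, indent=1))
    return {"committors": q_path, "net_flux": f_path, "pathways": p_path}


_STAGE_FN = {
    "simulate": _stage_simulate,
    "cards": _stage_cards,
    "msm": _stage_msm,
    "tpt": _stage_tpt,
}


def validate_inputs(paths) -> dict:
    """Per-file verdicts for dihedral-table inputs.

    Checks readability, header metadata consistency, the [-180, 180) angle
    range, NaN angles, and (across files) matching frame counts. Returns
    {path: {"ok": bool, "errors": [...], "warnings": [...], "n_frames": int}}.
    """
    report: dict = {}
    frame_counts: dict = {}
    for p in paths:
        entry = {"ok": True, "errors": [], "warnings": [], "n_frames": None}
        path = Path(p)
        try:
            series = read_dihedral_table_lenient(path, entry)
        except OSError as err:
            raise OSError(f"cannot read input file {path}: {err}") from err
        except ValueError as err:
            entry["ok"] = False
            entry["errors"].append(str(err))
            report[str(p)] = entry
            continue
        entry["n_frames"] = series.shape[0]
        frame_counts[str(p)] = series.shape[0]
        report[str(p)] = entry
    counts = set(frame_counts.values())
    if len(counts) > 1:
        for p in frame_counts:
            report[p]["ok"] = False
            report[p]["errors"].append(
                f"frame counts differ across inputs: {sorted(counts)}")
    return report


def read_dihedral_table_lenient(path: Path, entry: dict) -> np.ndarray:
    """Parse a dihedral table for validation, recording range/NaN problems."""
    with path.open() as fh:
        header = {}
        for _ in range(3):
            line = fh.readline()
            if not line.startswith("#"):
                raise ValueError("missing dihedral-table header line")
            key, *vals = line[1:].rstrip("\n").split("\t")
            header[key] = vals
        for key in ("dihedral_id", "residue", "class"):
            if key not in header:
                raise ValueError(f"header lacks '{key}' line")
        lens = {len(v) for v in header.values()}
        if len(lens) != 1:
            raise ValueError("header metadata lengths are inconsistent")
        angles = np.loadtxt(fh, delimiter="\t", ndmin=2)
    if angles.shape[1] != len(header["dihedral_id"]):
        raise ValueError("angle columns do not match header metadata")
    if np.isnan(angles).any():
        entry["warnings"].append("NaN angles present")
    finite = angles[~np.isnan(angles)]
    if finite.size and (finite.min() < -180.0 or finite.max() >= 180.0):
        entry["ok"] = False
        entry["errors"].append("angles outside [-180, 180)")
    return angles
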