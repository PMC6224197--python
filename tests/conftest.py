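import numpy as np
import pytest

from cardsflux import featurize, synthetic


@pytest.fixture(scope="session")
def planted_chain_ensemble():
    """10-residue ensemble with a planted A->B->C->D coupling chain
    (residues 0->1->2->3, epsilon 0.7), 100k frames."""
    spec = synthetic.PlantedNetworkSpec(
        n_residues=10, dihedrals_per_residue=2,
        edges=[(0, 1, 0.7), (1, 2, 0.7), (2, 3, 0.7)],
        frame_count=100_000, seed=2024)
    series = synthetic.gen_coupled_rotamers(spec)
    return spec, series


@pytest.fixture(scope="session")
def null_ensemble():
    """Fully independent (all couplings zero) 6-residue ensemble, 100k frames."""
    spec = synthetic.PlantedNetworkSpec(
        n_residues=6, dihedrals_per_residue=1, edges=[],
        frame_count=100_000, seed=11)
    return synthetic.gen_coupled_rotamers(spec)


@pytest.fixture(scope="session")
def null_states(null_ensemble):
    return featurize.assign_rotamers(null_ensemble)


def ideal_helix(n: int = 12, rise: float = 1.5, radius: float = 2.3,
                turn_deg: float = 100.0) -> np.ndarray:
    """Alpha-helix-like backbone trace along z."""
    t = np.arange(n) * np.radians(turn_deg)
    return np.stack([radius * np.cos(t), radius * np.sin(t),
                     rise * np.arange(n)], axis=1)


def rotation_matrix(axis, angle_deg) -> np.ndarray:
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    a = np.radians(angle_deg)
    k = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(a) * k + (1 - np.cos(a)) * (k @ k)
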