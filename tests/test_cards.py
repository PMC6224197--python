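"""Mutual-information channels, dynamical-state parsing, residue
communication, network tracing and entropy-based disorder."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cardsflux import cards, featurize, synthetic
from cardsflux.cards import (
    JointDistribution,
    assign_dynamical_states,
    channel_capacity,
    communication_to_target,
    delta_disorder,
    global_communication,
    holistic_matrix,
    mutual_information,
    residue_disorder,
    residue_matrix,
    trace_network,
)
from cardsflux.featurize import StateSeries, assign_rotamers


def brute_force_mi(counts: np.ndarray) -> float:
    """Independent oracle: explicit cell-by-cell summation of the MI formula."""
    counts = np.asarray(counts, dtype=float)
    n = counts.sum()
    total = 0.0
    px = counts.sum(axis=1) / n
    py = counts.sum(axis=0) / n
    for i in range(counts.shape[0]):
        for j in range(counts.shape[1]):
            pij = counts[i, j] / n
            if pij > 0:
                total += pij * np.log2(pij / (px[i] * py[j]))
    return total


def make_states(columns, classes=None, residues=None) -> StateSeries:
    """Build a StateSeries from integer state columns (3-state by default)."""
    states = np.stack([np.asarray(c, dtype=np.int8) for c in columns], axis=1)
    nd = states.shape[1]
    classes = classes or ["chi1"] * nd
    alphabet = np.array([2 if c in ("phi", "psi") else 3 for c in classes])
    residues = np.arange(nd) if residues is None else np.asarray(residues)
    return StateSeries(states=states, alphabet=alphabet, residues=residues,
                       classes=classes)


class TestMutualInformation:
    def test_perfectly_correlated_uniform_binary_is_one_bit(self):
        j = JointDistribution(np.array([[0.5, 0.0], [0.0, 0.5]]))
        assert mutual_information(j) == pytest.approx(1.0, abs=1e-12)

    def test_product_distribution_is_zero(self):
        j = JointDistribution(np.outer([0.3, 0.7], [0.2, 0.5, 0.3]))
        assert mutual_information(j) == pytest.approx(0.0, abs=1e-12)

    def test_four_term_oracle_value(self):
        table = np.array([[0.4, 0.1], [0.1, 0.4]])
        expected = brute_force_mi(table)  # ~0.278 bits
        assert expected == pytest.approx(0.278, abs=5e-4)
        assert mutual_information(JointDistribution(table)) == pytest.approx(expected, abs=1e-12)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_matches_oracle_and_symmetric_on_random_tables(self, seed):
        rng = np.random.default_rng(seed)
        nx, ny = rng.integers(2, 5, size=2)
        counts = rng.integers(0, 30, size=(nx, ny)).astype(float)
        if counts.sum() == 0:
            counts[0, 0] = 1
        mi = mutual_information(JointDistribution(counts))
        assert mi == pytest.approx(brute_force_mi(counts), abs=1e-12)
        assert mi == pytest.approx(brute_force_mi(counts.T), abs=1e-12)  # symmetry
        assert mi >= 0

    def test_merging_states_never_increases_mi(self):
        # data-processing: collapsing two rotamer rows can only lose information
        rng = np.random.default_rng(13)
        for _ in range(50):
            counts = rng.integers(0, 40, size=(3, 3)).astype(float)
            counts[0, 0] += 1
            merged = np.vstack([counts[0] + counts[1], counts[2]])
            assert mutual_information(JointDistribution(merged)) \
                <= mutual_information(JointDistribution(counts)) + 1e-12


class TestChannelCapacity:
    @pytest.mark.parametrize("nx,ny,expected", [
        (3, 3, np.log2(3)),  # structure-structure, side chains
        (3, 2, 1.0),         # structure-dynamics
        (2, 2, 1.0),         # dynamics-dynamics
    ])
    def test_capacity_values(self, nx, ny, expected):
        assert channel_capacity(nx, ny) == pytest.approx(expected)

    def test_degenerate_alphabet_rejected(self):
        with pytest.raises(ValueError):
            channel_capacity(1, 3)


class TestDynamicalStates:
    def test_constant_series_all_ordered(self):
        s = make_states([np.zeros(100)])
        dyn = assign_dynamical_states(s)
        assert np.all(dyn.codes == cards.ORDERED)
        assert np.isnan(dyn.ordered_timescale[0])

    def test_strict_alternation_all_disordered(self):
        s = make_states([np.arange(100) % 2])
        dyn = assign_dynamical_states(s)
        assert np.all(dyn.codes == cards.DISORDERED)

    def test_plateaus_ordered_flicker_bursts_disordered(self):
        # 100-frame plateaus interleaved with 2-frame flicker bursts: the
        # log-space nearest-timescale rule must separate the two modes
        col = []
        state = 0
        for _ in range(6):
            col.extend([state] * 100)
            state = 1 - state
            for _ in range(4):  # burst of 2-frame segments
                col.extend([state] * 2)
                state = 1 - state
        s = make_states([col], classes=["phi"])
        dyn = assign_dynamical_states(s)
        codes = dyn.codes[:, 0]
        col = np.asarray(col)
        starts = np.concatenate([[0], np.flatnonzero(np.diff(col)) + 1])
        durs = np.diff(np.concatenate([starts, [col.size]]))
        for start, dur in zip(starts, durs):
            expected = cards.ORDERED if dur >= 100 else cards.DISORDERED
            assert np.all(codes[start:start + dur] == expected)
        assert dyn.ordered_timescale[0] > dyn.disordered_timescale[0]

    def test_single_frame_rejected(self):
        with pytest.raises(ValueError):
            assign_dynamical_states(make_states([[0]]))


class TestHolisticMatrix:
    def test_duplicated_dihedral_saturates_structural_channel(self):
        rng = np.random.default_rng(21)
        col = rng.integers(0, 3, size=30_000)
        s = make_states([col, col])
        m = holistic_matrix(s)
        # near-uniform occupancy -> normalized structural MI at capacity
        assert m.i_ss[0, 1] > 0.99
        assert np.all(m.i_h >= 0) and np.all(m.i_h <= 4.0 + 1e-12)

    def test_independent_chains_near_zero(self, null_states):
        m = holistic_matrix(null_states)
        off = m.i_h[~np.eye(m.n_dihedrals, dtype=bool)]
        assert off.max() <= 0.05  # finite-sample null at 100k frames

    def test_planted_edge_is_off_diagonal_maximum(self):
        spec = synthetic.PlantedNetworkSpec(
            n_residues=4, dihedrals_per_residue=1, edges=[(0, 1, 1.0)],
            frame_count=50_000, seed=3)
        states = assign_rotamers(synthetic.gen_coupled_rotamers(spec))
        m = holistic_matrix(states)
        ih = m.i_h.copy()
        np.fill_diagonal(ih, -1)
        assert np.unravel_index(np.argmax(ih), ih.shape) in [(0, 1), (1, 0)]

    def test_symmetry_and_channel_bounds(self, null_states):
        m = holistic_matrix(null_states)
        assert np.allclose(m.i_h, m.i_h.T, atol=1e-12)
        assert np.allclose(m.i_ss, m.i_ss.T, atol=1e-12)
        assert np.allclose(m.i_dd, m.i_dd.T, atol=1e-12)
        assert np.allclose(m.i_sd, m.i_ds.T, atol=1e-12)  # mixed channels transpose
        for ch in (m.i_ss, m.i_sd, m.i_ds, m.i_dd):
            assert ch.min() >= 0 and ch.max() <= 1 + 1e-12

    def test_frame_count_mismatch_rejected(self):
        s = make_states([np.zeros(50), np.ones(50)])
        dyn = assign_dynamical_states(make_states([np.zeros(40), np.ones(40)]))
        with pytest.raises(ValueError, match="frame counts"):
            holistic_matrix(s, dyn)


class TestResidueCommunication:
    def test_single_dihedral_residues_profile_is_restricted_row_sum(self):
        spec = synthetic.PlantedNetworkSpec(
            n_residues=5, dihedrals_per_residue=1, edges=[(0, 1, 0.9)],
            frame_count=20_000, seed=5)
        states = assign_rotamers(synthetic.gen_coupled_rotamers(spec))
        m = holistic_matrix(states)
        prof = communication_to_target(states, [0], n_boot=3, seed=0)
        for r, score in zip(prof.residues, prof.score):
            assert score == pytest.approx(m.i_h[r, 0], abs=1e-12)

    def test_chain_ordering_toward_target(self, planted_chain_ensemble):
        _, series = planted_chain_ensemble
        states = assign_rotamers(series)
        prof = communication_to_target(states, [2], n_boot=3, seed=1)
        score = dict(zip(prof.residues, prof.score))
        background = max(v for r, v in score.items() if r >= 4)
        assert score[1] > score[0] > background  # B outranks A; both beat noise
        assert score[3] > background

    def test_unknown_target_rejected(self, null_states):
        with pytest.raises(ValueError, match="unknown"):
            communication_to_target(null_states, [99])


class TestTraceNetwork:
    def test_planted_chain_recovers_frontier_order(self, planted_chain_ensemble):
        _, series = planted_chain_ensemble
        states = assign_rotamers(series)
        net = trace_network(states, seed_site=[0], sink_site=[3], n_boot=5, seed=0)
        assert [f.tolist() for f in net.frontiers] == [[1], [2], [3]]
        assert net.reached_sink

    def test_null_ensemble_terminates_without_sink(self, null_states):
        net = trace_network(null_states, seed_site=[0], sink_site=[5],
                            n_boot=5, seed=3)
        assert not net.reached_sink
        assert len(net.frontiers) == 0

    def test_adjacent_strong_edge_single_step(self):
        spec = synthetic.PlantedNetworkSpec(
            n_residues=6, dihedrals_per_residue=1, edges=[(0, 1, 1.0)],
            frame_count=30_000, seed=8)
        states = assign_rotamers(synthetic.gen_coupled_rotamers(spec))
        net = trace_network(states, seed_site=[0], sink_site=[1], n_boot=5, seed=0)
        assert net.reached_sink and len(net.frontiers) == 1

    def test_overlapping_seed_sink_rejected(self, null_states):
        with pytest.raises(ValueError, match="disjoint"):
            trace_network(null_states, [0], [0])


class TestGlobalCommunication:
    def test_hub_attains_maximum(self):
        spec = synthetic.PlantedNetworkSpec(
            n_residues=6, dihedrals_per_residue=1,
            edges=[(0, 1, 0.3), (0, 2, 0.3), (0, 3, 0.3)],
            frame_count=50_000, seed=4)
        states = assign_rotamers(synthetic.gen_coupled_rotamers(spec))
        res, vals = global_communication(holistic_matrix(states))
        assert res[np.argmax(vals)] == 0

    def test_two_residue_symmetry(self):
        spec = synthetic.PlantedNetworkSpec(
            n_residues=2, dihedrals_per_residue=1, edges=[(0, 1, 0.5)],
            frame_count=20_000, seed=6)
        states = assign_rotamers(synthetic.gen_coupled_rotamers(spec))
        _, vals = global_communication(holistic_matrix(states))
        assert vals[0] == pytest.approx(vals[1])

    def test_residue_matrix_symmetric_nonnegative(self, planted_chain_ensemble):
        _, series = planted_chain_ensemble
        states = assign_rotamers(series)
        _, mat = residue_matrix(holistic_matrix(states))
        assert np.allclose(mat, mat.T) and mat.min() >= 0


class TestDisorder:
    def test_frozen_ensemble_zero(self):
        s = make_states([np.zeros(1000), np.ones(1000)], residues=[0, 0])
        prof = residue_disorder(s)
        assert prof.value[0] == 0.0

    def test_half_occupied_three_state_dihedral(self):
        # occupancies (0.5, 0.5, 0): H = 1 bit, capacity log2(3)
        col = np.array([0, 1] * 500)
        prof = residue_disorder(make_states([col]))
        assert prof.value[0] == pytest.approx(1.0 / np.log2(3), abs=1e-12)

    def test_uniform_occupancy_maximal(self):
        rng = np.random.default_rng(30)
        s = make_states([rng.integers(0, 3, 100_000) for _ in range(2)],
                        residues=[0, 0])
        prof = residue_disorder(s)
        assert prof.value[0] >= 0.99
        assert prof.value[0] <= 1.0

    def test_delta_disorder_antisymmetric_and_localized(self):
        frozen = make_states([np.zeros(2000), np.zeros(2000)], residues=[0, 1])
        half = make_states([np.zeros(2000), np.array([0, 1] * 1000)], residues=[0, 1])
        d = delta_disorder(frozen, half)
        assert d.value[0] == 0.0
        assert d.value[1] > 0  # support grew on residue 1 only
        swapped = delta_disorder(half, frozen)
        assert np.allclose(swapped.value, -d.value)

    def test_residue_mismatch_rejected(self):
        a = make_states([np.zeros(100)], residues=[0])
        b = make_states([np.zeros(100)], residues=[1])
        with pytest.raises(ValueError, match="different residues"):
            delta_disorder(a, b)
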