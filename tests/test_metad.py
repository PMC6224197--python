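"""Metadynamics bias deposition, free-energy reconstruction, string MFEP
and seeding."""

import warnings

import numpy as np
import pytest
from scipy import stats

from cardsflux import potentials, synthetic
from cardsflux.metad import (
    BiasPotential,
    FreeEnergySurface,
    StringPath,
    fes_estimate,
    run_metadynamics,
    seed_along_path,
    string_mfep,
)


def analytic_fes(potential, axes) -> FreeEnergySurface:
    """Ground-truth surface: the potential itself evaluated on a grid."""
    axes = tuple(np.asarray(a, dtype=float) for a in axes)
    mesh = np.meshgrid(*axes, indexing="ij")
    pts = np.stack([m.ravel() for m in mesh], axis=-1)
    vals = np.asarray(potential.energy(pts)).reshape(mesh[0].shape)
    return FreeEnergySurface(axes=axes, values=vals - vals.min())


class TestBiasPotential:
    def test_energy_nonnegative_and_monotone_in_deposits(self):
        rng = np.random.default_rng(0)
        centers = rng.uniform(-1, 1, size=(20, 1))
        pts = np.linspace(-1.5, 1.5, 50)[:, None]
        prev = np.zeros(50)
        for k in range(1, 21):
            bias = BiasPotential(centers=centers[:k], widths=[0.2], height=1.5, stride=10)
            v = bias.energy(pts)
            assert np.all(v >= prev - 1e-12)
            prev = v

    def test_gradient_matches_finite_difference(self):
        bias = BiasPotential(centers=[[0.3], [-0.5]], widths=[0.2], height=1.5, stride=10)
        h = 1e-6
        for x in (-0.4, 0.0, 0.45):
            fd = (bias.energy(np.array([x + h])) - bias.energy(np.array([x - h]))) / (2 * h)
            assert bias.gradient(np.array([x]))[0] == pytest.approx(fd, abs=1e-6)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            BiasPotential(centers=[[0.0]], widths=[0.0], height=1.5, stride=10)
        with pytest.raises(ValueError):
            BiasPotential(centers=[[0.0]], widths=[0.1], height=-1.0, stride=10)


class TestRunMetadynamics:
    def test_zero_height_bit_identical_to_unbiased_run(self):
        pot = potentials.DoubleWell1D(barrier=10.0, tilt=0.0)
        traj, bias = run_metadynamics(pot, height=0.0, n_steps=5000,
                                      temperature=2.494, step_size=0.002,
                                      seed=3, x0=np.array([-1.0]))
        plain = synthetic.gen_particle_trajectory(pot, 2.494, 0.002, 5000,
                                                  seed=3, x0=[-1.0])
        assert bias.n_gaussians == 0
        assert np.array_equal(traj.positions, plain.positions)

    def test_bias_enables_barrier_crossing(self):
        # 10 kT barrier: unbiased walker stays in its well on this budget,
        # the biased one crosses
        pot = potentials.DoubleWell1D(barrier=24.94, tilt=0.0)
        unbiased = synthetic.gen_particle_trajectory(pot, 2.494, 0.002, 100_000,
                                                     seed=5, x0=[-1.0])
        biased, _ = run_metadynamics(pot, height=1.5, widths=0.1, stride=500,
                                     n_steps=100_000, temperature=2.494,
                                     step_size=0.002, seed=5, x0=np.array([-1.0]))
        assert unbiased.positions[:, 0].max() < 0.0
        assert biased.positions[:, 0].max() > 0.5

    def test_flattened_well_samples_near_uniformly(self):
        # once the bias fills a harmonic well the visited distribution over
        # the well interior approaches uniformity
        pot = potentials.Harmonic(k=10.0, halfwidth=4.0)
        traj, _ = run_metadynamics(pot, height=1.5, widths=0.1, stride=500,
                                   n_steps=300_000, temperature=1.0,
                                   step_size=0.002, seed=2, x0=np.array([0.0]),
                                   record_stride=10)
        x = traj.positions[traj.n_frames // 2:, 0]
        win = 1.0
        sel = (x[np.abs(x) < win] + win) / (2 * win)
        ks_biased = stats.kstest(sel, "uniform").statistic
        plain = synthetic.gen_particle_trajectory(pot, 1.0, 0.002, 100_000,
                                                  seed=2, x0=[0.0]).positions[:, 0]
        sel0 = (plain[np.abs(plain) < win] + win) / (2 * win)
        ks_unbiased = stats.kstest(sel0, "uniform").statistic
        assert ks_biased < 0.15
        assert ks_biased < ks_unbiased

    def test_deterministic_per_seed(self):
        pot = potentials.DoubleWell1D(barrier=10.0, tilt=1.0)
        runs = [run_metadynamics(pot, height=1.5, widths=0.1, stride=100,
                                 n_steps=20_000, temperature=2.494,
                                 step_size=0.002, seed=11, x0=np.array([-1.0]))
                for _ in range(2)]
        assert np.array_equal(runs[0][0].positions, runs[1][0].positions)
        assert np.array_equal(runs[0][1].centers, runs[1][1].centers)

    def test_escape_truncates_with_diagnostic(self):
        pot = potentials.Harmonic(k=0.01, halfwidth=0.4)
        with pytest.warns(UserWarning, match="truncated"):
            traj, _ = run_metadynamics(pot, height=1.5, widths=0.1, stride=50,
                                       n_steps=200_000, temperature=5.0,
                                       step_size=0.002, seed=1, x0=np.array([0.0]))
        assert traj.truncated


class TestFesEstimate:
    def test_single_gaussian_inverted_with_zero_minimum(self):
        bias = BiasPotential(centers=[[0.2]], widths=[0.3], height=2.0, stride=10)
        grid = np.linspace(-1, 1, 201)
        fes = fes_estimate(bias, grid)
        assert fes.values.min() == 0.0
        assert grid[np.argmin(fes.values)] == pytest.approx(0.2, abs=0.02)
        # far from the Gaussian, F approaches the full height
        assert fes.values[0] == pytest.approx(
            2.0 - 2.0 * np.exp(-0.5 * (1.2 / 0.3) ** 2), abs=1e-9)

    def test_linearity_two_identical_gaussians(self):
        one = BiasPotential(centers=[[0.0]], widths=[0.2], height=1.0, stride=10)
        two = BiasPotential(centers=[[0.0], [0.0]], widths=[0.2], height=1.0, stride=10)
        grid = np.linspace(-1, 1, 101)
        f1 = fes_estimate(one, grid)
        f2 = fes_estimate(two, grid)
        # before anchoring, the bias doubles; anchored surfaces scale by 2
        assert np.allclose(f2.values, 2.0 * f1.values, atol=1e-12)

    def test_double_well_free_energy_difference_and_barrier(self):
        # the headline reconstruction: 10 kT barrier, 1.5 kJ/mol Gaussians
        pot = potentials.DoubleWell1D(barrier=25.0, tilt=2.5, halfwidth=3.5)
        lo, hi = pot.well_positions()
        grid = np.linspace(-3.5, 3.5, 351)
        traj, bias = run_metadynamics(pot, height=1.5, widths=0.2, stride=8000,
                                      n_steps=48_000_000, temperature=2.494,
                                      step_size=5e-4, seed=1, x0=np.array([lo]),
                                      record_stride=1000)
        fes = fes_estimate(bias, grid, tail_average=0.9)
        df = float(fes.interpolate([[hi]])[0] - fes.interpolate([[lo]])[0])
        assert abs(df - pot.delta_f()) <= 0.5
        xs = np.linspace(-0.4, 0.4, 81)
        barrier_est = float(fes.interpolate(xs[:, None]).max()
                            - fes.interpolate([[lo]])[0])
        barrier_true = float(np.max(pot.energy(xs)) - pot.energy(np.array([lo])))
        assert barrier_est == pytest.approx(barrier_true, rel=0.15)

    def test_empty_bias_rejected(self):
        bias = BiasPotential(centers=np.empty((0, 1)), widths=[0.1],
                             height=1.0, stride=10)
        with pytest.raises(ValueError, match="no Gaussians"):
            fes_estimate(bias, np.linspace(-1, 1, 11))


class TestStringMfep:
    def test_quadratic_bowl_straight_line(self):
        pot = potentials.QuadraticBowl(kx=1.0, ky=4.0, halfwidth=3.0)
        axes = (np.linspace(-3, 3, 121), np.linspace(-3, 3, 121))
        fes = analytic_fes(pot, axes)
        path = string_mfep(fes, start=(-2.0, 0.0), end=(2.0, 0.0), n_nodes=21)
        # gradient has no component off the x-axis line: string stays straight
        spacing = float(fes.spacing.min())
        assert np.abs(path.nodes[:, 1]).max() < spacing

    def test_two_well_surface_passes_through_saddle(self):
        pot = potentials.DoubleWell2D(barrier=10.0, ky=8.0)
        axes = (np.linspace(-1.8, 1.8, 181), np.linspace(-1.5, 1.5, 151))
        fes = analytic_fes(pot, axes)
        # independent saddle location: grid search for the minimax point
        path = string_mfep(fes, start=(-1.0, 0.8), end=(1.0, -0.8),
                           n_nodes=31, max_iter=5000, tol=1e-5)
        top = path.nodes[np.argmax(fes.interpolate(path.nodes))]
        cell = np.linalg.norm(fes.spacing)
        assert np.linalg.norm(top - pot.saddle) <= cell

    def test_endpoints_immobile_and_equal_arc_spacing(self):
        pot = potentials.DoubleWell2D()
        axes = (np.linspace(-1.8, 1.8, 91), np.linspace(-1.5, 1.5, 76))
        fes = analytic_fes(pot, axes)
        start, end = np.array([-1.0, 0.0]), np.array([1.0, 0.0])
        path = string_mfep(fes, start, end, n_nodes=25)
        assert np.array_equal(path.nodes[0], start)
        assert np.array_equal(path.nodes[-1], end)
        seg = np.linalg.norm(np.diff(path.nodes, axis=0), axis=1)
        assert seg.max() / seg.min() < 1.02  # +-1% equal arc length

    def test_descent_property(self):
        pot = potentials.DoubleWell2D()
        axes = (np.linspace(-1.8, 1.8, 91), np.linspace(-1.5, 1.5, 76))
        fes = analytic_fes(pot, axes)
        # a path displaced off the MFEP relaxes to lower total F
        bent = string_mfep(fes, (-1.0, 0.9), (1.0, 0.9), n_nodes=15, max_iter=0)
        relaxed = string_mfep(fes, (-1.0, 0.9), (1.0, 0.9), n_nodes=15,
                              max_iter=3000, tol=1e-6)
        assert fes.interpolate(relaxed.nodes).sum() \
            <= fes.interpolate(bent.nodes).sum() + 1e-9

    def test_degenerate_start_equals_end(self):
        fes = analytic_fes(potentials.QuadraticBowl(), (np.linspace(-1, 1, 11),
                                                        np.linspace(-1, 1, 11)))
        path = string_mfep(fes, (0.3, 0.3), (0.3, 0.3))
        assert path.n_nodes == 1

    def test_outside_grid_rejected(self):
        fes = analytic_fes(potentials.QuadraticBowl(), (np.linspace(-1, 1, 11),
                                                        np.linspace(-1, 1, 11)))
        with pytest.raises(ValueError, match="inside the grid"):
            string_mfep(fes, (-5.0, 0.0), (0.5, 0.0))


class TestSeedAlongPath:
    def _path(self):
        nodes = np.stack([np.linspace(0, 1, 11), np.zeros(11)], axis=1)
        return StringPath(nodes=nodes, alpha=np.linspace(0, 1, 11))

    def _traj(self, positions):
        return synthetic.CVTrajectory(positions=np.asarray(positions, dtype=float),
                                      step_size=0.01, temperature=1.0)

    def test_trajectory_on_path_gives_evenly_spaced_frames(self):
        path = self._path()
        traj = self._traj(np.stack([np.linspace(0, 1, 101), np.zeros(101)], axis=1))
        seeds = seed_along_path(path, traj, n=5, max_dist=0.05)
        assert len(seeds.frame_indices) == 5
        assert np.allclose(seeds.cv_values[:, 0], [0, 0.25, 0.5, 0.75, 1.0], atol=0.01)

    def test_single_seed_is_midpoint(self):
        path = self._path()
        traj = self._traj(np.stack([np.linspace(0, 1, 101), np.zeros(101)], axis=1))
        seeds = seed_along_path(path, traj, n=1)
        assert seeds.cv_values[0, 0] == pytest.approx(0.5, abs=0.01)

    def test_partial_coverage_warns_and_skips(self):
        path = self._path()
        traj = self._traj(np.stack([np.linspace(0, 0.4, 41), np.zeros(41)], axis=1))
        with pytest.warns(UserWarning, match="skipped"):
            seeds = seed_along_path(path, traj, n=5, max_dist=0.05)
        assert 0 < len(seeds.frame_indices) < 5
        assert len(seeds.skipped) == 5 - len(seeds.frame_indices)

    def test_no_nearby_frame_rejected(self):
        path = self._path()
        traj = self._traj(np.full((10, 2), 50.0))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            with pytest.raises(ValueError, match="near any path point"):
                seed_along_path(path, traj, n=3, max_dist=0.1)
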