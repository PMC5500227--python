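"""MSD estimators, power-law fits and turning-angle statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cortexmesh.errors import EmptyInputError, InvalidDataError, InvalidParameterError
from cortexmesh.spt_stats import (
    AngleDistribution,
    angle_distribution,
    angle_mode,
    ensemble_ta_msd,
    fit_anomalous_exponent,
    fit_diffusivity,
    lag_invariance_statistic,
    ta_msd,
    turning_angles,
)
from cortexmesh.trajectory import Trajectory, TrajectoryEnsemble

from conftest import make_random_trajectory


def brute_force_ta_msd(positions, k):
    n = len(positions)
    total = 0.0
    for i in range(n - k):
        d = positions[i + k] - positions[i]
        total += d @ d
    return total / (n - k)


class TestTaMSD:
    def test_ballistic_hand_example(self):
        traj = Trajectory("b", np.arange(4.0), np.array([[0, 0], [1, 0], [2, 0], [3, 0.0]]))
        msd = ta_msd(traj, max_lag=3.0)
        np.testing.assert_allclose(msd.values, [1.0, 4.0, 9.0])

    def test_stationary_particle_is_zero(self):
        traj = Trajectory("s", np.arange(10) * 0.02, np.full((10, 2), 3.7))
        assert np.all(ta_msd(traj, 0.1).values == 0)

    def test_matches_brute_force(self, rng):
        """The vectorized estimator equals the naive double loop to 1e-12
        relative on random trajectories."""
        for i in range(10):
            traj = make_random_trajectory(rng, n=100, track_id=f"r{i}")
            msd = ta_msd(traj, max_lag=50 * 0.02)
            for j, k in enumerate(range(1, len(msd.values) + 1)):
                expected = brute_force_ta_msd(traj.positions, k)
                assert abs(msd.values[j] - expected) <= 1e-12 * max(expected, 1e-30)

    def test_too_short_and_bad_lag(self):
        traj = Trajectory("x", [0.0], [[0.0, 0.0]])
        with pytest.raises(InvalidDataError):
            ta_msd(traj, 1.0)
        traj2 = Trajectory("y", [0.0, 0.02], [[0, 0], [1, 1.0]])
        with pytest.raises(InvalidParameterError):
            ta_msd(traj2, 10.0)


class TestEnsembleMSD:
    def test_identical_trajectories_zero_spread(self, random_trajectory):
        t = random_trajectory
        ens = TrajectoryEnsemble(
            [Trajectory(f"c{i}", t.times, t.positions) for i in range(4)], t.dt
        )
        msd = ensemble_ta_msd(ens, 0.4)
        np.testing.assert_allclose(msd.spread, 0.0, atol=1e-14)

    def test_singleton_equals_ta_msd(self, random_trajectory):
        ens = TrajectoryEnsemble([random_trajectory], random_trajectory.dt)
        np.testing.assert_allclose(
            ensemble_ta_msd(ens, 0.4).values, ta_msd(random_trajectory, 0.4).values
        )

    def test_empty_rejected(self):
        with pytest.raises(EmptyInputError):
            ensemble_ta_msd(TrajectoryEnsemble([], 0.02), 0.1)


class TestPowerLawFits:
    def test_exact_power_law_recovery(self):
        lags = np.arange(1, 40) * 0.02
        msd = type("C", (), {})
        from cortexmesh.spt_stats import MSDCurve

        curve = MSDCurve(lags, 0.02 * lags**0.74, np.zeros_like(lags), np.ones_like(lags))
        fit = fit_anomalous_exponent(curve, (lags[0], lags[-1]))
        assert abs(fit.exponent - 0.74) < 1e-12
        assert abs(fit.prefactor - 0.02) < 1e-12

    def test_linear_curve_exponent_one(self):
        from cortexmesh.spt_stats import MSDCurve

        lags = np.arange(1, 20) * 0.02
        curve = MSDCurve(lags, 4 * 0.19 * lags, np.zeros_like(lags), np.ones_like(lags))
        assert abs(fit_anomalous_exponent(curve, (0.02, 1.0)).exponent - 1.0) < 1e-12
        assert abs(fit_diffusivity(curve, (0.02, 1.0)).diffusivity - 0.19) < 1e-12

    def test_flat_curve_zero_diffusivity(self):
        from cortexmesh.spt_stats import MSDCurve

        lags = np.arange(1, 10) * 0.02
        curve = MSDCurve(lags, np.full_like(lags, 0.5), np.zeros_like(lags), np.ones_like(lags))
        assert fit_diffusivity(curve, (0.0, 1.0)).diffusivity == 0.0

    def test_zero_value_rejected(self):
        from cortexmesh.spt_stats import MSDCurve

        lags = np.arange(1, 10) * 0.02
        vals = lags.copy()
        vals[3] = 0.0
        curve = MSDCurve(lags, vals, np.zeros_like(lags), np.ones_like(lags))
        with pytest.raises(InvalidDataError):
            fit_anomalous_exponent(curve, (0.0, 1.0))

    def test_too_few_points_rejected(self):
        from cortexmesh.spt_stats import MSDCurve

        lags = np.arange(1, 10) * 0.02
        curve = MSDCurve(lags, lags, np.zeros_like(lags), np.ones_like(lags))
        with pytest.raises(InvalidDataError):
            fit_anomalous_exponent(curve, (0.02, 0.045))


class TestTurningAngles:
    @pytest.mark.parametrize(
        "third,expected",
        [((2.0, 0.0), 0.0), ((0.0, 0.0), 180.0), ((1.0, 1.0), 90.0)],
    )
    def test_hand_examples(self, third, expected):
        pos = np.array([[0.0, 0.0], [1.0, 0.0], list(third)])
        traj = Trajectory("h", np.arange(3) * 0.02, pos)
        angles = turning_angles(traj, 0.02)
        np.testing.assert_allclose(angles, [expected], atol=1e-12)

    def test_non_multiple_lag_rejected(self, random_trajectory):
        with pytest.raises(InvalidParameterError):
            turning_angles(random_trajectory, 0.03)

    def test_zero_displacements_skipped_and_counted(self):
        pos = np.array([[0, 0], [0, 0], [1, 0], [2, 0.0]])
        traj = Trajectory("z", np.arange(4) * 1.0, pos)
        angles, skipped = turning_angles(traj, 1.0, return_skips=True)
        assert skipped == 1
        np.testing.assert_allclose(angles, [0.0])

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_angles_bounded_and_density_normalized(self, seed):
        rng = np.random.default_rng(seed)
        traj = make_random_trajectory(rng, n=40)
        ens = TrajectoryEnsemble([traj], traj.dt)
        angles = turning_angles(traj, traj.dt)
        assert np.all((angles >= 0) & (angles <= 180))
        dist = angle_distribution(ens, [traj.dt])[0]
        widths = np.diff(dist.bin_edges)
        assert abs((dist.density * widths).sum() - 1.0) < 1e-9


class TestAngleDistribution:
    def test_brownian_is_uniform(self):
        """Free diffusion gives a flat turning-angle distribution."""
        from cortexmesh.simulators import simulate_brownian

        ens = simulate_brownian(0.1, 0.02, 200, 500, seed=13)
        dist = angle_distribution(ens, [0.02])[0]
        assert dist.n_angles > 90_000
        assert np.max(np.abs(dist.density - 1 / 180.0)) < 0.05 / 180.0

    def test_fbm_mode_at_180(self):
        from cortexmesh.simulators import FBMParams, simulate_fbm

        ens = simulate_fbm(FBMParams(hurst=0.3, n_steps=256, n_traj=300, seed=17))
        dist = angle_distribution(ens, [0.02])[0]
        assert angle_mode(dist) == 180.0

    def test_mode_tie_breaks_toward_180(self):
        edges = np.arange(0.0, 181.0, 5.0)
        dens = np.full(36, 1 / 180.0)
        dist = AngleDistribution(0.02, edges, dens, n_angles=100)
        mode, tie = angle_mode(dist, return_tie=True)
        assert mode == 180.0 and tie

    def test_rising_density_modes_at_edge(self):
        edges = np.arange(0.0, 181.0, 5.0)
        centers = 0.5 * (edges[:-1] + edges[1:])
        dens = centers / (centers.sum() * 5.0)
        dist = AngleDistribution(0.02, edges, dens, n_angles=10)
        assert angle_mode(dist) == 180.0


class TestLagInvariance:
    @staticmethod
    def point_mass(at_deg):
        edges = np.arange(0.0, 181.0, 5.0)
        dens = np.zeros(36)
        idx = min(int(at_deg // 5), 35)
        dens[idx] = 1 / 5.0
        return AngleDistribution(0.02, edges, dens, n_angles=10)

    def test_identical_distributions_give_zero(self):
        d = self.point_mass(90)
        assert lag_invariance_statistic([d, d]) == 0.0

    def test_opposite_point_masses_give_one(self):
        assert lag_invariance_statistic(
            [self.point_mass(0), self.point_mass(179)]
        ) == pytest.approx(1.0)

    def test_mismatched_bins_rejected(self):
        d1 = self.point_mass(90)
        edges = np.arange(0.0, 181.0, 10.0)
        d2 = AngleDistribution(0.02, edges, np.full(18, 1 / 180.0), n_angles=10)
        with pytest.raises(InvalidParameterError):
            lag_invariance_statistic([d1, d2])
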