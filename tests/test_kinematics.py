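"""Windowed velocities, windrose histograms and whole-path descriptors."""

import numpy as np
import pytest

from placotax import (
    Trajectory,
    TrialMeta,
    end_to_end_angle,
    first_passage_time,
    fraction_time_warmer,
    mean_velocity_components,
    momentary_velocities,
    windrose,
)
from tests.conftest import make_walk


def straight_up(n=21, step=0.05):
    return Trajectory(frame=np.arange(n), x=np.zeros(n), y=step * np.arange(n))


class TestMomentaryVelocities:
    def test_constant_velocity_path(self, warm_up_meta):
        kin = momentary_velocities(straight_up(), warm_up_meta, n=2)
        np.testing.assert_allclose(kin.v_parallel, 0.1, atol=1e-12)
        np.testing.assert_allclose(kin.v_orthogonal, 0.0, atol=1e-12)
        np.testing.assert_allclose(kin.speed, 0.1, atol=1e-12)
        assert kin.delta_t == pytest.approx(1.0)

    def test_stationary_trajectory_is_all_zero(self, warm_up_meta):
        traj = Trajectory(frame=np.arange(10), x=np.zeros(10), y=np.zeros(10))
        kin = momentary_velocities(traj, warm_up_meta, n=2)
        assert np.all(kin.speed == 0.0)

    def test_time_reversal_negates_parallel_velocity(self, warm_up_meta):
        traj, _ = make_walk("biased_crw", n_frames=101, seed=9, drift_bias=0.5)
        rev = Trajectory(frame=traj.frame, x=traj.x[::-1], y=traj.y[::-1])
        f = momentary_velocities(traj, warm_up_meta, n=2)
        b = momentary_velocities(rev, warm_up_meta, n=2)
        np.testing.assert_allclose(np.sort(b.v_parallel),
                                   np.sort(-f.v_parallel), atol=1e-12)

    def test_window_longer_than_series_is_empty(self, warm_up_meta):
        traj = straight_up(5)
        assert len(momentary_velocities(traj, warm_up_meta, n=10)) == 0

    def test_gap_windows_are_skipped(self, warm_up_meta):
        traj = straight_up(9)
        traj.valid[4] = False
        kin = momentary_velocities(traj, warm_up_meta, n=2, overlapping=True)
        # windows [2,4], [3,5] and [4,6] touch the gap
        assert len(kin) == (9 - 2) - 3

    def test_pythagorean_closure(self, warm_up_meta):
        traj, _ = make_walk("diffusive", n_frames=300, seed=2)
        kin = momentary_velocities(traj, warm_up_meta, n=2)
        np.testing.assert_allclose(kin.v_parallel**2 + kin.v_orthogonal**2,
                                   kin.speed**2, atol=1e-10)

    def test_rotation_covariance(self):
        """Rotating the trajectory and the gradient axis together leaves the
        decomposition unchanged."""
        traj, _ = make_walk("biased_crw", n_frames=200, seed=13, drift_bias=0.3)
        phi = 0.7
        c, s = np.cos(phi), np.sin(phi)
        rot = Trajectory(frame=traj.frame, x=c * traj.x - s * traj.y,
                         y=s * traj.x + c * traj.y)
        m1 = TrialMeta(theta=np.pi / 2)
        m2 = TrialMeta(theta=np.pi / 2 + phi)
        k1 = momentary_velocities(traj, m1, n=2)
        k2 = momentary_velocities(rot, m2, n=2)
        np.testing.assert_allclose(k1.v_parallel, k2.v_parallel, atol=1e-10)
        np.testing.assert_allclose(k1.v_orthogonal, k2.v_orthogonal, atol=1e-10)


class TestMeanVelocityComponents:
    def test_constant_walk_mean_equals_constant(self, warm_up_meta):
        kin = momentary_velocities(straight_up(), warm_up_meta, n=2)
        vp, vo, sp = mean_velocity_components(kin)
        assert vp == pytest.approx(0.1) and vo == pytest.approx(0.0)

    def test_cancelling_windows_average_to_zero_but_speed_positive(self, warm_up_meta):
        y = np.array([0.0, 0.05, 0.0])  # up then back down
        traj = Trajectory(frame=np.arange(3), x=np.zeros(3), y=y)
        kin = momentary_velocities(traj, warm_up_meta, n=1)
        vp, vo, sp = mean_velocity_components(kin)
        assert vp == pytest.approx(0.0, abs=1e-12)
        assert sp > 0

    def test_empty_input_raises(self, warm_up_meta):
        kin = momentary_velocities(straight_up(3), warm_up_meta, n=10)
        with pytest.raises(ValueError):
            mean_velocity_components(kin)

    def test_biased_cohort_has_positive_parallel_velocity(self):
        """Mean v_parallel over 50 biased seeds is positive at 3 SE."""
        means = []
        for seed in range(50):
            traj, meta = make_walk("biased_crw", n_frames=500, seed=seed,
                                   drift_bias=0.3)
            kin = momentary_velocities(traj, meta, n=2)
            means.append(mean_velocity_components(kin)[0])
        means = np.asarray(means)
        assert means.mean() > 3 * means.std(ddof=1) / np.sqrt(len(means))


class TestWindrose:
    def test_due_warm_mass_in_single_bin(self, warm_up_meta):
        kin = momentary_velocities(straight_up(100), warm_up_meta, n=20,
                                   overlapping=True)
        h = windrose(kin)
        assert h.sum() == pytest.approx(1.0)
        dir_mass = h.sum(axis=0)
        assert dir_mass[0] == pytest.approx(1.0)

    def test_total_mass_is_one(self, warm_up_meta):
        traj, _ = make_walk("diffusive", n_frames=500, seed=21)
        kin = momentary_velocities(traj, warm_up_meta, n=20, overlapping=True)
        h = windrose(kin, resolution_limit_mm=0.0601)
        assert h.sum() == pytest.approx(1.0)

    def test_empty_input_gives_zero_histogram(self, warm_up_meta):
        kin = momentary_velocities(straight_up(3), warm_up_meta, n=10)
        h = windrose(kin)
        assert h.sum() == 0.0

    def test_isotropic_walk_has_no_dominant_sector(self, warm_up_meta):
        """Direction mass of an isotropic walk stays below twice the uniform
        share (multinomial bound at 10^4 windows, checked over 50 seeds)."""
        for seed in range(50):
            rng = np.random.default_rng(seed)
            n = 10_000
            ang = rng.uniform(0, 2 * np.pi, n)
            L = rng.exponential(0.1, n)
            x = np.concatenate([[0], np.cumsum(L * np.cos(ang))])
            y = np.concatenate([[0], np.cumsum(L * np.sin(ang))])
            traj = Trajectory(frame=np.arange(n + 1), x=x, y=y)
            kin = momentary_velocities(traj, warm_up_meta, n=1)
            h = windrose(kin)
            assert h.sum(axis=0).max() <= 2.0 / 16.0


class TestFirstPassage:
    def test_straight_walk_at_half_mm_per_min(self, warm_up_meta):
        traj = straight_up(41, step=0.25)  # 0.5 mm/min
        fp = first_passage_time(traj, radius_mm=5.0)
        assert not fp.censored
        assert fp.time_min == pytest.approx(10.0)

    def test_confined_walk_is_censored(self):
        traj = straight_up(50, step=0.01)
        fp = first_passage_time(traj, radius_mm=5.0)
        assert fp.censored and fp.time_min is None

    def test_zero_radius_is_reached_immediately(self):
        fp = first_passage_time(straight_up(5), radius_mm=0.0)
        assert fp.time_min == 0.0


class TestFractionTimeWarmer:
    def test_all_up_path(self, warm_up_meta):
        traj = straight_up(20)
        traj.x[0] = 0.0
        # first frame sits exactly at the start isotherm: not "warmer"
        assert fraction_time_warmer(traj, warm_up_meta) == pytest.approx(19 / 20)

    def test_symmetric_square_wave(self, warm_up_meta):
        y = np.tile([0.5, -0.5], 50)
        traj = Trajectory(frame=np.arange(100), x=np.zeros(100), y=y)
        assert fraction_time_warmer(traj, warm_up_meta) == pytest.approx(0.5)

    def test_stationary_at_origin_is_zero(self, warm_up_meta):
        traj = Trajectory(frame=np.arange(10), x=np.zeros(10), y=np.zeros(10))
        assert fraction_time_warmer(traj, warm_up_meta) == 0.0


class TestEndToEndAngle:
    def test_cardinal_directions(self, warm_up_meta):
        for (ex, ey), expected in [((0, 1), 0.0), ((0, -1), 180.0),
                                   ((-1, 0), 90.0), ((1, 0), -90.0)]:
            traj = Trajectory(frame=np.arange(2), x=np.array([0.0, ex]),
                              y=np.array([0.0, ey]))
            assert end_to_end_angle(traj, warm_up_meta) == pytest.approx(expected)

    def test_zero_net_displacement_undefined(self, warm_up_meta):
        traj = Trajectory(frame=np.arange(3), x=np.array([0.0, 1.0, 0.0]),
                          y=np.array([0.0, 1.0, 0.0]))
        with pytest.raises(ValueError):
            end_to_end_angle(traj, warm_up_meta)
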