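"""Dispersal statistics: MSD and alpha, path metrics, persistence length,
RMSD crossover fits and step-length model comparison."""

import numpy as np
import pytest

from placotax import (
    Trajectory,
    TrialMeta,
    fit_rmsd_ballistic,
    fit_rmsd_taylor,
    levy_pdf,
    loglog_slope,
    msd_axis,
    path_metrics,
    persistence_length_scan,
    step_length_fits,
    taylor_rmsd,
    wlc_mean_square_displacement,
)
from placotax.trajstats import MSDCurve
from tests.conftest import make_walk


def ballistic_up(n=211, step=0.05):
    return Trajectory(frame=np.arange(n), x=np.zeros(n), y=step * np.arange(n))


class TestMsdAxis:
    def test_ballistic_parallel_matches_closed_form(self, warm_up_meta):
        msd = msd_axis(ballistic_up(), warm_up_meta, "parallel")
        expected = (0.1 * msd.lag_min) ** 2  # v = 0.1 mm/min
        np.testing.assert_allclose(msd.msd, expected, rtol=1e-10)

    def test_ballistic_orthogonal_is_zero(self, warm_up_meta):
        msd = msd_axis(ballistic_up(), warm_up_meta, "orthogonal")
        np.testing.assert_allclose(msd.msd, 0.0, atol=1e-20)

    def test_short_trajectory_rejected_under_end_window(self, warm_up_meta):
        with pytest.raises(ValueError):
            msd_axis(ballistic_up(100), warm_up_meta)

    def test_full_window_rule_accepts_short_series(self, warm_up_meta):
        msd = msd_axis(ballistic_up(50), warm_up_meta, window_rule="full")
        assert len(msd.msd) == 49

    def test_lattice_walk_msd_is_linear_in_lag(self, warm_up_meta):
        """1-D +-step random walk: time-averaged MSD(tau) tracks 2 D tau
        (D = step^2 / (2 dt)) within 10% at short lags, averaged over 100
        seeds."""
        step = 0.1
        acc = np.zeros(10)
        for seed in range(100):
            rng = np.random.default_rng(seed)
            y = np.concatenate([[0], np.cumsum(rng.choice([-step, step], 400))])
            traj = Trajectory(frame=np.arange(401), x=np.zeros(401), y=y)
            msd = msd_axis(traj, warm_up_meta, "parallel", window_rule="full")
            acc += msd.msd[:10]
        acc /= 100
        lags = np.arange(1, 11)
        np.testing.assert_allclose(acc, step**2 * lags, rtol=0.10)

    def test_time_reversal_invariance(self, warm_up_meta):
        traj, _ = make_walk("biased_crw", n_frames=300, seed=8, drift_bias=0.4)
        rev = Trajectory(frame=traj.frame, x=traj.x[::-1], y=traj.y[::-1])
        a = msd_axis(traj, warm_up_meta, "parallel", window_rule="full")
        b = msd_axis(rev, warm_up_meta, "parallel", window_rule="full")
        np.testing.assert_allclose(a.msd, b.msd, atol=1e-12)

    def test_msd_nonnegative(self, warm_up_meta):
        traj, _ = make_walk("diffusive", n_frames=250, seed=3)
        msd = msd_axis(traj, warm_up_meta, "parallel")
        assert np.all(msd.msd >= 0)


class TestLoglogSlope:
    def test_ballistic_slope_is_two(self, warm_up_meta):
        msd = msd_axis(ballistic_up(), warm_up_meta, "parallel")
        fit = loglog_slope(msd)
        assert fit["alpha"] == pytest.approx(2.0, abs=1e-3)
        assert fit.r2 == pytest.approx(1.0, abs=1e-9)

    def test_diffusive_slope_is_one(self, warm_up_meta):
        vals = []
        for seed in range(100):
            traj, _ = make_walk("diffusive", n_frames=211, seed=seed)
            msd = msd_axis(traj, warm_up_meta, "parallel")
            vals.append(loglog_slope(msd)["alpha"])
        assert np.mean(vals) == pytest.approx(1.0, abs=0.15)

    def test_flat_msd_has_zero_slope(self):
        msd = MSDCurve(lag_frames=np.arange(1, 21),
                       lag_min=0.5 * np.arange(1, 21),
                       msd=np.full(20, 3.0))
        assert loglog_slope(msd)["alpha"] == pytest.approx(0.0, abs=1e-12)

    def test_too_few_positive_points_rejected(self):
        msd = MSDCurve(lag_frames=np.arange(1, 5), lag_min=0.5 * np.arange(1, 5),
                       msd=np.array([0.0, 0.0, 1.0, 2.0]))
        with pytest.raises(ValueError):
            loglog_slope(msd)


class TestPathMetrics:
    def test_straight_warm_path(self, warm_up_meta):
        pm = path_metrics(ballistic_up(), warm_up_meta)
        assert pm.straightness == pytest.approx(1.0)
        assert pm.directionality == pytest.approx(1.0)
        assert pm.positive_thermotaxis and pm.effective_thermotaxis

    def test_anti_warm_path(self, warm_up_meta):
        traj = Trajectory(frame=np.arange(10), x=np.zeros(10),
                          y=-0.5 * np.arange(10))
        pm = path_metrics(traj, warm_up_meta)
        assert pm.directionality == pytest.approx(-1.0)
        assert not pm.positive_thermotaxis

    def test_right_angle_path(self, warm_up_meta):
        traj = Trajectory(frame=np.arange(3), x=np.array([0.0, 1.0, 1.0]),
                          y=np.array([0.0, 0.0, 1.0]))
        pm = path_metrics(traj, warm_up_meta)
        assert pm.straightness == pytest.approx(np.sqrt(2) / 2)
        assert pm.directionality == pytest.approx(0.5)  # D cos(45deg) / 2

    def test_threshold_semantics(self, warm_up_meta):
        """directionality in (0, 0.1] is positive but not effective."""
        # path with directionality 0.05: up 0.05 of the total length
        y = np.array([0.0, 1.0, 0.0, 1.0, 0.0, 0.05])
        x = np.zeros(6)
        traj = Trajectory(frame=np.arange(6), x=x, y=y)
        pm = path_metrics(traj, warm_up_meta)
        assert pm.directionality == pytest.approx(0.05 / 4.05)
        assert pm.positive_thermotaxis and not pm.effective_thermotaxis

    def test_stationary_path_is_undefined(self, warm_up_meta):
        traj = Trajectory(frame=np.arange(5), x=np.zeros(5), y=np.zeros(5))
        pm = path_metrics(traj, warm_up_meta)
        assert not pm.defined

    def test_directionality_bounded_by_straightness(self, warm_up_meta):
        for seed in range(10):
            traj, _ = make_walk("biased_crw", n_frames=300, seed=seed,
                                drift_bias=0.2)
            pm = path_metrics(traj, warm_up_meta)
            assert -1.0 <= pm.directionality <= pm.straightness <= 1.0


class TestPersistenceLength:
    def test_straight_path_diverges_to_bound(self, warm_up_meta):
        traj = ballistic_up(400, step=0.1)
        table, L_at_max, fit = persistence_length_scan(traj, L_max_mm=10.0)
        assert not fit.converged
        assert np.all(table["Lp_mm"] >= 100.0 * table["L_mm"])

    def test_wlc_walk_recovers_target_lp(self):
        """Persistence scan on a worm-like-chain walk recovers the target
        within 20% at Lp = 2 mm."""
        traj, _ = make_walk("wlc", n_frames=10_000, seed=1, Lp_target=2.0,
                            step_rate=10.0)
        table, L_at_max, fit = persistence_length_scan(
            traj, L_max_mm=20.0, L_step_mm=1.0)
        assert fit["Lp"] == pytest.approx(2.0, rel=0.20)

    def test_scan_upper_bound_is_respected(self, warm_up_meta):
        traj, _ = make_walk("wlc", n_frames=3000, seed=2, Lp_target=2.0)
        table, _, _ = persistence_length_scan(traj, L_max_mm=20.0)
        assert table["L_mm"].max() <= 20.0

    def test_fit_residual_locally_optimal(self):
        """The WLC residual at the fitted Lp is no worse than at 0.5x / 2x."""
        traj, _ = make_walk("wlc", n_frames=5000, seed=3, Lp_target=2.0)
        table, L_at_max, fit = persistence_length_scan(traj)
        row = table.loc[table["L_mm"] == L_at_max].iloc[0]
        L, r2bar, lp = row["L_mm"], row["mean_r2_mm2"], fit["Lp"]
        res = lambda q: (wlc_mean_square_displacement(L, q) - r2bar) ** 2
        assert res(lp) <= res(0.5 * lp) + 1e-12
        assert res(lp) <= res(2.0 * lp) + 1e-12


class TestRmsdFits:
    def test_taylor_self_consistency(self):
        """(v, tau) recovered within 5% from a curve generated by the model
        with mild noise."""
        t = 0.5 * np.arange(1, 200)
        rng = np.random.default_rng(0)
        y = taylor_rmsd(t, 0.2, 5.0) * (1 + 0.01 * rng.standard_normal(len(t)))
        fit = fit_rmsd_taylor(t, y)
        assert fit["v"] == pytest.approx(0.2, rel=0.05)
        assert fit["tau"] == pytest.approx(5.0, rel=0.05)

    def test_short_time_limit_is_ballistic(self):
        t = np.array([1e-4, 2e-4, 5e-4])
        np.testing.assert_allclose(taylor_rmsd(t, 0.3, 5.0), 0.3 * t, rtol=1e-3)

    def test_long_time_limit_is_diffusive(self):
        v, tau = 0.3, 2.0
        t = np.array([1e5, 2e5])
        np.testing.assert_allclose(taylor_rmsd(t, v, tau) ** 2 / t,
                                   2 * v**2 * tau, rtol=1e-4)

    def test_ballistic_exact_line(self):
        t = np.linspace(0.5, 50, 100)
        fit = fit_rmsd_ballistic(t, 0.3 * t)
        assert fit["v"] == pytest.approx(0.3, abs=1e-12)
        assert fit.r2 == pytest.approx(1.0)

    def test_all_zero_rmsd_gives_zero_speed(self):
        t = np.linspace(0.5, 10, 20)
        fit = fit_rmsd_ballistic(t, np.zeros(20))
        assert fit["v"] == 0.0

    def test_diffusive_curve_prefers_crossover_model(self, warm_up_meta):
        """On sqrt-t RMSD data the crossover fit beats the pure line."""
        traj, _ = make_walk("diffusive", n_frames=400, seed=5)
        msd = msd_axis(traj, warm_up_meta, "parallel")
        tay = fit_rmsd_taylor(msd.lag_min, msd.rmsd())
        bal = fit_rmsd_ballistic(msd.lag_min, msd.rmsd())
        assert tay.r2 > bal.r2


class TestStepLengthFits:
    def test_exponential_rate_recovery_and_model_choice(self):
        rng = np.random.default_rng(7)
        d = rng.exponential(1 / 5.0, 10_000)  # lambda = 5 / mm
        fits, best = step_length_fits(d)
        by = {f.model: f for f in fits}
        assert best == "exponential"
        assert by["exponential"]["lambda"] == pytest.approx(5.0, rel=0.05)
        assert by["exponential"].r2 > by["levy"].r2
        assert by["exponential"].r2 > by["powerlaw"].r2

    def test_levy_density_vanishes_at_location(self):
        x = np.array([1.0 + 1e-9, 1.0 + 1e-6])
        assert np.all(levy_pdf(x, c=1.0, mu=1.0) < 1e-100)
        assert levy_pdf(np.array([0.5]), 1.0, 1.0)[0] == 0.0

    def test_forty_bins_default(self):
        rng = np.random.default_rng(1)
        d = rng.exponential(0.2, 2000)
        fits, _ = step_length_fits(d)
        # density histogram over 40 bins integrates to 1
        heights, edges = np.histogram(d, bins=40, density=True)
        assert np.sum(heights * np.diff(edges)) == pytest.approx(1.0)
        assert all(f.domain == (edges[0], edges[-1]) for f in fits
                   if f.converged)

    def test_degenerate_sample_rejected(self):
        with pytest.raises(ValueError):
            step_length_fits(np.full(500, 0.3))

    def test_model_comparison_recovers_generator(self):
        """Exponential vs power-law generators are correctly ranked by the
        histogram r2 comparison in >= 95% of 100 seeded runs."""
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            d = rng.exponential(0.2, 10_000)
            _, best = step_length_fits(d)
            hits += best == "exponential"
        assert hits >= 95
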