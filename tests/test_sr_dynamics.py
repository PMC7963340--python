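"""SR stochastic process: trajectories, first passage, calibration."""

import numpy as np
import pytest

from srinc.sr_dynamics import (
    SRParameters,
    calibrate_sr_parameters,
    empirical_hazard,
    first_crossing_ages,
    first_passage_times,
    simulate_trajectory,
)
from srinc.incidence_model import DiseaseModel, hazard_params_from_threshold
from srinc.cohort import _invert_survival  # inverse-CDF oracle helper


class TestTrajectory:
    def test_no_production_no_noise_stays_at_zero(self):
        p = SRParameters(eta=0.0, beta=1.0, kappa=1.0, epsilon=0.0)
        traj = simulate_trajectory(p, horizon=50.0, dt=0.1, seed=0)
        assert np.all(traj.values == 0.0)

    def test_deterministic_limit_is_parabola(self):
        """With removal negligible (kappa huge) and no noise, X(t) = eta t^2/2."""
        p = SRParameters(eta=0.01, beta=1e-9, kappa=1e9, epsilon=0.0)
        traj = simulate_trajectory(p, horizon=60.0, dt=0.001, seed=0)
        expected = 0.5 * p.eta * traj.times**2
        np.testing.assert_allclose(traj.values, expected, atol=5e-4)

    def test_seed_reproducibility_bit_identical(self, sr_params):
        a = simulate_trajectory(sr_params, horizon=30.0, dt=0.02, seed=7)
        b = simulate_trajectory(sr_params, horizon=30.0, dt=0.02, seed=7)
        np.testing.assert_array_equal(a.values, b.values)
        c = simulate_trajectory(sr_params, horizon=30.0, dt=0.02, seed=8)
        assert not np.array_equal(a.values, c.values)

    def test_values_remain_non_negative(self, sr_params):
        traj = simulate_trajectory(sr_params, horizon=50.0, dt=0.02, seed=1)
        assert np.all(traj.values >= 0.0)

    def test_invalid_grid_rejected(self, sr_params):
        with pytest.raises(ValueError):
            simulate_trajectory(sr_params, horizon=-1.0, dt=0.01, seed=0)
        with pytest.raises(ValueError):
            simulate_trajectory(sr_params, horizon=10.0, dt=0.0, seed=0)

    def test_mean_trajectory_converges_with_step_refinement(self, sr_params):
        """Sample-mean X at selected ages agrees between dt and dt/10
        within combined Monte-Carlo error."""
        ages = np.array([20.0, 35.0, 50.0])
        n = 2000
        means, sems = [], []
        for dt in (0.01, 0.001):
            rng = np.random.default_rng(123)
            steps = int(round(50.0 / dt))
            x = np.zeros(n)
            sq = np.sqrt(2 * sr_params.epsilon * dt)
            rec = {int(round(a / dt)): a for a in ages}
            got = {}
            for k in range(1, steps + 1):
                t = (k - 1) * dt
                x += (sr_params.eta * t - sr_params.beta * x / (sr_params.kappa + x)) * dt
                x += sq * rng.standard_normal(n)
                np.maximum(x, 0.0, out=x)
                if k in rec:
                    got[rec[k]] = (x.mean(), x.std(ddof=1) / np.sqrt(n))
            means.append(np.array([got[a][0] for a in ages]))
            sems.append(np.array([got[a][1] for a in ages]))
        diff = np.abs(means[0] - means[1])
        tol = 4.0 * np.hypot(sems[0], sems[1])
        assert np.all(diff < tol)


class TestFirstPassage:
    def test_threshold_at_start_crosses_immediately(self, sr_params):
        sample = first_passage_times(sr_params, threshold=0.0, n=50, dt=0.1,
                                     horizon=10.0, seed=0)
        assert np.all(sample.ages == 0.0)

    def test_negative_threshold_rejected(self, sr_params):
        with pytest.raises(ValueError):
            first_passage_times(sr_params, threshold=-1.0, n=10)

    def test_crossing_ages_monotone_in_threshold_on_shared_paths(self, sr_params):
        rng = np.random.default_rng(5)
        ages = first_crossing_ages(
            sr_params, np.array([10.0, 14.0, 17.0]), 300, 0.02, 110.0, rng
        )
        filled = np.nan_to_num(ages, nan=np.inf)
        assert np.all(filled[0] <= filled[1])
        assert np.all(filled[1] <= filled[2])

    def test_crossing_fraction_monotone_in_horizon(self, sr_params):
        fracs = []
        for horizon in (70.0, 90.0, 110.0):
            s = first_passage_times(sr_params, 17.0, n=400, dt=0.02,
                                    horizon=horizon, seed=3)
            fracs.append(s.n_crossed / s.n)
        assert 0.0 < fracs[0] <= fracs[1] <= fracs[2] <= 1.0

    def test_death_hazard_slope_near_printed_value(self, sr_params):
        """The simulated death-crossing hazard rises exponentially through
        mid-life with slope close to ad = 0.132/yr."""
        s = first_passage_times(sr_params, 17.0, n=20_000, dt=0.01,
                                horizon=110.0, seed=9)
        edges = np.arange(30.0, 70.1, 5.0)
        mid = 0.5 * (edges[:-1] + edges[1:])
        alive = np.nan_to_num(s.ages, nan=np.inf)
        haz = np.array([
            np.sum((s.ages >= lo) & (s.ages < hi)) / (np.sum(alive >= lo) * (hi - lo))
            for lo, hi in zip(edges[:-1], edges[1:])
        ])
        slope = np.polyfit(mid, np.log(haz), 1)[0]
        assert slope == pytest.approx(0.132, rel=0.15)

    def test_log_hazard_slope_increases_with_threshold(self, sr_params):
        """alpha ~ eta*Xc/epsilon: steeper exponential rise for higher
        thresholds."""
        rng = np.random.default_rng(17)
        thr = np.array([12.0, 14.0, 17.0])
        ages = first_crossing_ages(sr_params, thr, 20_000, 0.02, 110.0, rng)
        slopes = []
        for row in ages:
            edges = np.arange(40.0, 80.1, 5.0)
            mid = 0.5 * (edges[:-1] + edges[1:])
            alive = np.nan_to_num(row, nan=np.inf)
            haz = np.array([
                np.sum((row >= lo) & (row < hi)) / (np.sum(alive >= lo) * (hi - lo))
                for lo, hi in zip(edges[:-1], edges[1:])
            ])
            slopes.append(np.polyfit(mid, np.log(np.maximum(haz, 1e-9)), 1)[0])
        assert slopes[0] < slopes[1] < slopes[2]


class TestEmpiricalHazard:
    def test_person_year_accounting_identity(self, sr_params):
        s = first_passage_times(sr_params, 14.0, n=500, dt=0.02, horizon=110.0, seed=2)
        curve = empirical_hazard(s, bin_width=5.0)
        assert np.nansum(curve.cases) == s.n_crossed
        finite = np.isfinite(curve.incidence)
        np.testing.assert_allclose(
            curve.incidence[finite] * curve.person_years[finite],
            curve.cases[finite],
            rtol=1e-9,
        )

    def test_all_crossing_in_first_bin(self):
        from srinc.sr_dynamics import FirstPassageSample

        s = FirstPassageSample(threshold=1.0, ages=np.full(10, 0.5), horizon=10.0, seed=0)
        curve = empirical_hazard(s, bin_width=1.0)
        assert curve.cases[0] == 10
        assert np.all(curve.person_years[1:] == 0)
        assert np.all(~np.isfinite(curve.incidence[1:]))

    def test_recovers_analytic_hazard_from_inverse_cdf_sample(self, constants):
        """Oracle: sample crossing ages by inverting the closed-form
        survival, then check the recovered hazard against h(t)."""
        hp = hazard_params_from_threshold(14.0, constants)
        rng = np.random.default_rng(11)
        n = 200_000
        u = rng.random(n)
        ages = _invert_survival(hp.A, hp.b, hp.a, -np.log(u))
        from srinc.sr_dynamics import FirstPassageSample
        from srinc.incidence_model import hazard

        horizon = 110.0
        ages = np.where(ages <= horizon, ages, np.nan)
        sample = FirstPassageSample(threshold=14.0, ages=ages, horizon=horizon, seed=11)
        curve = empirical_hazard(sample, bin_width=2.0)
        sel = np.isfinite(curve.incidence) & (curve.cases >= 50)
        expected = np.asarray(hazard(curve.ages[sel], hp))
        se = np.sqrt(expected / curve.person_years[sel])
        assert np.all(np.abs(curve.incidence[sel] - expected) < 4 * se)

    def test_empty_sample_rejected(self):
        from srinc.sr_dynamics import FirstPassageSample

        s = FirstPassageSample(threshold=1.0, ages=np.array([]), horizon=10.0, seed=0)
        with pytest.raises(ValueError):
            empirical_hazard(s)


class TestCalibration:
    def test_single_threshold_rejected(self, constants):
        with pytest.raises(ValueError):
            calibrate_sr_parameters(constants, thresholds=[14.0], n=10, seed=0)

    def test_recovers_noise_to_production_ratio(self, constants, sr_params):
        """Self-consistency: calibrating against first-passage CDFs
        generated by a known parameter set recovers eta/epsilon within
        +-20% relative."""
        truth = sr_params
        thr = np.array([12.0, 13.0, 14.0, 15.0, 16.0, 17.0])
        ages_grid = np.arange(20.0, 111.0, 2.0)
        rng = np.random.default_rng(100)
        ages = first_crossing_ages(truth, thr, 4000, 0.05, 110.0, rng)
        target = np.stack([
            np.mean(np.nan_to_num(a, nan=np.inf)[:, None] <= ages_grid[None, :], axis=0)
            for a in ages
        ])
        start = SRParameters(
            eta=truth.eta * 1.6, beta=truth.beta * 0.7,
            kappa=truth.kappa * 2.0, epsilon=truth.epsilon * 0.6,
        )
        result = calibrate_sr_parameters(
            constants, thresholds=thr, n=800, seed=100, dt=0.05,
            initial=start, target_cdfs=target, maxiter=400, anchor_weight=0.0,
        )
        ratio_true = truth.eta / truth.epsilon
        ratio_fit = result.params.eta / result.params.epsilon
        assert ratio_fit == pytest.approx(ratio_true, rel=0.2)

    def test_determinism(self, constants):
        kw = dict(thresholds=[12.0, 14.0, 17.0], n=100, seed=5, dt=0.1, maxiter=5)
        a = calibrate_sr_parameters(constants, **kw)
        b = calibrate_sr_parameters(constants, **kw)
        assert a.params == b.params
        assert a.loss == b.loss
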