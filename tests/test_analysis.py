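"""MSD estimation, diffusivity fits, tortuosity and quote-wise statistics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mcfrw.analysis import (confidence_interval, diffusion_coefficient,
                            extract_subtrajectory, fit_msd, msd_time_average,
                            order_of_magnitude, quote_sweep, tortuosity)
from mcfrw.errors import ParameterError, UndefinedTortuosityError
from mcfrw.fixtures import ballistic_trajectory, oracle_msd
from mcfrw.walker import Trajectory


def _traj(positions, delta_t=1.0):
    return Trajectory(positions=np.asarray(positions, dtype=float),
                      delta_t=delta_t, seed=0)


class TestMSD:
    def test_constant_trajectory_is_zero(self):
        tr = _traj(np.tile([3.0, -2.0, 7.0], (20, 1)))
        curve = msd_time_average(tr)
        assert np.allclose(curve.values, 0.0, atol=1e-9)

    def test_collinear_example(self):
        tr = _traj([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]])
        curve = msd_time_average(tr, lags=[2])
        # pairs (0->2) and (1->3), both displacements of 2
        assert curve.values[0] == pytest.approx(4.0, rel=1e-12)

    def test_matches_double_loop_oracle_on_random_walks(self, rng):
        pos = rng.normal(0.0, 1.0, (50, 3)).cumsum(axis=0) + 500.0
        tr = _traj(pos)
        curve = msd_time_average(tr)
        for lag, value in zip(curve.lags, curve.values):
            ref = oracle_msd(tr, int(lag))
            assert value == pytest.approx(ref, rel=1e-9)

    def test_invalid_lags(self):
        tr = _traj(np.zeros((5, 3)))
        with pytest.raises(ParameterError):
            msd_time_average(tr, lags=[5])
        with pytest.raises(ParameterError):
            msd_time_average(_traj(np.zeros((1, 3))))

    @given(st.integers(min_value=5, max_value=40),
           st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=25, deadline=None)
    def test_oracle_equivalence_property(self, n, seed):
        pos = np.random.default_rng(seed).normal(0, 2.0, (n, 3)).cumsum(
            axis=0)
        tr = _traj(pos)
        curve = msd_time_average(tr)
        lag = int(curve.lags[len(curve.lags) // 2])
        assert curve.values[curve.lags == lag][0] == pytest.approx(
            oracle_msd(tr, lag), rel=1e-9, abs=1e-12)


class TestFitMSD:
    def test_exact_line_recovered(self):
        lags = np.arange(1, 11)
        curve_values = 5.0 + 3.0 * lags * 1.0
        from mcfrw.analysis import MSDCurve
        curve = MSDCurve(lags=lags, values=curve_values, delta_t=1.0)
        fit = fit_msd(curve, window=(1, 10))
        assert fit.beta0 == pytest.approx(5.0, abs=1e-9)
        assert fit.beta1 == pytest.approx(3.0, abs=1e-9)
        assert fit.r_squared == pytest.approx(1.0)

    def test_free_walk_recovers_slope_6_D(self, rng):
        """Einstein relation: mean slope/6 approximates the input diffusivity.

        A single time-averaged MSD fit scatters by tens of percent, so the
        check averages an ensemble of independent walks.
        """
        D = 2.0  # nm^2 per time unit
        n = 3000
        slopes = []
        for _ in range(16):
            steps = rng.normal(0.0, math.sqrt(2 * D), (n, 3))
            pos = np.vstack([np.zeros(3), steps.cumsum(axis=0)])
            slopes.append(fit_msd(msd_time_average(_traj(pos))).beta1)
        assert np.mean(slopes) / 6.0 == pytest.approx(D, rel=0.15)

    def test_degenerate_window_is_an_error(self):
        from mcfrw.analysis import MSDCurve
        curve = MSDCurve(lags=np.arange(1, 5), values=np.ones(4),
                         delta_t=1.0)
        with pytest.raises(ParameterError):
            fit_msd(curve, window=(2, 2))


class TestDiffusionCoefficient:
    def test_unit_conversion(self):
        from mcfrw.analysis import LinearFit
        fit = LinearFit(beta0=0.0, beta1=6.0, fit_lag_window=(1, 2),
                        r_squared=1.0)
        assert diffusion_coefficient(fit) == pytest.approx(1e-18)

    def test_zero_slope(self):
        from mcfrw.analysis import LinearFit
        fit = LinearFit(beta0=1.0, beta1=0.0, fit_lag_window=(1, 2),
                        r_squared=0.0)
        assert diffusion_coefficient(fit) == 0.0


class TestTortuosity:
    def test_straight_path_is_one(self):
        tr = _traj([[0, 0, 0], [0, 0, 1], [0, 0, 2]])
        assert tortuosity(tr) == pytest.approx(1.0)

    def test_right_angle_path(self):
        tr = _traj([[0, 0, 0], [1, 0, 0], [1, 1, 0]])
        assert tortuosity(tr) == pytest.approx(2.0 / math.sqrt(2.0),
                                               rel=1e-12)

    def test_coincident_endpoints_are_an_error(self):
        tr = _traj([[0, 0, 0], [1, 0, 0], [0, 0, 0]])
        with pytest.raises(UndefinedTortuosityError):
            tortuosity(tr)

    @given(st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=30, deadline=None)
    def test_always_at_least_one(self, seed):
        pos = np.random.default_rng(seed).normal(0, 1, (30, 3)).cumsum(
            axis=0)
        tr = _traj(pos)
        try:
            assert tortuosity(tr) >= 1.0 - 1e-12
            assert tortuosity(tr, resolution=2.5) >= 1.0 - 1e-12
        except UndefinedTortuosityError:
            pass

    def test_coarse_graining_reduces_brownian_path_length(self, rng):
        pos = rng.normal(0, 1, (5000, 3)).cumsum(axis=0)
        tr = _traj(pos)
        try:
            fine = tortuosity(tr)
            coarse = tortuosity(tr, resolution=10.0)
        except UndefinedTortuosityError:
            pytest.skip("degenerate chord")
        assert coarse < fine


class TestExtractSubtrajectory:
    def test_first_passage_prefix(self):
        L = [0.0, 50.0, 140.0, 100.0, 200.0]
        pos = np.column_stack([np.zeros(5), np.zeros(5), L])
        sub = extract_subtrajectory(_traj(pos), 134.0)
        assert len(sub) == 3
        assert sub.positions[-1, 2] == 140.0

    def test_unreached_quote_returns_none(self):
        pos = np.column_stack([np.zeros(4), np.zeros(4),
                               [0.0, 10.0, 20.0, 30.0]])
        assert extract_subtrajectory(_traj(pos), 134.0) is None

    def test_quote_at_the_end_returns_the_full_trajectory(self):
        pos = np.column_stack([np.zeros(4), np.zeros(4),
                               [0.0, 40.0, 80.0, 120.0]])
        sub = extract_subtrajectory(_traj(pos), 120.0)
        assert len(sub) == 4


class TestConfidenceInterval:
    def test_identical_values_zero_width(self):
        lo, hi = confidence_interval([4.2, 4.2, 4.2])
        assert lo == hi == pytest.approx(4.2)

    def test_three_values_against_t_table(self):
        lo, hi = confidence_interval([1.0, 2.0, 3.0], level=0.95)
        half = 4.302652729911275 * 1.0 / math.sqrt(3.0)
        assert lo == pytest.approx(2.0 - half, rel=1e-6)
        assert hi == pytest.approx(2.0 + half, rel=1e-6)

    def test_midpoint_is_the_mean(self, rng):
        v = rng.normal(3.0, 1.0, 17)
        lo, hi = confidence_interval(v)
        assert (lo + hi) / 2.0 == pytest.approx(v.mean())

    def test_too_few_values(self):
        with pytest.raises(ParameterError):
            confidence_interval([1.0])

    def test_coverage_near_nominal(self):
        """95% CIs contain the true mean in ~95% of replicates."""
        rng = np.random.default_rng(42)
        hits = 0
        n_rep = 500
        for _ in range(n_rep):
            sample = rng.normal(10.0, 2.0, 15)
            lo, hi = confidence_interval(sample, 0.95)
            hits += lo <= 10.0 <= hi
        assert abs(hits / n_rep - 0.95) <= 0.03


class TestOrderOfMagnitude:
    @pytest.mark.parametrize("x,expected", [
        (4.12e-10, 1e-10),
        (1.0, 1.0),
        (9.99e-10, 1e-10),
        (0.05, 0.01),
    ])
    def test_values(self, x, expected):
        assert order_of_magnitude(x) == pytest.approx(expected)

    def test_nonpositive_is_an_error(self):
        with pytest.raises(ParameterError):
            order_of_magnitude(0.0)


class TestQuoteSweep:
    def test_simple_means(self):
        # two straight paths with known tortuosity 1 and one zig-zag
        a = _traj(np.column_stack([np.zeros(11), np.zeros(11),
                                   np.linspace(0, 200, 11)]))
        zig = np.column_stack([np.r_[np.zeros(5), np.linspace(0, 300, 6)],
                               np.zeros(11),
                               np.r_[np.linspace(0, 100, 5), 100 + np.linspace(0, 100, 6)]])
        b = _traj(zig)
        reports = quote_sweep([a, b], quotes=[150.0],
                              tortuosity_resolution=None)
        r = reports[0]
        assert r.n_subtrajectories == 2
        ta = tortuosity(extract_subtrajectory(a, 150.0))
        tb = tortuosity(extract_subtrajectory(b, 150.0))
        assert r.mean_tortuosity == pytest.approx((ta + tb) / 2.0)

    def test_equal_values_give_zero_width_ci(self):
        trajs = [_traj(np.column_stack([np.zeros(8), np.zeros(8),
                                        np.linspace(0, 140, 8)]))
                 for _ in range(3)]
        r = quote_sweep(trajs, quotes=[100.0],
                        tortuosity_resolution=None)[0]
        assert r.tortuosity_ci95[0] == pytest.approx(r.tortuosity_ci95[1])

    def test_unreached_quote_is_flagged_not_averaged(self):
        tr = _traj(np.column_stack([np.zeros(5), np.zeros(5),
                                    np.linspace(0, 50, 5)]))
        r = quote_sweep([tr], quotes=[999.0])[0]
        assert r.n_subtrajectories == 0
        assert math.isnan(r.mean_tortuosity)
        assert math.isnan(r.mean_D)
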