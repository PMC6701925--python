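"""Track statistics: velocity profiles, OU fitting, partitioning measures."""

import math
import warnings

import numpy as np
import pytest

from oriseg.params import InvalidParameterError
from oriseg.synthetic_data import OUTrackSpec, gen_colocalised_pair
from oriseg.trajectory_analysis import (OUFit, Track, crossing_count,
                                        detect_foci, fit_ou,
                                        independence_null, mad_correlation,
                                        partitioning_accuracy,
                                        restoring_force, segregation_velocity,
                                        separation_cdf,
                                        stepwise_velocity_profile)


class TestVelocityProfile:
    def test_constant_track_zero_velocity(self):
        t = np.arange(100) * 60.0
        tr = Track(t, np.full(100, 1.3), np.full(100, 2.5))
        prof = stepwise_velocity_profile([tr], min_count=10)
        np.testing.assert_allclose(prof.mean_v, 0.0)
        np.testing.assert_allclose(prof.var_v, 0.0)

    def test_ou_slope_matches_closed_form(self, ou_track_ensemble):
        spec, tracks = ou_track_ensemble
        prof = stepwise_velocity_profile(tracks)
        fit = fit_ou(prof)
        expected = (math.exp(-spec.delta_t / spec.tau) - 1.0) / spec.delta_t
        assert abs(fit.slope - expected) < 2.5 * fit.slope_se
        assert expected == pytest.approx(-9.71e-4, abs=1e-6)

    def test_ou_variance_flat_across_central_bins(self, ou_track_ensemble):
        _, tracks = ou_track_ensemble
        prof = stepwise_velocity_profile(tracks)
        sel = np.abs(prof.bin_centres) <= 0.3
        v = prof.var_v[sel]
        # each bin variance within its own 4-sigma band of the pooled value
        pooled = np.average(v, weights=prof.counts[sel])
        assert np.all(np.abs(v - pooled) < 4 * prof.se_var[sel])

    def test_focus_reference(self):
        t = np.arange(50) * 60.0
        rng = np.random.default_rng(0)
        x = 1.25 + 0.05 * rng.standard_normal(50)
        tr = Track(t, x, np.full(50, 2.5))
        ref = Track(t, x, np.full(50, 2.5))  # perfectly colocalised focus
        prof = stepwise_velocity_profile([tr], reference=[ref], min_count=5)
        assert np.all(np.abs(prof.bin_centres) < 0.1)


class TestOUFit:
    def test_parameter_recovery(self, ou_track_ensemble):
        spec, tracks = ou_track_ensemble
        fit = fit_ou(stepwise_velocity_profile(tracks))
        assert fit.valid
        assert abs(fit.D_a / spec.D_a - 1.0) < 0.10
        assert abs(fit.d_a * spec.tau - 1.0) < 0.20

    def test_brownian_limit_estimator(self):
        # as dt/tau -> 0 the variance-based estimator approaches var*dt/2
        prof_var = 2.0e-5
        dt = 60.0
        fit = OUFit(D_a=0, d_a=1e-9, tau=1e9, f_over_kT=0, D_a_ci=(0, 0),
                    d_a_ci=(0, 0), slope=0, slope_se=1, intercept=0)
        tau = 1e9
        D_full = prof_var * dt ** 2 / (tau * (1 - math.exp(-2 * dt / tau)))
        assert D_full == pytest.approx(prof_var * dt / 2.0, rel=1e-6)

    def test_pure_brownian_slope_ci_covers_zero(self):
        rng = np.random.default_rng(8)
        dt = 60.0
        D = 5e-5
        tracks = []
        for _ in range(60):
            steps = rng.normal(0, math.sqrt(2 * D * dt), 200)
            x = 12.5 + np.concatenate([[0.0], np.cumsum(steps)])
            tracks.append(Track(np.arange(201) * dt, x, np.full(201, 25.0)))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            prof = stepwise_velocity_profile(tracks)
        fit = fit_ou(prof, central=1.0)
        assert fit.slope - 1.96 * fit.slope_se < 0 < fit.slope + 1.96 * fit.slope_se

    def test_positive_slope_flagged_invalid(self):
        # construct a profile with an outward (destabilising) drift
        from oriseg.trajectory_analysis import VelocityProfile
        x = np.linspace(-0.3, 0.3, 7)
        vp = VelocityProfile(x, 1e-3 * x, np.full(7, 1e-6),
                             np.full(7, 1e-8), np.full(7, 1e-8),
                             np.full(7, 100), 60.0)
        fit = fit_ou(vp)
        assert not fit.valid and math.isnan(fit.d_a)


class TestRestoringForce:
    def test_zero_at_home(self):
        fit = OUFit(1.0, 23.9, 1 / 23.9, 23.9, (0, 0), (0, 0), -1, 0.1, 0)
        assert restoring_force(fit, 0.0) == 0.0

    def test_printed_value(self):
        fit = OUFit(1.0, 23.9, 1 / 23.9, 23.9, (0, 0), (0, 0), -1, 0.1, 0)
        assert restoring_force(fit, 0.2) == pytest.approx(0.0200, abs=3e-4)

    def test_linearity(self):
        fit = OUFit(1.0, 10.0, 0.1, 10.0, (0, 0), (0, 0), -1, 0.1, 0)
        assert restoring_force(fit, 0.4) == pytest.approx(
            2 * restoring_force(fit, 0.2))

    def test_invalid_fit_raises(self):
        fit = OUFit(1.0, float("nan"), math.inf, 0.0, (0, 0), (0, 0), 1, 0.1,
                    0, valid=False)
        with pytest.raises(InvalidParameterError):
            restoring_force(fit, 0.1)


class TestDetectFoci:
    def test_single_compartment_mass(self):
        v = np.zeros(25)
        v[7] = 42
        pos, n = detect_foci(v, 1)
        assert n == 1 and pos[0] == pytest.approx(0.75)

    def test_gaussian_field_centroid(self):
        x = (np.arange(25) + 0.5) * 0.1
        v = 100 * np.exp(-0.5 * ((x - 1.3) / 0.2) ** 2)
        pos, _ = detect_foci(v, 1)
        assert abs(pos[0] - 1.3) < 0.05

    def test_symmetric_two_peaks(self):
        x = (np.arange(50) + 0.5) * 0.1
        v = (np.exp(-0.5 * ((x - 1.25) / 0.2) ** 2)
             + np.exp(-0.5 * ((x - 3.75) / 0.2) ** 2)) * 50
        pos, n = detect_foci(v, 2)
        assert n == 2
        assert pos[0] + pos[1] == pytest.approx(5.0, abs=1e-6)

    def test_fewer_peaks_than_requested_flagged(self):
        x = (np.arange(25) + 0.5) * 0.1
        v = 100 * np.exp(-0.5 * ((x - 1.25) / 0.2) ** 2)
        pos, n = detect_foci(v, 2)
        assert n == 1 and len(pos) == 1

    def test_empty_profile_rejected(self):
        with pytest.raises(InvalidParameterError):
            detect_foci(np.zeros(10), 1)


class TestPartitioningAndCrossings:
    def test_opposite_quarters(self):
        L = np.full(10, 4.0)
        assert partitioning_accuracy(np.full(10, 1.0), np.full(10, 3.0),
                                     L) == 1.0

    def test_same_quarter(self):
        L = np.full(10, 4.0)
        assert partitioning_accuracy(np.full(10, 1.0), np.full(10, 1.2),
                                     L) == 0.0

    def test_tie_excluded_with_warning(self):
        L = np.full(3, 4.0)
        with pytest.warns(UserWarning):
            acc = partitioning_accuracy(np.array([1.0, 2.0, 1.0]),
                                        np.array([3.0, 3.0, 1.5]), L)
        assert acc == 0.5

    def test_parallel_tracks_no_crossing(self):
        assert crossing_count(np.ones(10), np.zeros(10)) == 0

    def test_single_exchange(self):
        assert crossing_count(np.array([1, 1, 0, 0.]),
                              np.array([0, 0, 1, 1.])) == 1

    def test_zero_attributed_to_following_step(self):
        # touch and return: no crossing; touch and pass: one crossing
        assert crossing_count(np.array([1., 0.5, 1.]),
                              np.array([0., 0.5, 0.])) == 0
        assert crossing_count(np.array([1., 0.5, 0.]),
                              np.array([0., 0.5, 1.])) == 1

    def test_brownian_pairs_crossings_grow_with_duration(self):
        rng = np.random.default_rng(21)
        short, full = [], []
        for _ in range(60):
            a = np.cumsum(rng.normal(0, 0.1, 400))
            b = np.cumsum(rng.normal(0, 0.1, 400))
            short.append(crossing_count(a[:100], b[:100]))
            full.append(crossing_count(a, b))
        assert np.mean(full) > np.mean(short)


class TestSegregationVelocity:
    def test_non_growing_no_correction(self):
        x1 = np.array([1.0, 1.1, 1.3])
        x2 = np.array([0.5, 0.4, 0.2])
        rates = segregation_velocity(x1, x2, 60.0)
        np.testing.assert_allclose(rates, [0.2 / 60, 0.4 / 60])

    def test_linear_separation_recovered(self):
        t = np.arange(50) * 60.0
        c = 1e-3
        x1 = 1.0 + c * t / 2
        x2 = 1.0 - c * t / 2
        rates = segregation_velocity(x1, x2, 60.0)
        np.testing.assert_allclose(rates, c, rtol=1e-9)

    def test_comoving_with_growth_corrected_to_zero(self):
        T = 120 * 60.0
        t = np.arange(60) * 60.0
        L = 2.5 * np.exp2(t / T)
        x1, x2 = 0.25 * L, 0.75 * L
        rates = segregation_velocity(x1, x2, 60.0, T_double_s=T)
        # discrete rate vs instantaneous dilation differ at second order in
        # dt/T: residual ~ dilation * (dt ln2 / T)/2 ~ 7e-7, vs the raw
        # dilation term of ~2.4e-4 that the correction removes
        assert np.max(np.abs(rates)) < 1e-6


class TestSeparationAndIndependence:
    def test_identical_tracks_step_cdf(self):
        x = np.random.default_rng(0).random(100)
        sep, cdf = separation_cdf(x, x)
        assert sep.max() == 0.0 and cdf[-1] == 1.0

    def test_independent_uniform_triangular_cdf(self):
        rng = np.random.default_rng(4)
        L = 2.0
        a, b = rng.uniform(0, L, 20000), rng.uniform(0, L, 20000)
        sep, cdf = separation_cdf(a, b)
        grid = np.linspace(0.05, L - 0.05, 30)
        exact = grid * (2 * L - grid) / L ** 2
        emp = np.searchsorted(sep, grid, side="right") / len(sep)
        assert np.max(np.abs(emp - exact)) < 0.02

    def test_null_point_mass_for_degenerate_marginals(self):
        res = independence_null(np.zeros(200), np.zeros(200), 200,
                                rng=np.random.default_rng(0))
        assert res["null_mean"] == 0.0 and res["observed_mean"] == 0.0

    def test_colocalised_pairs_reject_independence(self):
        spec = OUTrackSpec(D_a=5e-5, tau=1000.0, home=1.25, n_tracks=1,
                           n_steps=500, seed=3)
        a, b = gen_colocalised_pair(spec, coupling=0.02)
        res = independence_null(a.positions, b.positions, 999,
                                rng=np.random.default_rng(1))
        assert res["p_value"] < 0.01
        assert res["observed_mean"] < res["null_mean"]

    def test_shuffled_pairs_show_no_signal(self):
        rng = np.random.default_rng(9)
        ps = []
        for _ in range(40):
            a = rng.normal(1.0, 0.3, 300)
            b = rng.normal(1.0, 0.3, 300)
            ps.append(independence_null(a, b, 199, rng=rng)["p_value"])
        ps = np.array(ps)
        # p-values roughly uniform: mean near 0.5, spread over (0, 1)
        assert 0.3 < ps.mean() < 0.7
        assert (ps < 0.25).any() and (ps > 0.75).any()


class TestMadCorrelation:
    def test_perfect_correlation(self):
        x = np.random.default_rng(0).normal(size=100)
        assert mad_correlation(x, x) == 1.0
        assert mad_correlation(x, -x) == -1.0

    def test_independent_gaussians_near_zero(self):
        rng = np.random.default_rng(2)
        x, y = rng.normal(size=10_000), rng.normal(size=10_000)
        assert abs(mad_correlation(x, y)) < 0.05

    def test_zero_mad_rejected(self):
        with pytest.raises(InvalidParameterError):
            mad_correlation(np.ones(10), np.arange(10.0))
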