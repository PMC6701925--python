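"""Ori-MukBEF coupling: interpolation, jump rates, loading, repulsion,
duplication."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from oriseg import _ssa
from oriseg import model_core as mc
from oriseg.ori_coupling import (OriState, biased_rates, duplicate_ori,
                                 interpolate_v, jump_rates, loading_weights,
                                 repulsion_bias, repulsion_speed,
                                 sample_duplication_length,
                                 sample_duplication_time)
from oriseg.params import (GrowthParams, InvalidParameterError, OriParams,
                           TuringParams)

D_ORI = 5.4e-5
H_S = 0.1 / 21
D_H2 = D_ORI / H_S ** 2  # 2.381 s^-1


class TestInterpolation:
    def test_compartment_centres_are_nodes(self):
        v = np.array([3.0, 7.0, 2.0])
        for i, val in enumerate(v):
            centre = i * 21 + 10
            assert interpolate_v(v, centre, 21) == val

    def test_flat_field_everywhere(self):
        v = np.full(4, 5.0)
        assert all(interpolate_v(v, j, 7) == 5.0 for j in range(28))

    def test_unit_slope_ramp(self):
        # v = (0, 21) with 21 sub-compartments: slope 1 per sub-step
        v = np.array([0.0, 21.0])
        assert interpolate_v(v, 11, 21) == pytest.approx(1.0)
        for k in range(22):
            assert interpolate_v(v, 10 + k, 21) == pytest.approx(float(k))

    def test_constant_extrapolation_beyond_outer_centres(self):
        v = np.array([2.0, 8.0])
        assert interpolate_v(v, 0, 21) == 2.0
        assert interpolate_v(v, 41, 21) == 8.0

    def test_matches_kernel_helper(self):
        v = np.array([1.0, 6.0, 4.0, 9.0])
        for j in range(4 * 21):
            assert interpolate_v(v, j, 21) == pytest.approx(
                _ssa.interp_v(v, j, 4, 21))


class TestJumpRates:
    def test_flat_field_reduces_to_pure_diffusion(self):
        F, B = jump_rates(5.0, 5.0, D_ORI, 0.026, H_S)
        assert F == B == pytest.approx(2.381, abs=1e-3)

    def test_unit_bias_rates(self):
        F, B = biased_rates(1.0, D_ORI, H_S)
        assert F == pytest.approx(3.768, abs=2e-3)
        assert B == pytest.approx(1.386, abs=2e-3)

    def test_extreme_bias_no_overflow(self):
        F, B = biased_rates(800.0, D_ORI, H_S)
        assert np.isfinite(F) and B == 0.0
        F2, B2 = biased_rates(-800.0, D_ORI, H_S)
        assert F2 == 0.0 and np.isfinite(B2)

    @given(st.floats(-50, 50), st.floats(-50, 50))
    def test_detailed_balance_identity(self, v1, v2):
        # the forward rate i -> i+1 equals the backward rate of i+1 -> i
        F_fwd, _ = jump_rates(v1, v2, D_ORI, 0.026, H_S)
        _, B_rev = jump_rates(v2, v1, D_ORI, 0.026, H_S)
        assert F_fwd == pytest.approx(B_rev, rel=1e-12)

    @given(st.floats(-100, 100))
    def test_drift_rate_identity(self, alpha):
        # (F - B)*h_s = D*alpha/h_s exactly (algebraic identity of the scheme)
        F, B = biased_rates(alpha, D_ORI, H_S)
        assert (F - B) * H_S == pytest.approx(D_ORI * alpha / H_S,
                                              rel=1e-9, abs=1e-12)


class TestLoadingWeights:
    def test_uniform_without_preferential_loading(self):
        g = loading_weights(25, {3, 7}, 1.0)
        np.testing.assert_allclose(g, 1.0 / 25)

    def test_six_fold_example(self):
        g = loading_weights(50, {10, 40}, 6.0)
        assert g[10] == pytest.approx(6.0 / 60.0)
        assert g[0] == pytest.approx(1.0 / 60.0)
        assert g.sum() == pytest.approx(1.0)

    @given(st.integers(1, 60), st.floats(1.0, 20.0),
           st.sets(st.integers(0, 59), max_size=4))
    def test_normalisation(self, n, ratio, occ):
        occ = {i for i in occ if i < n}
        g = loading_weights(n, occ, ratio)
        assert g.sum() == pytest.approx(1.0)

    def test_errors(self):
        with pytest.raises(InvalidParameterError):
            loading_weights(0, set(), 1.0)
        with pytest.raises(InvalidParameterError):
            loading_weights(10, set(), 0.5)

    def test_double_occupancy_counts_once(self):
        # matches the kernel: a compartment with two oris is one ori
        # compartment
        g = loading_weights(10, {4}, 6.0)
        buf = np.zeros(10)
        _ssa.compute_loading_weights(buf, 10, np.array([84, 85, 0, 0]),
                                     2, 21, 6.0)
        np.testing.assert_allclose(buf, g)


class TestRepulsion:
    def test_zero_at_contact(self):
        assert repulsion_speed(0.0, 5.0, 0.2) == 0.0
        assert repulsion_bias(0.0, 5.0, 0.2, D_ORI, H_S) == 0.0

    def test_formula_value(self):
        vs = repulsion_speed(0.2, 1.0, 0.2)
        assert vs == pytest.approx(0.2 * math.exp(-0.5), rel=1e-12)
        assert vs == pytest.approx(0.1213, abs=1e-4)

    def test_speed_maximised_at_sigma(self):
        sigma = 0.2
        d = np.linspace(0.01, 1.0, 991)
        vs = np.array([repulsion_speed(x, 1.0, sigma) for x in d])
        assert d[np.argmax(vs)] == pytest.approx(sigma, abs=0.005)

    def test_bias_equals_half_speed_over_drift_factor(self):
        vs = repulsion_speed(0.3, 2.0, 0.2)
        a = repulsion_bias(0.3, 2.0, 0.2, D_ORI, H_S)
        # drift identity: bias a produces velocity D*a/h_s = vs/2
        assert D_ORI * a / H_S == pytest.approx(vs / 2.0, rel=1e-12)

    def test_simulated_separation_speed_matches(self):
        # flat MukBEF field, repulsion only: each sister moves away at vs/2,
        # so the separation initially grows at vs.  The horizon is kept
        # short so the separation (hence vs) barely changes, and the
        # starting point sits at the maximum of vs where it is flattest.
        par = TuringParams()
        op = OriParams(mu=0.0, k_rep=0.1, sigma_rep=0.3)
        d0 = 0.3
        j1 = int((1.25 - d0 / 2) / (0.1 / 21))
        j2 = int((1.25 + d0 / 2) / (0.1 / 21))
        horizon = 2.0
        reps = 2000
        seps = []
        for s in range(reps):
            st_ = mc._SimState(par, op, 2.5, 2, [j1, j2], 25)
            st_.ori_sister[:2] = [1, 0]
            for i in range(5):
                st_.P[i] = 0.0
            st_.P[_ssa.P_DU] = 0.0
            st_.P[_ssa.P_DV] = 0.0
            st_.v[:25] = 5  # flat
            st_.rebuild()
            st_.rs = _ssa.make_rng_state(9000 + s)
            st_.run_until(horizon)
            x = st_.ori_um()
            seps.append(abs(x[1] - x[0]))
        d_start = (j2 - j1) * (0.1 / 21)
        vs = repulsion_speed(d0, 0.1, 0.3)
        rate = (np.mean(seps) - d_start) / horizon
        se = np.std(seps, ddof=1) / math.sqrt(reps) / horizon
        assert abs(rate - vs) < max(3 * se, 0.1 * vs)


class TestDuplication:
    def test_birth_length_gives_time_zero(self):
        g = GrowthParams()
        assert g.length_to_time(2.5) == 0.0

    def test_length_time_map(self):
        g = GrowthParams()
        assert g.length_to_time(3.0) == pytest.approx(120 * math.log2(1.2))
        assert g.length_to_time(3.0) == pytest.approx(31.6, abs=0.05)

    def test_truncated_normal_moments(self):
        op = OriParams()
        rng = np.random.default_rng(5)
        draws = np.array([sample_duplication_length(op, rng)
                          for _ in range(100_000)])
        assert draws.min() >= 2.5 and draws.max() <= 5.0
        a = (2.5 - 3.0) / 0.48
        b = (5.0 - 3.0) / 0.48
        # asymmetric truncation (the left bound sits at -1.04 sd, the right
        # at +4.2 sd) shifts the mean up to ~3.13 um
        exact = stats.truncnorm.mean(a, b, loc=3.0, scale=0.48)
        assert draws.mean() == pytest.approx(exact, abs=0.01)
        assert exact == pytest.approx(3.13, abs=0.01)

    def test_duplication_time_range_check(self):
        op = OriParams(dup_range=(2.0, 5.0))
        with pytest.raises(InvalidParameterError):
            sample_duplication_time(GrowthParams(), op,
                                    np.random.default_rng(0))

    def test_duplicate_ori_state(self):
        st_ = OriState([100], 25, 21)
        new = duplicate_ori(st_, 0)
        assert new.count == 2
        assert new.positions == [100, 100]
        assert new.sisters == [1, 0]
        with pytest.raises(RuntimeError):
            duplicate_ori(new, 0)

    def test_duplicate_preserves_others(self):
        st_ = OriState([50, 400], 25, 21)
        new = duplicate_ori(st_, 1)
        assert new.positions[:2] == [50, 400]
        assert new.sisters == [-1, 2, 1]

    def test_repulsion_displacement_symmetric(self):
        # after duplication with repulsion in a flat field, the signed
        # displacements of the sisters are +/- symmetric over replicates
        par = TuringParams()
        op = OriParams(mu=0.0, k_rep=5.0, sigma_rep=0.2)
        j0 = 262  # mid-cell sub-compartment
        signed = []
        for s in range(200):
            st_ = mc._SimState(par, op, 2.5, 2, [j0, j0], 25)
            st_.ori_sister[:2] = [1, 0]
            for i in range(5):
                st_.P[i] = 0.0
            st_.P[_ssa.P_DU] = 0.0
            st_.P[_ssa.P_DV] = 0.0
            st_.rebuild()
            st_.rs = _ssa.make_rng_state(12000 + s)
            st_.run_until(60.0)
            x = st_.ori_um()
            signed.append(x[0] + x[1] - 2 * 1.25)
        se = np.std(signed, ddof=1) / math.sqrt(len(signed))
        assert abs(np.mean(signed)) < 3 * se + 1e-9


class TestSubCompartmentStability:
    def test_apparent_diffusion_stable_between_11_and_21(self):
        # frozen triangular v-peak: the apparent diffusion constant of the
        # biased walk changes by < 5% between 11 and 21 sub-compartments
        par = TuringParams()
        results = {}
        for n_sub in (11, 21):
            op = OriParams(n_sub=n_sub)
            st_ = mc._SimState(par, op, 2.5, 1, [12 * n_sub + n_sub // 2], 25)
            prof = np.maximum(0, 60 - 12 * np.abs(np.arange(25) - 12))
            st_.v[:25] = prof
            for i in range(5):
                st_.P[i] = 0.0
            st_.P[_ssa.P_DU] = 0.0
            st_.P[_ssa.P_DV] = 0.0
            st_.rebuild()
            st_.rs = _ssa.make_rng_state(31)
            xs = []
            hs_ = op.h_sub(par.h)
            for i in range(40_000):
                st_.run_until((i + 1) * 60.0)
                xs.append((st_.ori_pos[0] + 0.5) * hs_)
            xs = np.array(xs)
            v = np.diff(xs) / 60.0
            x_rel = xs[:-1] - 1.25
            sel = np.abs(x_rel) <= 0.3
            var = v[sel].var(ddof=1)
            slope = np.polyfit(x_rel[sel], v[sel], 1)[0]
            d_a = -math.log(1 + slope * 60.0) / 60.0
            tau = 1.0 / d_a
            results[n_sub] = var * 3600.0 / (tau * (1 - math.exp(-120.0 / tau)))
        assert abs(results[11] / results[21] - 1.0) < 0.05
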