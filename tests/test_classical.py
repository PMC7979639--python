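"""One- and two-compartment exact solutions under equi-dosing."""

import math

import numpy as np
import pytest
from scipy.integrate import quad

from transitpk import PKParams, Regimen
from transitpk import classical
from transitpk.core import RateCoincidenceError

from _oracles import bolus_oracle, infusion_oracle


class TestM1Beq:
    def test_initial_value_is_effective_dose(self, hypo_iv_params):
        r = Regimen(kind="Beq", D0=500.0, T=12.0, M=10)
        tc = classical.m1_beq(hypo_iv_params, r, [0.0])
        assert tc.central[0] == pytest.approx(500.0)

    def test_single_dose_reduction(self, hypo_iv_params):
        r1 = Regimen(kind="Beq", D0=500.0, T=12.0, M=1)
        t = np.linspace(0, 40, 101)
        tc = classical.m1_beq(hypo_iv_params, r1, t)
        expected = 500.0 * np.exp(-0.0692 * t)
        np.testing.assert_allclose(tc.central, expected, rtol=1e-12)

    def test_steady_interval_start_matches_long_dose_train(self, hypo_iv_params):
        # 500-dose propagation vs the closed-form periodic limit
        r = Regimen(kind="Beq", D0=500.0, T=12.0, M=500)
        sol = classical.solve(hypo_iv_params, r)
        start = 499 * 12.0
        oracle = bolus_oracle(hypo_iv_params, r, [start])["central"][0]
        ss = sol.steady().initial_values["central"]
        assert ss == pytest.approx(oracle, rel=1e-6)

    def test_collapsed_form_equals_dose_sum(self, hypo_iv_params):
        r = Regimen(kind="Beq", D0=500.0, T=12.0, M=40)
        sol = classical.solve(hypo_iv_params, r)
        t = np.linspace(0.0, 600.0, 701)
        np.testing.assert_allclose(
            sol.levels(t)["central"],
            sol.levels_sum(t)["central"],
            rtol=1e-10,
            atol=1e-12,
        )

    def test_interval_evaluator_consistent_with_transient(self, hypo_iv_params):
        r = Regimen(kind="Beq", D0=500.0, T=12.0, M=8)
        sol = classical.solve(hypo_iv_params, r)
        t_m = np.linspace(0.0, 12.0, 25, endpoint=False)
        for m in (1, 3, 8):
            np.testing.assert_allclose(
                sol.interval(m, t_m),
                sol.central((m - 1) * 12.0 + t_m),
                rtol=1e-12,
            )

    def test_steady_interval_average_is_clearance_ratio(self, hypo_iv_params):
        # mean of the periodic profile equals F (D0/T) / k_e
        r = Regimen(kind="Beq", D0=500.0, T=12.0, M="infinite")
        ss = classical.solve(hypo_iv_params, r).steady()
        avg, _ = quad(lambda x: ss(np.array([x]))["central"][0], 0.0, 12.0)
        avg /= 12.0
        assert avg == pytest.approx((500.0 / 12.0) / 0.0692, rel=1e-9)


class TestM1BeqL:
    def test_equal_loading_dose_reduces_to_beq(self, hypo_iv_params):
        t = np.linspace(0, 100, 301)
        r = Regimen(kind="Beq", D0=500.0, T=12.0, M=9)
        rl = Regimen(kind="BeqL", D0=500.0, T=12.0, M=9, D_L=500.0)
        np.testing.assert_allclose(
            classical.m1_beql(hypo_iv_params, rl, t).central,
            classical.m1_beq(hypo_iv_params, r, t).central,
            rtol=1e-14,
        )

    def test_initial_value_is_loading_dose(self, hypo_iv_params):
        rl = Regimen(kind="BeqL", D0=500.0, T=12.0, M=9, D_L=800.0)
        tc = classical.m1_beql(hypo_iv_params, rl, [0.0])
        assert tc.central[0] == pytest.approx(800.0)

    def test_matches_impulse_restart_oracle(self, hypo_iv_params):
        rl = Regimen(kind="BeqL", D0=500.0, T=12.0, M=9, D_L=800.0)
        tc = classical.m1_beql(hypo_iv_params, rl, [30.0])
        oracle = bolus_oracle(hypo_iv_params, rl, [30.0])["central"][0]
        assert tc.central[0] == pytest.approx(oracle, rel=1e-8)


class TestM1Ieq:
    def test_steady_period_average(self, hypo_iv_params):
        # time-average of the periodic profile = F k_in t_f / (k_e T)
        r = Regimen(kind="Ieq", k_in=41.67, t_f=3.0, T=6.0, M="infinite")
        ss = classical.solve(hypo_iv_params, r).steady()
        avg, _ = quad(
            lambda x: ss(np.array([x]))["central"][0], 0.0, 6.0, points=[3.0]
        )
        avg /= 6.0
        assert avg == pytest.approx(41.67 * 3.0 / (0.0692 * 6.0), rel=1e-9)

    def test_matches_piecewise_forcing_oracle(self, hypo_iv_params):
        r = Regimen(kind="Ieq", k_in=41.67, t_f=3.0, T=6.0, M=30)
        tc = classical.m1_ieq(hypo_iv_params, r, [100.0])
        oracle = infusion_oracle(hypo_iv_params, r, [100.0])[0]
        assert tc.central[0] == pytest.approx(oracle, rel=1e-8)

    def test_continuous_at_switch_times(self, hypo_iv_params):
        r = Regimen(kind="Ieq", k_in=41.67, t_f=3.0, T=6.0, M=10)
        sol = classical.solve(hypo_iv_params, r)
        eps = 1e-9
        for switch in (6.0, 9.0, 12.0, 15.0):
            lo = sol.central(np.array([switch - eps]))[0]
            hi = sol.central(np.array([switch + eps]))[0]
            assert hi == pytest.approx(lo, rel=1e-6)

    def test_near_continuous_infusion_limit(self, hypo_iv_params):
        # t_f -> T with many doses approaches the constant-infusion plateau
        r = Regimen(kind="Ieq", k_in=41.67, t_f=5.999, T=6.0, M="infinite")
        ss = classical.solve(hypo_iv_params, r).steady()
        plateau = 41.67 / 0.0692
        mid = ss(np.array([3.0]))["central"][0]
        assert mid == pytest.approx(plateau, rel=1e-2)


class TestM2:
    def test_initial_conditions(self, hypo_oral_params):
        r = Regimen(kind="Beq", D0=500.0, T=12.0, M=5)
        tc = classical.m2_beq(hypo_oral_params, r, [0.0])
        assert tc["absorption"][0] == pytest.approx(500.0)
        assert tc.central[0] == pytest.approx(0.0, abs=1e-12)

    def test_single_dose_matches_oracle_and_is_unimodal(self, hypo_oral_params):
        r = Regimen(kind="Beq", D0=500.0, T=1e9, M=1)
        t = np.linspace(0.0, 40.0, 401)
        tc = classical.m2_beq(hypo_oral_params, r, t)
        oracle = bolus_oracle(hypo_oral_params, r, [5.0])["central"][0]
        at5 = classical.m2_beq(hypo_oral_params, r, [5.0]).central[0]
        assert at5 == pytest.approx(oracle, rel=1e-8)
        assert np.all(tc.central >= 0)
        d = np.diff(tc.central)
        sign_changes = np.sum(np.diff(np.sign(d[d != 0])) != 0)
        assert sign_changes == 1  # single interior maximum

    def test_rate_coincidence_rejected(self):
        p = PKParams(model="M2", k_e=0.7, k_a=0.7)
        r = Regimen(kind="Beq", D0=1.0, T=1.0, M=2)
        with pytest.raises(RateCoincidenceError):
            classical.m2_beq(p, r, [0.0, 1.0])

    def test_loading_matches_oracle(self, hypo_oral_params):
        rl = Regimen(kind="BeqL", D0=500.0, T=12.0, M=9, D_L=800.0)
        tc = classical.m2_beql(hypo_oral_params, rl, [30.0])
        oracle = bolus_oracle(hypo_oral_params, rl, [30.0])["central"][0]
        assert tc.central[0] == pytest.approx(oracle, rel=1e-8)

    def test_long_train_converges_to_steady_profile(self, hypo_oral_params):
        r = Regimen(kind="Beq", D0=500.0, T=12.0, M=400)
        sol = classical.solve(hypo_oral_params, r)
        t_inf = np.linspace(0.0, 12.0, 97, endpoint=False)
        final = sol.central(399 * 12.0 + t_inf)
        ss = sol.steady()(t_inf)["central"]
        assert np.max(np.abs(final - ss)) / ss.max() < 1e-6

    def test_steady_extrema_match_dense_sampling(self, hypo_oral_params):
        a_min, t_star, a_max = classical.m2_steady_extrema(
            hypo_oral_params, 12.0, 500.0
        )
        ss = classical.solve(
            hypo_oral_params, Regimen(kind="Beq", D0=500.0, T=12.0, M="infinite")
        ).steady()
        t = np.linspace(0.0, 12.0, 100_000, endpoint=False)
        ac = ss(t)["central"]
        assert a_max == pytest.approx(ac.max(), rel=1e-8)
        assert a_min == pytest.approx(ac.min(), rel=1e-8)
        assert abs(t_star - t[np.argmax(ac)]) < 12.0 / 100_000 * 1.5
        assert 0.0 < t_star < 12.0 and a_min < a_max

    def test_steady_extrema_long_interval_limits(self, hypo_oral_params):
        # T -> inf: trough -> 0 and peak -> single-dose peak
        a_min, _, a_max = classical.m2_steady_extrema(hypo_oral_params, 400.0, 500.0)
        t = np.linspace(0.0, 60.0, 20_001)
        single = classical.m2_beq(
            hypo_oral_params, Regimen(kind="Beq", D0=500.0, T=1e9, M=1), t
        ).central
        assert a_min == pytest.approx(0.0, abs=1e-6)
        assert a_max == pytest.approx(single.max(), rel=1e-6)


class TestReferenceProfiles:
    def test_continuous_infusion_plateau(self, hypo_iv_params):
        t = np.linspace(0.0, 300.0, 301)
        tc = classical.continuous_infusion(hypo_iv_params, 41.67, t)
        assert tc.central[0] == 0.0
        assert np.all(np.diff(tc.central) >= 0)
        assert tc.central[-1] == pytest.approx(41.67 / 0.0692, rel=1e-6)

    def test_continuous_infusion_matches_oracle(self, hypo_iv_params):
        r = Regimen(kind="Ieq", k_in=41.67, t_f=11.999999, T=12.0, M=2)
        # a single long "on" phase approximates constant infusion to t=12
        tc = classical.continuous_infusion(hypo_iv_params, 41.67, [12.0])
        oracle = infusion_oracle(hypo_iv_params, r, [11.9999])[0]
        assert tc.central[0] == pytest.approx(oracle, rel=1e-5)

    def test_lag_profile_is_shifted_single_dose(self, hypo_oral_params):
        t = np.linspace(0.0, 40.0, 161)
        lag = classical.lag_time_solution(hypo_oral_params, 500.0, 3.0, t)
        plain = classical.lag_time_solution(hypo_oral_params, 500.0, 0.0, t)
        single = classical.m2_beq(
            hypo_oral_params, Regimen(kind="Beq", D0=500.0, T=1e9, M=1), t
        )
        np.testing.assert_allclose(plain.central, single.central, rtol=1e-12)
        assert np.all(lag.central[t < 3.0] == 0.0)
        # value at t = 5 equals the unshifted curve at t = 2
        at5 = classical.lag_time_solution(hypo_oral_params, 500.0, 3.0, [5.0])
        at2 = classical.m2_beq(
            hypo_oral_params, Regimen(kind="Beq", D0=500.0, T=1e9, M=1), [2.0]
        )
        assert at5.central[0] == pytest.approx(at2.central[0], rel=1e-12)


class TestStructuralProperties:
    @pytest.mark.parametrize("model_kind", ["m1", "m2"])
    def test_superposition_of_shifted_single_doses(
        self, model_kind, hypo_iv_params, hypo_oral_params
    ):
        params = hypo_iv_params if model_kind == "m1" else hypo_oral_params
        r = Regimen(kind="Beq", D0=500.0, T=12.0, M=6)
        t = np.linspace(0.0, 100.0, 301)
        sol = classical.solve(params, r)
        total = np.zeros_like(t)
        single = classical.solve(
            params, Regimen(kind="Beq", D0=500.0, T=1e9, M=1)
        )
        for j in range(6):
            shifted = t - 12.0 * j
            vals = single.central(np.where(shifted >= 0, shifted, -1.0))
            total += np.where(shifted >= 0, vals, 0.0)
        np.testing.assert_allclose(sol.central(t), total, rtol=1e-10, atol=1e-10)

    def test_bolus_train_approaches_infusion_as_interval_shrinks(
        self, hypo_iv_params
    ):
        # k_in = D0/T fixed: sup-gap to the constant-infusion curve
        # shrinks monotonically with T
        k_in = 41.67
        t = np.linspace(0.0, 48.0, 2001)
        ref = classical.continuous_infusion(hypo_iv_params, k_in, t).central
        gaps = []
        for T in (1.0, 0.5, 0.1):
            r = Regimen(kind="Beq", D0=k_in * T, T=T, M="infinite")
            sol = classical.solve(hypo_iv_params, r)
            gaps.append(np.max(np.abs(sol.central(t) - ref)))
        assert gaps[0] > gaps[1] > gaps[2]

    def test_trajectories_nonnegative(self, hypo_iv_params, hypo_oral_params):
        t = np.linspace(-5.0, 80.0, 401)
        for params, r in [
            (hypo_iv_params, Regimen(kind="Beq", D0=500.0, T=12.0, M=5)),
            (hypo_oral_params, Regimen(kind="BeqL", D0=500.0, T=12.0, M=5, D_L=900.0)),
            (hypo_iv_params, Regimen(kind="Ieq", k_in=41.67, t_f=3.0, T=6.0, M=8)),
        ]:
            tc = classical.solve(params, r).timecourse(t)
            for series in tc.levels.values():
                assert np.all(series >= -1e-9)
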