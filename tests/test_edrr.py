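"""Equi-dosing regimen regions: boundaries, slices, classification."""

import math

import numpy as np
import pytest
from scipy.optimize import brentq

from transitpk import PKParams, Regimen, TherapeuticRange
from transitpk import classical, edrr


class TestIVBolusRegion:
    def test_crossover_dose_is_window_width(self, hypo_iv_params, therapeutic_window):
        reg = edrr.edrr_iv_bolus(hypo_iv_params, therapeutic_window)
        t_star, d_star = reg.crossover
        assert d_star == pytest.approx(700.0)
        assert t_star == pytest.approx(math.log(1000 / 300) / 0.0692)

    def test_crossover_matches_bisection_root(self, hypo_iv_params, therapeutic_window):
        reg = edrr.edrr_iv_bolus(hypo_iv_params, therapeutic_window)
        f = lambda T: (
            300.0 * math.expm1(0.0692 * T) - 1000.0 * -math.expm1(-0.0692 * T)
        )
        root = brentq(f, 1.0, 100.0, xtol=1e-12)
        assert reg.crossover[0] == pytest.approx(root, rel=1e-10)

    def test_upper_boundary_hits_max_safe_level(self, hypo_iv_params, therapeutic_window):
        # a regimen sampled on f_hi has steady peak exactly D_MS
        reg = edrr.edrr_iv_bolus(
            hypo_iv_params, therapeutic_window, T_grid=[6.0, 10.0, 15.0]
        )
        for T, d0 in zip(reg.T, reg.f_hi):
            r = Regimen(kind="Beq", D0=float(d0), T=float(T), M="infinite")
            _, a_max = edrr.steady_extrema(hypo_iv_params, r)
            assert a_max == pytest.approx(1000.0, rel=1e-10)

    def test_lower_boundary_hits_min_effective_level(
        self, hypo_iv_params, therapeutic_window
    ):
        reg = edrr.edrr_iv_bolus(
            hypo_iv_params, therapeutic_window, T_grid=[6.0, 10.0, 15.0]
        )
        for T, d0 in zip(reg.T, reg.f_lo):
            r = Regimen(kind="Beq", D0=float(d0), T=float(T), M="infinite")
            a_min, _ = edrr.steady_extrema(hypo_iv_params, r)
            assert a_min == pytest.approx(300.0, rel=1e-10)

    def test_petal_empty_without_window(self, hypo_iv_params):
        # degenerate range (D_me ~ D_MS) leaves no acceptable regimen
        rng = TherapeuticRange(D_me=999.999999, D_MS=1000.0)
        reg = edrr.edrr_iv_bolus(hypo_iv_params, rng, T_grid=np.linspace(1, 30, 30))
        assert not reg.nonempty or reg.crossover[0] < 1e-4


class TestOralBolusRegion:
    def test_boundaries_invert_steady_extrema(self, hypo_oral_params, therapeutic_window):
        reg = edrr.edrr_oral_bolus(
            hypo_oral_params, therapeutic_window, T_grid=[8.0, 12.0, 16.0]
        )
        for T, lo, hi in zip(reg.T, reg.f_lo, reg.f_hi):
            a_min, _, _ = classical.m2_steady_extrema(hypo_oral_params, T, float(lo))
            _, _, a_max = classical.m2_steady_extrema(hypo_oral_params, T, float(hi))
            assert a_min == pytest.approx(300.0, rel=1e-10)
            assert a_max == pytest.approx(1000.0, rel=1e-10)

    def test_fast_absorption_limit_approaches_iv_petal(self, therapeutic_window):
        # k_a -> inf: the oral petal collapses onto the IV petal
        p_iv = PKParams(model="M1", k_e=0.0692)
        grid = np.linspace(2.0, 15.0, 14)
        iv = edrr.edrr_iv_bolus(p_iv, therapeutic_window, T_grid=grid)
        gaps = []
        for mult in (100, 300, 1000):
            p_fast = PKParams(model="M2", k_e=0.0692, k_a=mult * 0.0692)
            oral = edrr.edrr_oral_bolus(p_fast, therapeutic_window, T_grid=grid)
            gaps.append(
                max(
                    np.max(np.abs(oral.f_hi - iv.f_hi) / iv.f_hi),
                    np.max(np.abs(oral.f_lo - iv.f_lo) / iv.f_lo),
                )
            )
        assert gaps[0] > gaps[1] > gaps[2]
        assert gaps[2] < 0.01

    def test_crossover_found_numerically(self, hypo_oral_params, therapeutic_window):
        reg = edrr.edrr_oral_bolus(hypo_oral_params, therapeutic_window)
        t_star, d_star = reg.crossover
        lo, hi = edrr.edrr_oral_bolus(
            hypo_oral_params, therapeutic_window, T_grid=[t_star]
        ).f_lo[0], edrr.edrr_oral_bolus(
            hypo_oral_params, therapeutic_window, T_grid=[t_star]
        ).f_hi[0]
        assert lo == pytest.approx(hi, rel=1e-8)
        assert d_star == pytest.approx(lo, rel=1e-8)


class TestLoadingRegion:
    def test_unsafe_loading_dose_empties_slice(self, hypo_iv_params, therapeutic_window):
        region = edrr.edrr_loading(
            hypo_iv_params, therapeutic_window, D_L_values=[1200.0]
        )
        assert not region.slices[0].nonempty

    def test_slice_is_chopped_base_petal(self, hypo_iv_params, therapeutic_window):
        base = edrr.edrr_iv_bolus(hypo_iv_params, therapeutic_window)
        region = edrr.edrr_loading(
            hypo_iv_params, therapeutic_window, D_L_values=[650.0]
        )
        s = region.slices[0]
        t_chop = math.log(650.0 / 300.0) / 0.0692
        inside = s.T < t_chop
        np.testing.assert_allclose(s.f_lo[inside], base.f_lo[inside])
        assert np.all(np.isnan(s.f_lo[~inside]))

    def test_interior_regimen_therapeutic_immediately_and_always(
        self, hypo_iv_params, therapeutic_window
    ):
        # pick a point inside a chopped petal and simulate ten periods
        region = edrr.edrr_loading(
            hypo_iv_params, therapeutic_window, D_L_values=[650.0]
        )
        s = region.slices[0]
        ok = np.where(np.isfinite(s.f_lo) & (s.f_lo < s.f_hi))[0]
        i = ok[len(ok) // 2]
        T = float(s.T[i])
        d0 = 0.5 * (s.f_lo[i] + s.f_hi[i])
        r = Regimen(kind="BeqL", D0=d0, T=T, M=10, D_L=650.0)
        t = np.linspace(0.0, 10 * T, 4001)
        ac = classical.solve(hypo_iv_params, r).central(t)
        assert ac.min() > 300.0 and ac.max() < 1000.0

    def test_interval_extrema_monotonic_in_time(self, hypo_iv_params):
        # the per-interval peaks/troughs evolve monotonically, so the
        # first interval and the steady state bound every interval
        r = Regimen(kind="BeqL", D0=400.0, T=10.0, M=12, D_L=700.0)
        sol = classical.solve(hypo_iv_params, r)
        peaks, troughs = [], []
        for m in range(1, 13):
            seg = sol.central((m - 1) * 10.0 + np.linspace(0, 10.0, 400, endpoint=False))
            peaks.append(seg.max())
            troughs.append(seg.min())
        assert np.all(np.diff(peaks) <= 1e-9) or np.all(np.diff(peaks) >= -1e-9)
        assert np.all(np.diff(troughs) <= 1e-9) or np.all(np.diff(troughs) >= -1e-9)


class TestInfusionRegion:
    @pytest.fixture
    def fast_elim(self):
        return PKParams(model="M1", k_e=0.2)

    @pytest.fixture
    def wide_window(self):
        return TherapeuticRange(D_me=200.0, D_MS=3000.0)

    def test_crossover_rate_matches_boundary_intersection(self, fast_elim, wide_window):
        tf = 2.5
        kin_star = edrr.infusion_crossover(fast_elim, wide_window, tf)
        ke = 0.2

        def gap(T):
            lo = ke * 200.0 * math.expm1(ke * T) / math.expm1(ke * tf)
            hi = ke * 3000.0 * -math.expm1(-ke * T) / -math.expm1(-ke * tf)
            return hi - lo

        T_star = brentq(gap, tf + 1e-9, tf + 200.0, xtol=1e-12)
        lo_at_star = ke * 200.0 * math.expm1(ke * T_star) / math.expm1(ke * tf)
        assert kin_star == pytest.approx(lo_at_star, rel=1e-8)
        assert T_star == pytest.approx(tf + math.log(3000 / 200) / ke, rel=1e-8)

    def test_upper_boundary_hits_max_safe_level(self, fast_elim, wide_window):
        region = edrr.edrr_infusion(fast_elim, wide_window, t_f_values=[2.5], T_points=10)
        s = region.slices[0]
        for T, kin in zip(s.T[:-1], s.f_hi[:-1]):
            r = Regimen(kind="Ieq", k_in=float(kin), t_f=2.5, T=float(T), M="infinite")
            _, a_max = edrr.steady_extrema(fast_elim, r)
            assert a_max == pytest.approx(3000.0, rel=1e-10)

    def test_short_pulse_limit_recovers_bolus_petal(self, fast_elim, wide_window):
        # t_f -> 0 with k_in t_f = D0: infusion region -> IV bolus petal
        tf = 1e-4
        region = edrr.edrr_infusion(fast_elim, wide_window, t_f_values=[tf], T_points=50)
        s = region.slices[0]
        bolus = edrr.edrr_iv_bolus(fast_elim, wide_window, T_grid=s.T)
        np.testing.assert_allclose(s.f_lo * tf, bolus.f_lo, rtol=1e-3)
        np.testing.assert_allclose(s.f_hi * tf, bolus.f_hi, rtol=1e-3)

    def test_slice_domain_is_chopped_at_tf(self, fast_elim, wide_window):
        region = edrr.edrr_infusion(fast_elim, wide_window, t_f_values=[2.5])
        s = region.slices[0]
        assert s.T.min() > 2.5
        assert s.T.max() == pytest.approx(2.5 + math.log(15.0) / 0.2)


class TestNumericalRegion:
    def test_linearity_route_matches_iv_analytical(
        self, hypo_iv_params, therapeutic_window
    ):
        grid = np.linspace(2.0, 16.0, 8)
        ana = edrr.edrr_iv_bolus(hypo_iv_params, therapeutic_window, T_grid=grid)
        num = edrr.edrr_numerical(hypo_iv_params, therapeutic_window, T_grid=grid)
        np.testing.assert_allclose(num.f_lo, ana.f_lo, rtol=1e-10)
        np.testing.assert_allclose(num.f_hi, ana.f_hi, rtol=1e-10)

    def test_scan_route_matches_m2_analytical_within_grid_step(
        self, hypo_oral_params, therapeutic_window
    ):
        grid = np.linspace(6.0, 14.0, 5)
        ana = edrr.edrr_oral_bolus(hypo_oral_params, therapeutic_window, T_grid=grid)
        d0_grid = np.linspace(50.0, 1500.0, 300)
        step = d0_grid[1] - d0_grid[0]
        num = edrr.edrr_numerical(
            hypo_oral_params,
            therapeutic_window,
            T_grid=grid,
            method="scan",
            D0_grid=d0_grid,
        )
        assert np.max(np.abs(num.f_lo - ana.f_lo)) <= step
        assert np.max(np.abs(num.f_hi - ana.f_hi)) <= step

    def test_transit_region_contains_oral_region(self, therapeutic_window):
        # smoothing the delay widens the acceptable region: the
        # no-transit oral petal is a subset of every TCM petal
        p2 = PKParams(model="M2", k_e=0.0692, k_a=0.7, F=1.0)
        grid = np.linspace(4.0, 20.0, 9)
        oral = edrr.edrr_oral_bolus(p2, therapeutic_window, T_grid=grid)
        for n in (3, 10):
            pt = PKParams(
                model="Mt", k_e=0.0692, k_a=0.7, k=n / 4.4, n=n, F=1.0
            )
            reg = edrr.edrr_numerical(
                pt, therapeutic_window, T_grid=grid, samples=600
            )
            assert np.all(reg.f_lo <= oral.f_lo * (1 + 1e-9))
            assert np.all(reg.f_hi >= oral.f_hi * (1 - 1e-9))

    def test_regions_nest_towards_oral_as_cascade_sharpens(self, therapeutic_window):
        # fixed MTT: delay variance is MTT^2/n, so larger n means a
        # sharper (more lag-like) delay, a wider steady band, and a
        # smaller region; the petals nest down onto the oral petal
        p2 = PKParams(model="M2", k_e=0.0692, k_a=0.7, F=1.0)
        grid = np.linspace(6.0, 18.0, 5)
        oral = edrr.edrr_oral_bolus(p2, therapeutic_window, T_grid=grid)
        prev = None
        for n in (3, 10, 30):
            pt = PKParams(model="Mt", k_e=0.0692, k_a=0.7, k=n / 4.4, n=n, F=1.0)
            reg = edrr.edrr_numerical(pt, therapeutic_window, T_grid=grid, samples=600)
            if prev is not None:
                assert np.all(reg.f_lo >= prev.f_lo * (1 - 1e-9))
                assert np.all(reg.f_hi <= prev.f_hi * (1 + 1e-9))
            prev = reg
        assert np.all(prev.f_lo <= oral.f_lo * (1 + 1e-9))
        assert np.all(prev.f_hi >= oral.f_hi * (1 - 1e-9))


class TestClassification:
    def test_point_inside_petal_is_acceptable(self, hypo_iv_params, therapeutic_window):
        r = Regimen(kind="Beq", D0=350.0, T=8.0, M="infinite")
        v = edrr.classify_regimen(hypo_iv_params, r, therapeutic_window)
        assert v.verdict is edrr.Verdict.ACCEPTABLE
        assert 300.0 < v.steady_min < v.steady_max < 1000.0

    def test_excessive_dose_is_unsafe(self, hypo_iv_params, therapeutic_window):
        r = Regimen(kind="Beq", D0=900.0, T=6.0, M="infinite")
        v = edrr.classify_regimen(hypo_iv_params, r, therapeutic_window)
        assert v.verdict is edrr.Verdict.UNSAFE

    def test_sparse_dosing_overshoots_and_undershoots(
        self, hypo_iv_params, therapeutic_window
    ):
        # beyond the petal tip a moderate dose swings out both sides
        r = Regimen(kind="Beq", D0=900.0, T=30.0, M="infinite")
        v = edrr.classify_regimen(hypo_iv_params, r, therapeutic_window)
        assert v.verdict is edrr.Verdict.BOTH

    def test_tiny_dose_is_ineffective(self, hypo_iv_params, therapeutic_window):
        r = Regimen(kind="Beq", D0=50.0, T=8.0, M="infinite")
        v = edrr.classify_regimen(hypo_iv_params, r, therapeutic_window)
        assert v.verdict is edrr.Verdict.INEFFECTIVE

    def test_transit_model_classification(self, tcm_multidose_params, therapeutic_window):
        r = Regimen(kind="Beq", D0=500.0, T=8.0, M="infinite")
        v = edrr.classify_regimen(tcm_multidose_params, r, therapeutic_window)
        assert v.verdict is edrr.Verdict.ACCEPTABLE
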