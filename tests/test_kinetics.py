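"""One-tissue-compartment forward model, fitting and extraction conversion."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mbfagree.kinetics import (ExtractionParams, FitOptions, FrameSchedule,
                               TimeActivityCurve, compute_mfr,
                               default_schedule, extraction_fraction,
                               fit_1tcm, k1_to_mbf, mbf_to_k1,
                               model_pet_signal, tissue_concentration,
                               tissue_response)


class TestFrameSchedule:
    def test_default_schedule_shape(self, schedule):
        assert schedule.n_frames == 21
        assert schedule.total_duration_s == pytest.approx(486.0)
        # contiguous frames
        np.testing.assert_allclose(
            schedule.frame_start_s[1:],
            schedule.frame_start_s[:-1] + schedule.frame_duration_s[:-1])

    @pytest.mark.parametrize("starts,durs", [
        ([0, 5], [6, 5]),          # overlap
        ([5, 0], [2, 2]),          # decreasing starts
        ([0, 5], [0, 5]),          # zero duration
    ])
    def test_invalid_schedules_rejected(self, starts, durs):
        with pytest.raises(ValueError):
            FrameSchedule(np.array(starts, float), np.array(durs, float))

    def test_tac_requires_one_value_per_frame(self, schedule):
        with pytest.raises(ValueError):
            TimeActivityCurve(schedule, np.ones(5))
        with pytest.raises(ValueError):
            TimeActivityCurve(schedule, np.full(schedule.n_frames, np.nan))


class TestExtractionConversion:
    def test_k1_at_unit_flow_matches_formula(self):
        # direct evaluation: K1 = 1 - 0.77*exp(-0.63)
        assert mbf_to_k1(1.0) == pytest.approx(1 - 0.77 * np.exp(-0.63),
                                               abs=1e-12)
        assert mbf_to_k1(1.0) == pytest.approx(0.5899, abs=1e-4)

    def test_zero_flow_limit(self):
        assert mbf_to_k1(0.0) == 0.0
        assert k1_to_mbf(0.0) == 0.0

    def test_high_flow_asymptote(self):
        # extraction tends to 1 - a = 0.23
        m = 1e6
        assert mbf_to_k1(m) / m == pytest.approx(0.23, rel=1e-4)

    def test_roundtrip(self):
        x = np.linspace(0.01, 10.0, 200)
        back = k1_to_mbf(mbf_to_k1(x))
        np.testing.assert_allclose(back, x, atol=1e-8)

    def test_inverse_of_forward_example(self):
        assert k1_to_mbf(0.5899) == pytest.approx(1.0, abs=2e-4)

    def test_extraction_fraction_range_and_monotonicity(self):
        m = np.linspace(0.05, 20, 500)
        e = extraction_fraction(m)
        assert np.all((e > 0.23) & (e < 1.0))
        assert np.all(np.diff(e) < 0)
        k1 = mbf_to_k1(m)
        assert np.all(np.diff(k1) > 0)

    @settings(derandomize=True, max_examples=50)
    @given(st.floats(0.001, 10), st.floats(0.001, 10))
    def test_inverse_is_monotone(self, k1a, k1b):
        lo, hi = sorted([k1a, k1b])
        assert k1_to_mbf(lo) <= k1_to_mbf(hi) + 1e-12

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            mbf_to_k1(-0.1)
        with pytest.raises(ValueError):
            k1_to_mbf(-0.1)
        with pytest.raises(ValueError):
            ExtractionParams(a=1.2)


class TestMFR:
    def test_printed_segmental_medians_ratio(self):
        assert compute_mfr(2.24, 1.08) == pytest.approx(2.074, abs=1e-3)

    def test_identity_and_missing_flag(self):
        assert compute_mfr(1.3, 1.3) == pytest.approx(1.0)
        with pytest.warns(UserWarning):
            out = compute_mfr(np.array([2.0, 2.0]), np.array([1.0, 0.0]))
        assert out[0] == pytest.approx(2.0)
        assert np.isnan(out[1])


class TestTissueResponse:
    def test_zero_uptake_is_zero(self, blood_tac):
        t, ct = tissue_response(0.0, 0.2, blood_tac)
        assert np.all(ct == 0)

    def test_constant_input_closed_form(self, constant_input):
        # Ca == 1, K1=0.6, k2=0.2: Ct(t) = 3*(1 - exp(-0.2 t))
        t = np.array([1.0, 2.5, 5.0, 8.0])
        ct = tissue_concentration(0.6, 0.2, constant_input, t)
        np.testing.assert_allclose(ct, 3.0 * (1 - np.exp(-0.2 * t)), atol=1e-8)

    def test_pure_integrator_limit(self, constant_input):
        # k2=0, Ca == 1: Ct = K1 * t
        t = np.array([1.0, 4.0, 6.0])
        ct = tissue_concentration(0.8, 0.0, constant_input, t)
        np.testing.assert_allclose(ct, 0.8 * t, atol=1e-8)

    def test_linearity_in_input_scale(self, schedule, blood_tac):
        doubled = TimeActivityCurve(schedule, 2.0 * blood_tac.activity)
        t = np.linspace(0.1, 8.0, 40)
        ct1 = tissue_concentration(0.6, 0.3, blood_tac, t)
        ct2 = tissue_concentration(0.6, 0.3, doubled, t)
        np.testing.assert_allclose(ct2, 2.0 * ct1, rtol=1e-12)

    def test_nonnegative_for_nonnegative_input(self, blood_tac):
        _, ct = tissue_response(0.9, 1.5, blood_tac)
        assert np.all(ct >= 0)
        assert ct[0] == 0.0

    def test_matches_trapezoid_quadrature(self, schedule):
        # exact piecewise-analytic convolution vs brute trapezoid on a
        # 0.01-s grid, random smooth input
        rng = np.random.default_rng(7)
        act = np.abs(np.cumsum(rng.normal(2, 1, schedule.n_frames)))
        tac = TimeActivityCurve(schedule, act)
        K1, k2 = 0.7, 0.4
        tk, ck = tac.interp_knots()
        tq = np.arange(0.0, 8.1 + 1e-9, 0.01 / 60.0)
        ca = np.interp(tq, tk, ck)
        for t_eval in [2.0, 5.0, 8.1]:
            m = tq <= t_eval + 1e-12
            integrand = ca[m] * np.exp(-k2 * (t_eval - tq[m]))
            brute = K1 * np.trapezoid(integrand, tq[m])
            exact = tissue_concentration(K1, k2, tac, [t_eval])[0]
            assert exact == pytest.approx(brute, rel=1e-4)

    def test_negative_rates_rejected(self, blood_tac):
        with pytest.raises(ValueError):
            tissue_concentration(-0.1, 0.2, blood_tac, [1.0])
        with pytest.raises(ValueError):
            tissue_concentration(0.1, -0.2, blood_tac, [1.0])


class TestModelPetSignal:
    def test_pure_blood_pool_equals_input(self, schedule, blood_tac):
        model = model_pet_signal(0.6, 0.2, 1.0, blood_tac, schedule)
        np.testing.assert_allclose(model.activity, blood_tac.activity,
                                   rtol=1e-12)

    def test_zero_everything_is_zero(self, schedule, blood_tac):
        model = model_pet_signal(0.0, 0.0, 0.0, blood_tac, schedule)
        assert np.all(model.activity == 0)

    def test_short_frames_converge_to_point_values(self, constant_input):
        # as durations -> 0 the frame average approaches the
        # instantaneous signal; analytic case Ca == 1
        K1, k2, tbv = 0.6, 0.2, 0.3
        t_mid = 5.0
        exact_ct = 3.0 * (1 - np.exp(-0.2 * t_mid))
        point = (1 - tbv) * exact_ct + tbv * 1.0
        vals = []
        for dur_s in [60.0, 6.0, 0.6]:
            sch = FrameSchedule(
                np.concatenate([[0.0], [t_mid * 60 - dur_s / 2]]),
                np.array([1e-6, dur_s]))
            tac = TimeActivityCurve(sch, np.ones(2))
            vals.append(model_pet_signal(K1, k2, tbv, tac, sch).activity[-1])
        errs = np.abs(np.array(vals) - point)
        assert errs[-1] < 1e-6
        assert np.all(np.diff(errs) < 0)  # monotone refinement

    def test_schedule_mismatch_rejected(self, schedule, blood_tac):
        other = FrameSchedule(schedule.frame_start_s + 1.0,
                              schedule.frame_duration_s)
        with pytest.raises(ValueError):
            model_pet_signal(0.5, 0.1, 0.3, blood_tac, other)


class TestFit1TCM:
    TRUTH = (0.59, 0.15, 0.35)

    def test_noise_free_self_consistency(self, schedule, blood_tac):
        K1, k2, tbv = self.TRUTH
        meas = model_pet_signal(K1, k2, tbv, blood_tac, schedule)
        fit = fit_1tcm(meas, blood_tac)
        assert fit.converged
        assert fit.K1 == pytest.approx(K1, rel=1e-4)
        assert fit.k2 == pytest.approx(k2, rel=1e-4)
        assert fit.tbv == pytest.approx(tbv, rel=1e-4)
        assert fit.wrss == pytest.approx(0.0, abs=1e-12)
        assert fit.mbf == pytest.approx(k1_to_mbf(K1), rel=1e-4)

    def test_matches_grid_search_oracle(self, schedule, blood_tac):
        # coarse brute-force grid over (K1, k2, tbv); the fit must land
        # within one grid cell of the grid argmin
        K1t, k2t, tbvt = self.TRUTH
        y = model_pet_signal(K1t, k2t, tbvt, blood_tac, schedule).activity
        w = schedule.duration_min
        k1_grid = np.linspace(0.0, 2.0, 50)
        k2_grid = np.linspace(0.0, 1.0, 50)
        tbv_grid = np.linspace(0.0, 0.95, 20)
        ca_avg = model_pet_signal(0.0, 0.0, 1.0, blood_tac, schedule).activity
        best, argmin = np.inf, None
        for k2g in k2_grid:
            # tissue average for unit K1 (signal is linear in K1)
            ct1 = model_pet_signal(1.0, k2g, 0.0, blood_tac, schedule).activity
            for k1g in k1_grid:
                ct = k1g * ct1
                pred = ((1 - tbv_grid[:, None]) * ct[None, :]
                        + tbv_grid[:, None] * ca_avg[None, :])
                wrss = np.sum(w * (pred - y[None, :]) ** 2, axis=1)
                i = int(np.argmin(wrss))
                if wrss[i] < best:
                    best, argmin = wrss[i], (k1g, k2g, tbv_grid[i])
        fit = fit_1tcm(model_pet_signal(K1t, k2t, tbvt, blood_tac, schedule),
                       blood_tac)
        assert abs(fit.K1 - argmin[0]) <= np.diff(k1_grid)[0] + 1e-12
        assert abs(fit.k2 - argmin[1]) <= np.diff(k2_grid)[0] + 1e-12
        assert abs(fit.tbv - argmin[2]) <= np.diff(tbv_grid)[0] + 1e-12

    def test_monte_carlo_recovery_under_noise(self, schedule, blood_tac):
        # i.i.d. Gaussian noise, sigma = 5% of curve peak: mean K1
        # estimate over 200 replicates within 5% of truth
        K1, k2, tbv = self.TRUTH
        clean = model_pet_signal(K1, k2, tbv, blood_tac, schedule).activity
        sigma = 0.05 * clean.max()
        rng = np.random.default_rng(2024)
        est = []
        for _ in range(200):
            noisy = TimeActivityCurve(
                schedule, np.clip(clean + sigma * rng.standard_normal(
                    clean.size), 0, None))
            est.append(fit_1tcm(noisy, blood_tac).K1)
        assert np.mean(est) == pytest.approx(K1, rel=0.05)

    def test_all_zero_tac_returns_zero_fit(self, schedule, blood_tac):
        zero = TimeActivityCurve(schedule, np.zeros(schedule.n_frames))
        with pytest.warns(UserWarning):
            fit = fit_1tcm(zero, blood_tac)
        assert fit.K1 == 0.0 and fit.mbf == 0.0

    def test_too_few_frames_rejected(self, blood_tac):
        sch = FrameSchedule(np.arange(4) * 8.0, np.full(4, 8.0))
        tac = TimeActivityCurve(sch, np.ones(4))
        with pytest.raises(ValueError):
            fit_1tcm(tac, tac)

    def test_uniform_weights_mode(self, schedule, blood_tac):
        meas = model_pet_signal(*self.TRUTH, blood_tac, schedule)
        fit = fit_1tcm(meas, blood_tac, options=FitOptions(
            weights_mode="uniform"))
        assert fit.K1 == pytest.approx(self.TRUTH[0], rel=1e-4)
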