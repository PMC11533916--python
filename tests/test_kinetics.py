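"""One-tissue-compartment kinetics: closed forms, sampling, noise, fitting."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from suvrkit import (
    OneTissueParams,
    PlasmaInput,
    TimeActivityCurve,
    add_noise,
    default_frame_schedule,
    evaluate_plasma,
    fit_1tc,
    frame_average,
    simulate_1tc,
    tissue_curve,
)
from suvrkit.kinetics import C11_DECAY_RATE, ExpSum, FrameSchedule, KineticsError

from conftest import brute_force_1tc


class TestPlasmaInput:
    def test_zero_before_delay(self, plasma):
        t = np.array([0.0, plasma.delay * 0.5, plasma.delay * 0.99])
        assert np.all(evaluate_plasma(plasma, t) == 0.0)

    def test_single_exponential_at_origin(self):
        p = PlasmaInput(delay=0.0, a1=0.0, lam1=1.0, a2=1.0, lam2=0.1, a3=0.0, lam3=0.01)
        assert evaluate_plasma(p, [0.0])[0] == pytest.approx(1.0)

    def test_matches_direct_formula(self, plasma):
        t = 10.0
        tp = t - plasma.delay
        expected = (plasma.a1 * tp * np.exp(-plasma.lam1 * tp)
                    + plasma.a2 * np.exp(-plasma.lam2 * tp)
                    + plasma.a3 * np.exp(-plasma.lam3 * tp))
        assert evaluate_plasma(plasma, [t])[0] == pytest.approx(expected, rel=1e-12)

    def test_nonnegative_everywhere(self, plasma):
        t = np.linspace(0, 120, 2000)
        assert np.all(evaluate_plasma(plasma, t) >= 0.0)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(KineticsError):
            PlasmaInput(lam1=0.1, lam2=0.45, lam3=0.012)  # order violated
        with pytest.raises(KineticsError):
            PlasmaInput(a2=np.nan)
        with pytest.raises(KineticsError):
            evaluate_plasma(PlasmaInput(), [-1.0])


class TestSimulate1TC:
    def test_constant_infusion_closed_form(self):
        # C_p = c constant: C_T(t) = (K1 c / k2)(1 − e^{−k2 t})
        const = ExpSum([(2.0, 0.0, 0.0, 0.0)])
        ct = const.convolve_exp(0.1).scaled(0.3)
        for t in (1.0, 10.0, 50.0):
            assert ct(t) == pytest.approx((0.3 * 2.0 / 0.1) * (1 - np.exp(-0.1 * t)), rel=1e-12)

    def test_mono_exponential_closed_form(self):
        # C_p = e^{−λt}, λ ≠ k2: C_T = K1 (e^{−λt} − e^{−k2 t})/(k2 − λ)
        lam, k2, k1 = 0.3, 0.1, 0.5
        mono = ExpSum([(1.0, 0.0, 0.0, lam)])
        ct = mono.convolve_exp(k2).scaled(k1)
        for t in (2.0, 20.0):
            expected = k1 * (np.exp(-lam * t) - np.exp(-k2 * t)) / (k2 - lam)
            assert ct(t) == pytest.approx(expected, rel=1e-12)

    def test_matches_brute_force_convolution(self, plasma):
        p = OneTissueParams(0.3, 0.1)
        for t in (5.0, 30.0, 90.0):
            ours = simulate_1tc(p, plasma, [t])[0]
            oracle = brute_force_1tc(p, plasma, t)
            assert ours == pytest.approx(oracle, rel=1e-3)

    def test_brute_force_agreement_over_parameter_grid(self, plasma):
        rng = np.random.default_rng(42)
        for _ in range(8):
            p = OneTissueParams(rng.uniform(0.1, 0.6), rng.uniform(0.02, 0.3))
            t = rng.uniform(10, 90)
            assert simulate_1tc(p, plasma, [t])[0] == pytest.approx(
                brute_force_1tc(p, plasma, t), rel=1e-3)

    def test_starts_at_zero_and_nonnegative(self, plasma):
        p = OneTissueParams(0.3, 0.1)
        t = np.linspace(0, 90, 500)
        ct = simulate_1tc(p, plasma, t)
        assert ct[0] == 0.0
        assert np.all(ct >= 0.0)

    def test_constant_infusion_equilibrium_reaches_vt(self):
        # C_T/C_p → VT as t → ∞; checked at t = 10/k2 within 1%
        const = ExpSum([(1.0, 0.0, 0.0, 0.0)])
        for k1, k2 in [(0.3, 0.1), (0.2, 0.05)]:
            ct = const.convolve_exp(k2).scaled(k1)
            t = 10.0 / k2
            assert ct(t) / 1.0 == pytest.approx(k1 / k2, rel=1e-2)

    def test_invalid_k2_rejected(self, plasma):
        with pytest.raises(KineticsError):
            OneTissueParams(0.3, -0.1)
        with pytest.raises(KineticsError):
            plasma.as_expsum().convolve_exp(0.0)


class TestFrameSchedule:
    def test_default_schedule_shape(self, schedule):
        assert len(schedule) == 27
        assert schedule.total_duration == 90.0
        durs = schedule.durations
        assert np.allclose(durs[:6], 0.5) and np.allclose(durs[6:9], 1.0)
        assert np.allclose(durs[9:11], 2.0) and np.allclose(durs[11:], 5.0)

    @pytest.mark.parametrize("frames", [
        [],
        [(1.0, 2.0)],                 # does not start at 0
        [(0.0, 1.0), (2.0, 3.0)],     # gap
        [(0.0, 0.0)],                 # empty frame
    ])
    def test_invalid_schedules_rejected(self, frames):
        with pytest.raises(KineticsError):
            FrameSchedule(frames)


class TestFrameAverage:
    def test_constant_curve(self, schedule):
        tac = frame_average(lambda t: np.full_like(np.asarray(t, float), 3.0), schedule)
        assert np.allclose(tac.values, 3.0)

    def test_linear_curve_first_frame(self):
        sched = FrameSchedule([(0.0, 1.0)])
        tac = frame_average(lambda t: np.asarray(t, float), sched)
        assert tac.values[0] == pytest.approx(0.5, rel=1e-6)

    def test_exact_integration_matches_quadrature(self, plasma, schedule):
        curve = tissue_curve(OneTissueParams(0.3, 0.1), plasma)
        exact = frame_average(curve, schedule).values
        numeric = frame_average(lambda t: curve(t), schedule).values
        nz = exact > 1e-12
        assert np.allclose(exact[nz], numeric[nz], rtol=1e-3)


class TestAddNoise:
    def _tac(self, plasma, schedule):
        return frame_average(tissue_curve(OneTissueParams(0.3, 0.02), plasma), schedule)

    def test_scale_zero_is_identity(self, plasma, schedule):
        tac = self._tac(plasma, schedule)
        out = add_noise(tac, 0.0, seed=1)
        assert np.array_equal(out.values, tac.values)

    def test_deterministic_under_seed(self, plasma, schedule):
        tac = self._tac(plasma, schedule)
        a = add_noise(tac, 0.05, seed=123)
        b = add_noise(tac, 0.05, seed=123)
        assert np.array_equal(a.values, b.values)
        c = add_noise(tac, 0.05, seed=124)
        assert not np.array_equal(a.values, c.values)

    def test_variance_follows_stated_model(self, plasma, schedule):
        tac = self._tac(plasma, schedule)
        idx = 20  # a late 5-min frame
        scale = 0.05
        reps = np.array([add_noise(tac, scale, seed=s).values[idx] for s in range(1000)])
        t_mid, dur = schedule.midpoints[idx], schedule.durations[idx]
        expected_var = scale**2 * tac.values[idx] * np.exp(C11_DECAY_RATE * t_mid) / dur
        assert reps.var(ddof=1) == pytest.approx(expected_var, rel=0.10)

    def test_negative_scale_rejected(self, plasma, schedule):
        with pytest.raises(KineticsError):
            add_noise(self._tac(plasma, schedule), -0.1, seed=0)


class TestFit1TC:
    def test_noiseless_recovery(self, plasma, schedule):
        truth = OneTissueParams(0.3, 0.1)
        tac = frame_average(tissue_curve(truth, plasma), schedule)
        fit = fit_1tc(tac, plasma)
        assert isinstance(fit, OneTissueParams)
        assert fit.K1 == pytest.approx(truth.K1, rel=5e-3)
        assert fit.k2 == pytest.approx(truth.k2, rel=5e-3)

    def test_scaling_tac_doubles_k1_only(self, plasma, schedule):
        truth = OneTissueParams(0.25, 0.08)
        tac = frame_average(tissue_curve(truth, plasma), schedule)
        doubled = TimeActivityCurve(schedule=schedule, values=2 * tac.values)
        fit = fit_1tc(doubled, plasma)
        assert fit.K1 == pytest.approx(2 * truth.K1, rel=5e-3)
        assert fit.k2 == pytest.approx(truth.k2, rel=5e-3)

    def test_median_bias_small_under_noise(self, plasma, schedule):
        truth = OneTissueParams(0.3, 0.1)
        clean = frame_average(tissue_curve(truth, plasma), schedule)
        k1s = []
        for s in range(50):
            fit = fit_1tc(add_noise(clean, 0.05, seed=1000 + s), plasma)
            if isinstance(fit, OneTissueParams):
                k1s.append(fit.K1)
        assert len(k1s) >= 45
        assert abs(np.median(k1s) / truth.K1 - 1) < 0.05

    def test_too_few_frames_rejected(self, plasma):
        sched = FrameSchedule([(0, 1), (1, 2), (2, 3)])
        tac = frame_average(lambda t: np.asarray(t, float), sched)
        with pytest.raises(KineticsError):
            fit_1tc(tac, plasma)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(k1=st.floats(0.1, 0.6), k2=st.floats(0.02, 0.3), t=st.floats(1.0, 90.0))
def test_tissue_curve_is_nonnegative_and_bounded_by_equilibrium(k1, k2, t):
    """C_T stays within [0, VT·max C_p] for any physiological parameters."""
    plasma = PlasmaInput()
    p = OneTissueParams(k1, k2)
    val = simulate_1tc(p, plasma, [t])[0]
    grid = np.linspace(0, t, 400)
    cp_max = float(np.max(evaluate_plasma(plasma, grid)))
    assert 0.0 <= val <= p.VT * cp_max * (1 + 1e-9)
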