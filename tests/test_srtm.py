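"""SRTM/SRTM2 reference-tissue fitting: exactness, oracles, invariants."""

import numpy as np
import pytest
from scipy.optimize import minimize

from suvrkit import (
    OneTissueParams,
    estimate_k2prime,
    fit_srtm,
    fit_srtm2,
    frame_average,
    simulate_1tc,
    srtm_predict,
    tissue_curve,
)
from suvrkit.kinetics import KineticsError, TimeActivityCurve, decay_duration_weights
from suvrkit.srtm import SRTMFit, exp_conv_sampled


def make_pair(plasma, schedule, target: OneTissueParams, ref: OneTissueParams):
    tt = frame_average(tissue_curve(target, plasma), schedule)
    rt = frame_average(tissue_curve(ref, plasma), schedule)
    return tt, rt


class TestSrtmPredict:
    def test_identity_when_target_equals_reference(self, plasma, schedule, typical_pair):
        _, ref = typical_pair
        rt = frame_average(tissue_curve(ref, plasma), schedule)
        pred = srtm_predict(rt, R1=1.0, k2a=ref.k2, k2prime=ref.k2)
        assert np.allclose(pred, rt.values)

    def test_exact_for_two_1tc_regions(self, plasma):
        # both regions 1TC with shared input: operational equation is exact
        target = OneTissueParams(0.3, 0.06)
        ref = OneTissueParams(0.3, 0.12)
        times = np.linspace(1.0, 60.0, 60)
        pred = srtm_predict(tissue_curve(ref, plasma), R1=1.0, k2a=0.06,
                            k2prime=0.12, times=times)
        truth = simulate_1tc(target, plasma, times)
        assert np.allclose(pred, truth, rtol=2e-3)

    def test_sampled_convolution_matches_exact(self, plasma, typical_pair):
        _, ref = typical_pair
        curve = tissue_curve(ref, plasma)
        times = np.linspace(0.5, 60, 120)
        vals = np.asarray(curve(times))
        for rate in (0.02, 0.1, 0.5):
            approx = exp_conv_sampled(times, vals, np.array([rate]))[0]
            exact = np.asarray(curve.convolve_exp(rate)(times))
            assert np.allclose(approx[10:], exact[10:], rtol=2e-2)

    def test_invalid_parameters_rejected(self, plasma, schedule, typical_pair):
        _, ref = typical_pair
        rt = frame_average(tissue_curve(ref, plasma), schedule)
        with pytest.raises(KineticsError):
            srtm_predict(rt, R1=-1.0, k2a=0.05, k2prime=0.1)


class TestFitSrtm:
    def test_self_reference_gives_unity_dvr(self, plasma, schedule, typical_pair):
        _, ref = typical_pair
        rt = frame_average(tissue_curve(ref, plasma), schedule)
        fit = fit_srtm(rt, rt)
        assert fit.R1 == pytest.approx(1.0, abs=1e-3)
        assert fit.DVR == pytest.approx(1.0, abs=5e-3)

    def test_vt_ratio_of_two_recovered(self, plasma, schedule):
        target = OneTissueParams(0.3, 0.06)   # VT 5
        ref = OneTissueParams(0.3, 0.12)      # VT 2.5
        tt, rt = make_pair(plasma, schedule, target, ref)
        fit = fit_srtm(tt, rt)
        assert fit.DVR == pytest.approx(2.0, rel=1e-2)
        assert fit.k2prime == pytest.approx(0.12, rel=2e-2)

    def test_noisy_median_dvr_bias_small(self, plasma, schedule, typical_pair):
        from suvrkit import add_noise
        target, ref = typical_pair
        tt, rt = make_pair(plasma, schedule, target, ref)
        true_dvr = target.VT / ref.VT
        dvrs = []
        for s in range(50):
            fit = fit_srtm(add_noise(tt, 0.05, 2000 + s), add_noise(rt, 0.05, 3000 + s))
            if isinstance(fit, SRTMFit):
                dvrs.append(fit.DVR)
        assert abs(np.median(dvrs) / true_dvr - 1) < 0.03


class TestFitSrtm2:
    def test_self_reference_unity(self, plasma, schedule, typical_pair):
        _, ref = typical_pair
        rt = frame_average(tissue_curve(ref, plasma), schedule)
        fit = fit_srtm2(rt, rt, k2prime=ref.k2)
        assert fit.DVR == pytest.approx(1.0, abs=5e-3)

    def test_analytic_exactness_over_grid(self, plasma, schedule):
        """Noiseless 1TC pairs with correct k2': DVR = VT_t/VT_r within 1%."""
        rng = np.random.default_rng(11)
        for _ in range(20):
            target = OneTissueParams(rng.uniform(0.15, 0.5), rng.uniform(0.015, 0.08))
            ref = OneTissueParams(rng.uniform(0.15, 0.5), rng.uniform(0.015, 0.08))
            tt, rt = make_pair(plasma, schedule, target, ref)
            fit = fit_srtm2(tt, rt, k2prime=ref.k2)
            assert fit.DVR == pytest.approx(target.VT / ref.VT, rel=1e-2)

    def test_dvr_invariant_to_common_rescaling(self, plasma, schedule, typical_pair):
        target, ref = typical_pair
        tt, rt = make_pair(plasma, schedule, target, ref)
        base = fit_srtm2(tt, rt, k2prime=ref.k2)
        tt2 = TimeActivityCurve(schedule=schedule, values=7.3 * tt.values)
        rt2 = TimeActivityCurve(schedule=schedule, values=7.3 * rt.values)
        scaled = fit_srtm2(tt2, rt2, k2prime=ref.k2)
        assert scaled.DVR == pytest.approx(base.DVR, rel=1e-9)
        assert scaled.k2a == pytest.approx(base.k2a, rel=1e-6)

    def test_dvr_monotone_in_target_vt(self, plasma, schedule):
        ref = OneTissueParams(0.32, 0.32 / 14.0)
        rt = frame_average(tissue_curve(ref, plasma), schedule)
        dvrs = []
        for vt in (8.0, 11.0, 14.0, 18.0):
            tt = frame_average(tissue_curve(OneTissueParams(0.3, 0.3 / vt), plasma), schedule)
            dvrs.append(fit_srtm2(tt, rt, k2prime=ref.k2).DVR)
        assert np.all(np.diff(dvrs) > 0)

    def test_matches_brute_force_nonlinear_oracle(self, plasma, schedule):
        """Basis+refine solution equals direct 2-parameter NLS on (R1, k2a)."""
        rng = np.random.default_rng(5)
        w = decay_duration_weights(schedule)
        for _ in range(5):
            target = OneTissueParams(rng.uniform(0.2, 0.4), rng.uniform(0.018, 0.05))
            ref = OneTissueParams(rng.uniform(0.2, 0.4), rng.uniform(0.018, 0.05))
            tt, rt = make_pair(plasma, schedule, target, ref)
            k2p = ref.k2 * 1.1  # deliberately slightly mis-set
            fit = fit_srtm2(tt, rt, k2prime=k2p)

            mask = schedule.ends <= 60.0 + 1e-9
            t_mid, y = schedule.midpoints, tt.values[mask]

            def rss(theta):
                r1, k2a = theta
                if r1 <= 0 or k2a <= 0:
                    return 1e9
                conv = exp_conv_sampled(t_mid, rt.values, np.array([k2a]))[0, mask]
                pred = r1 * (rt.values[mask] + (k2p - k2a) * conv)
                return float(np.sum(w[mask] * (y - pred) ** 2))

            oracle = min(
                (minimize(rss, x0=[r0, k0], method="Nelder-Mead",
                          options={"xatol": 1e-10, "fatol": 1e-14, "maxiter": 4000})
                 for r0 in (0.5, 1.0, 2.0) for k0 in (0.01, 0.03, 0.1)),
                key=lambda r: r.fun,
            )
            assert fit.k2a == pytest.approx(oracle.x[1], rel=1e-3)
            assert fit.R1 == pytest.approx(oracle.x[0], rel=1e-3)

    def test_missett_k2prime_bias_matches_refit_oracle(self, plasma, schedule, typical_pair):
        """±25% k2' mis-set: our DVR equals the brute-force refit's DVR."""
        target, ref = typical_pair
        tt, rt = make_pair(plasma, schedule, target, ref)
        for fac in (0.75, 1.25):
            fit = fit_srtm2(tt, rt, k2prime=ref.k2 * fac)
            # oracle: dense fine grid without refinement
            fine = fit_srtm2(tt, rt, k2prime=ref.k2 * fac,
                             k2a_grid=np.geomspace(0.006, 0.6, 4096), refine=False)
            assert fit.DVR == pytest.approx(fine.DVR, rel=2e-3)


class TestEstimateK2Prime:
    def _fit(self, k2prime, bpnd=1.0):
        r1 = 1.0
        k2 = r1 * k2prime
        return SRTMFit(R1=r1, k2=k2, BPND=bpnd, k2a=k2 / (1 + bpnd), rss=0.0)

    def test_single_fit_returns_its_value(self):
        assert estimate_k2prime([self._fit(0.11)]) == pytest.approx(0.11)

    def test_median_of_three(self):
        fits = [self._fit(v) for v in (0.1, 0.2, 0.3)]
        assert estimate_k2prime(fits) == pytest.approx(0.2)

    def test_threshold_fallback_when_no_high_binding(self):
        fits = [self._fit(v, bpnd=0.05) for v in (0.1, 0.2, 0.3)]
        assert estimate_k2prime(fits, bpnd_threshold=0.5) == pytest.approx(0.2)

    def test_cohort_recovery_noiseless(self, plasma, schedule):
        ref = OneTissueParams(0.3, 0.12)
        rt = frame_average(tissue_curve(ref, plasma), schedule)
        fits = []
        for vt in (4.0, 5.0, 6.0):
            tt = frame_average(tissue_curve(OneTissueParams(0.3, 0.3 / vt), plasma), schedule)
            fits.append(fit_srtm(tt, rt))
        assert estimate_k2prime(fits) == pytest.approx(0.12, rel=1e-2)

    def test_empty_and_fixed_strategies(self):
        with pytest.raises(KineticsError):
            estimate_k2prime([])
        assert estimate_k2prime([], strategy="fixed", fixed_value=0.027) == 0.027
        with pytest.raises(KineticsError):
            estimate_k2prime([], strategy="fixed")
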