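"""Simplified reference tissue models (SRTM, SRTM2).

SRTM expresses a target-region curve through the reference-region curve,

    C_T(t) = R1·C_R(t) + R1·(k2' − k2a)·∫_0^t C_R(s)·e^(−k2a·(t−s)) ds,

with R1 = K1_target/K1_ref, k2' the reference efflux, and k2a the apparent
target efflux; BPND = R1·k2'/k2a − 1 and DVR = BPND + 1. When target and
reference are both one-tissue regions sharing a plasma input the equation
is exact with k2a equal to the target efflux. SRTM2 fixes k2' (one fewer
parameter), as used for DVR quantification over a 0–60 min window with a
whole-cerebellum reference.

Fitting is by basis functions: for each k2a on a log-spaced grid the model
is linear in the remaining coefficients, solved by weighted least squares;
the grid minimum is then polished by a bounded 1-D search.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

from .kinetics import (
    ExpSum,
    FitFailure,
    KineticsError,
    TimeActivityCurve,
    decay_duration_weights,
)

__all__ = [
    "SRTMFit",
    "SRTM2Fit",
    "default_k2a_grid",
    "exp_conv_sampled",
    "srtm_predict",
    "fit_srtm",
    "fit_srtm2",
    "estimate_k2prime",
]

DEFAULT_FIT_WINDOW = (0.0, 60.0)


@dataclass(frozen=True)
class SRTMFit:
    """Three-parameter SRTM estimate for one target/reference pair."""

    R1: float
    k2: float
    BPND: float
    k2a: float
    rss: float
    region: str = ""
    converged: bool = True

    @property
    def k2prime(self) -> float:
        return self.k2 / self.R1

    @property
    def DVR(self) -> float:
        return self.BPND + 1.0


@dataclass(frozen=True)
class SRTM2Fit:
    """Two-parameter SRTM2 estimate with the reference efflux k2' fixed."""

    R1: float
    k2a: float
    k2prime: float
    BPND: float
    window: tuple[float, float]
    rss: float
    region: str = ""
    converged: bool = True

    @property
    def DVR(self) -> float:
        return self.BPND + 1.0


def default_k2a_grid(lo: float = 0.006, hi: float = 0.6, n: int = 128) -> np.ndarray:
    """Log-spaced apparent-efflux grid spanning the physiological range."""
    return np.geomspace(lo, hi, n)


def exp_conv_sampled(times: np.ndarray, values: np.ndarray, rates: np.ndarray) -> np.ndarray:
    """∫_0^t C(s)·e^(−θ·(t−s)) ds for a sampled curve, at the sample times.

    The curve is treated as piecewise linear through (0, 0) and the samples;
    the segment-wise convolution is closed-form, accumulated recursively.
    Returns an array of shape (len(rates), len(times)).
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    rates = np.atleast_1d(np.asarray(rates, dtype=float))
    if np.any(rates <= 0):
        raise KineticsError("convolution rates must be positive")
    t = np.concatenate([[0.0], times])
    c = np.concatenate([[0.0], values])
    out = np.zeros((len(rates), len(times)))
    F = np.zeros(len(rates))
    for j in range(len(times)):
        dt = t[j + 1] - t[j]
        slope = (c[j + 1] - c[j]) / dt
        E = np.exp(-rates * dt)
        g1 = (1.0 - E) / rates            # ∫_0^dt e^{−θ(dt−u)} du
        g2 = (dt - g1) / rates            # ∫_0^dt u·e^{−θ(dt−u)} du
        F = F * E + c[j] * g1 + slope * g2
        out[:, j] = F
    return out


def _reference_samples(ref, times: np.ndarray | None):
    """Return (times, C_R(times), conv-provider) for TAC or continuous refs."""
    if isinstance(ref, TimeActivityCurve):
        t = ref.schedule.midpoints if times is None else np.asarray(times, dtype=float)
        if times is None:
            cr = ref.values
        else:
            cr = np.interp(t, ref.schedule.midpoints, ref.values, left=0.0)
        base_t = ref.schedule.midpoints
        base_c = ref.values

        def conv(rates):
            full = exp_conv_sampled(base_t, base_c, rates)
            if times is None:
                return full
            out = np.empty((full.shape[0], len(t)))
            for i in range(full.shape[0]):
                out[i] = np.interp(t, base_t, full[i], left=0.0)
            return out

        return t, cr, conv
    if isinstance(ref, ExpSum):
        if times is None:
            raise KineticsError("explicit times required for a continuous reference")
        t = np.asarray(times, dtype=float)
        cr = np.asarray(ref(t))

        def conv(rates):
            rates = np.atleast_1d(rates)
            return np.stack([np.asarray(ref.convolve_exp(r)(t)) for r in rates])

        return t, cr, conv
    raise KineticsError(f"unsupported reference curve type: {type(ref)!r}")


def srtm_predict(ref, R1: float, k2a: float, k2prime: float,
                 times: np.ndarray | None = None) -> np.ndarray:
    """Evaluate the SRTM operational equation for given parameters.

    `ref` may be a TimeActivityCurve (piecewise-linear interpolation; `times`
    defaults to its frame midpoints) or a continuous ExpSum curve (exact
    convolution; `times` required).
    """
    if R1 <= 0 or k2a <= 0 or k2prime <= 0:
        raise KineticsError("R1, k2a, k2prime must all be positive")
    t, cr, conv = _reference_samples(ref, times)
    conv_vals = conv(np.array([k2a]))[0]
    return R1 * cr + R1 * (k2prime - k2a) * conv_vals


def _window_mask(schedule, window: tuple[float, float]) -> np.ndarray:
    lo, hi = float(window[0]), float(window[1])
    if not (0.0 <= lo < hi):
        raise KineticsError(f"invalid fit window {window}")
    return (schedule.starts >= lo - 1e-9) & (schedule.ends <= hi + 1e-9)


def _prepare_pair(target: TimeActivityCurve, ref: TimeActivityCurve,
                  window, weights):
    if target.schedule != ref.schedule:
        raise KineticsError("target and reference must share a frame schedule")
    mask = _window_mask(target.schedule, window)
    if mask.sum() < 3:
        raise KineticsError(f"fit window {window} covers fewer than 3 frames")
    if weights is None:
        weights = target.weights if target.weights is not None \
            else decay_duration_weights(target.schedule)
    w = np.asarray(weights, dtype=float)[mask]
    t_mid = target.schedule.midpoints
    y = target.values[mask]
    return mask, t_mid, y, w


def fit_srtm(target: TimeActivityCurve, ref: TimeActivityCurve,
             window: tuple[float, float] = DEFAULT_FIT_WINDOW,
             k2a_grid: np.ndarray | None = None,
             weights: np.ndarray | None = None,
             refine: bool = True) -> SRTMFit | FitFailure:
    """Basis-function SRTM fit of a target TAC against a reference TAC.

    For each k2a the model is linear in (θ1, θ2) with
    C_T = θ1·C_R + θ2·(C_R ⊗ e^(−k2a·t)); the weighted-RSS-minimizing basis
    wins (ties to the smallest k2a), then R1 = θ1, k2 = θ2 + θ1·k2a,
    BPND = k2/k2a − 1, k2' = k2/R1.
    """
    if k2a_grid is None:
        k2a_grid = default_k2a_grid()
    mask, t_mid, y, w = _prepare_pair(target, ref, window, weights)
    cr_full = ref.values
    conv_all = exp_conv_sampled(t_mid, cr_full, k2a_grid)[:, mask]
    cr = cr_full[mask]

    def solve_for(conv_vals):
        X = np.column_stack([cr, conv_vals])
        Xw = X * w[:, None]
        yw = y * w
        theta, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
        resid = yw - Xw @ theta
        return theta, float(resid @ resid)

    rss = np.empty(len(k2a_grid))
    thetas = np.empty((len(k2a_grid), 2))
    for i in range(len(k2a_grid)):
        thetas[i], rss[i] = solve_for(conv_all[i])
    if not np.any(np.isfinite(rss)):
        return FitFailure("all SRTM basis solves failed", region=target.region)
    best = int(np.nanargmin(rss))
    k2a_best, theta_best, rss_best = k2a_grid[best], thetas[best], rss[best]

    if refine:
        lo = k2a_grid[max(best - 1, 0)]
        hi = k2a_grid[min(best + 1, len(k2a_grid) - 1)]
        if hi > lo:
            def objective(k2a):
                conv_vals = exp_conv_sampled(t_mid, cr_full, np.array([k2a]))[0, mask]
                return solve_for(conv_vals)[1]
            res = minimize_scalar(objective, bounds=(lo, hi), method="bounded",
                                  options={"xatol": 1e-7})
            if res.success and res.fun <= rss_best:
                k2a_best = float(res.x)
                conv_vals = exp_conv_sampled(t_mid, cr_full, np.array([k2a_best]))[0, mask]
                theta_best, rss_best = solve_for(conv_vals)

    R1 = float(theta_best[0])
    k2 = float(theta_best[1] + theta_best[0] * k2a_best)
    if R1 <= 0 or k2 <= 0:
        return FitFailure(f"non-physical SRTM solution R1={R1:.4g}, k2={k2:.4g}",
                          region=target.region,
                          details={"k2a": float(k2a_best)})
    return SRTMFit(R1=R1, k2=k2, BPND=k2 / k2a_best - 1.0, k2a=float(k2a_best),
                   rss=rss_best, region=target.region)


def fit_srtm2(target: TimeActivityCurve, ref: TimeActivityCurve,
              k2prime: float,
              window: tuple[float, float] = DEFAULT_FIT_WINDOW,
              k2a_grid: np.ndarray | None = None,
              weights: np.ndarray | None = None,
              refine: bool = True) -> SRTM2Fit | FitFailure:
    """SRTM2 basis fit with fixed reference efflux k2'.

    With k2' fixed, each basis curve b(t) = C_R + (k2' − k2a)·(C_R ⊗ e^(−k2a·t))
    leaves a single linear coefficient R1; BPND = R1·k2'/k2a − 1 and
    DVR = BPND + 1. Default window 0–60 min. Negative BPND is reported
    as-is (never clipped) so downstream statistics stay unbiased.
    """
    if k2prime <= 0:
        raise KineticsError(f"k2prime must be positive, got {k2prime}")
    if k2a_grid is None:
        k2a_grid = default_k2a_grid()
    mask, t_mid, y, w = _prepare_pair(target, ref, window, weights)
    cr_full = ref.values
    conv_all = exp_conv_sampled(t_mid, cr_full, k2a_grid)[:, mask]
    cr = cr_full[mask]
    w2 = w * w

    def solve_for(k2a, conv_vals):
        b = cr + (k2prime - k2a) * conv_vals
        denom = float(w2 @ (b * b))
        if denom <= 0:
            return np.nan, np.inf
        r1 = float(w2 @ (b * y)) / denom
        resid = np.sqrt(w2) * (y - r1 * b)
        return r1, float(resid @ resid)

    rss = np.empty(len(k2a_grid))
    r1s = np.empty(len(k2a_grid))
    for i, k2a in enumerate(k2a_grid):
        r1s[i], rss[i] = solve_for(k2a, conv_all[i])
    if not np.any(np.isfinite(rss)):
        return FitFailure("all SRTM2 basis solves failed", region=target.region)
    best = int(np.nanargmin(rss))
    k2a_best, r1_best, rss_best = float(k2a_grid[best]), r1s[best], rss[best]

    if refine:
        lo = k2a_grid[max(best - 1, 0)]
        hi = k2a_grid[min(best + 1, len(k2a_grid) - 1)]
        if hi > lo:
            def objective(k2a):
                conv_vals = exp_conv_sampled(t_mid, cr_full, np.array([k2a]))[0, mask]
                return solve_for(k2a, conv_vals)[1]
            res = minimize_scalar(objective, bounds=(lo, hi), method="bounded",
                                  options={"xatol": 1e-7})
            if res.success and res.fun <= rss_best:
                k2a_best = float(res.x)
                conv_vals = exp_conv_sampled(t_mid, cr_full, np.array([k2a_best]))[0, mask]
                r1_best, rss_best = solve_for(k2a_best, conv_vals)

    if not np.isfinite(r1_best) or r1_best <= 0:
        return FitFailure(f"non-physical SRTM2 solution R1={r1_best:.4g}",
                          region=target.region, details={"k2a": k2a_best})
    bpnd = r1_best * k2prime / k2a_best - 1.0
    return SRTM2Fit(R1=float(r1_best), k2a=k2a_best, k2prime=float(k2prime),
                    BPND=float(bpnd), window=(float(window[0]), float(window[1])),
                    rss=rss_best, region=target.region)


def estimate_k2prime(fits, strategy: str = "median",
                     bpnd_threshold: float = 0.5,
                     fixed_value: float | None = None) -> float:
    """Population reference-efflux estimate from first-pass SRTM fits.

    "median": median k2' over converged fits with BPND above the threshold
    (fits with appreciable specific binding constrain k2' best); when no fit
    clears the threshold — the norm for tracers with near-unity DVR — the
    median over all converged fits is used. "fixed": return `fixed_value`.
    """
    if strategy == "fixed":
        if fixed_value is None or fixed_value <= 0:
            raise KineticsError("fixed k2prime strategy requires a positive value")
        return float(fixed_value)
    if strategy != "median":
        raise KineticsError(f"unknown k2prime strategy: {strategy!r}")
    good = [f for f in fits if isinstance(f, SRTMFit) and f.converged]
    if not good:
        raise KineticsError("no successful SRTM fits to estimate k2prime from")
    high = [f.k2prime for f in good if f.BPND > bpnd_threshold]
    pool = high if high else [f.k2prime for f in good]
    return float(np.median(pool))
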