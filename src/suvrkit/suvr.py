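"""Windowed standardized uptake value ratios (SUVR).

SUVR over a scan window is the duration-weighted mean target activity
divided by the duration-weighted mean reference activity across the frames
in the window — equivalent, up to a constant that cancels in the ratio, to
summing the frames. The nine standard windows are the 20- and 30-min
windows between 30 and 90 min post-injection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .kinetics import FrameSchedule, KineticsError, TimeActivityCurve

__all__ = ["ScanWindow", "SUVROutcome", "standard_windows", "compute_suvr",
           "instantaneous_ratio"]


@dataclass(frozen=True)
class ScanWindow:
    """Post-injection interval [start, end] in minutes over which frames are combined."""

    start: float
    end: float

    def __post_init__(self):
        if not (0.0 <= self.start < self.end):
            raise KineticsError(f"invalid scan window ({self.start}, {self.end})")

    @property
    def label(self) -> str:
        return f"{self.start:g}-{self.end:g}"


@dataclass(frozen=True)
class SUVROutcome:
    subject: str
    region: str
    window: str
    value: float


def standard_windows() -> list[ScanWindow]:
    """The nine standard SUVR windows: 30-min then 20-min spans, 30–90 min."""
    spans = [(30, 60), (40, 70), (50, 80), (60, 90),
             (30, 50), (40, 60), (50, 70), (60, 80), (70, 90)]
    return [ScanWindow(float(a), float(b)) for a, b in spans]


def _window_frame_fractions(schedule: FrameSchedule, window: ScanWindow) -> np.ndarray:
    """Fraction of each frame's duration inside the window (prorated overlap)."""
    if window.end > schedule.total_duration + 1e-9:
        raise KineticsError(
            f"window {window.label} extends past scan end {schedule.total_duration} min")
    overlap = (np.minimum(schedule.ends, window.end)
               - np.maximum(schedule.starts, window.start))
    frac = np.clip(overlap, 0.0, None) / schedule.durations
    partial = (frac > 1e-12) & (frac < 1.0 - 1e-12)
    if np.any(partial):
        warnings.warn(
            f"scan window {window.label} does not align with frame boundaries; "
            "partial frames prorated by overlap", stacklevel=3)
    return frac


def compute_suvr(target: TimeActivityCurve, ref: TimeActivityCurve,
                 window: ScanWindow, subject: str = "") -> SUVROutcome:
    """Duration-weighted mean target/reference activity ratio over a window."""
    if target.schedule != ref.schedule:
        raise KineticsError("target and reference must share a frame schedule")
    frac = _window_frame_fractions(target.schedule, window)
    w = frac * target.schedule.durations
    if w.sum() <= 0:
        raise KineticsError(f"window {window.label} covers no frames")
    ref_mean = float(w @ ref.values) / w.sum()
    if ref_mean <= 0:
        raise KineticsError(f"non-positive reference mean in window {window.label}")
    tgt_mean = float(w @ target.values) / w.sum()
    return SUVROutcome(subject=subject, region=target.region,
                       window=window.label, value=tgt_mean / ref_mean)


def instantaneous_ratio(target, ref, times) -> np.ndarray:
    """Pointwise C_T(t)/C_R(t); NaN where the reference is zero.

    Curves may be callables/ExpSum (evaluated directly) or TACs (values
    interpolated at frame midpoints).
    """
    times = np.asarray(times, dtype=float)

    def _eval(curve):
        if isinstance(curve, TimeActivityCurve):
            return np.interp(times, curve.schedule.midpoints, curve.values)
        return np.asarray(curve(times), dtype=float)

    ct, cr = _eval(target), _eval(ref)
    out = np.full_like(ct, np.nan)
    ok = cr != 0.0
    out[ok] = ct[ok] / cr[ok]
    return out
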