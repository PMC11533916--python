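"""Group-comparison and validation statistics.

Cohen d (pooled-SD form, sign convention CN − AD), ordinary least-squares
SUVR-on-DVR regression with Pearson r and two-tailed p, identity-line bias
summaries, and the per-window effect-size table with the correlation of
window-wise d against DVR's d across regions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["EffectSize", "RegressionSummary", "StatsError", "cohen_d",
           "regress_suvr_on_dvr", "identity_bias", "effect_size_table"]


class StatsError(ValueError):
    """Degenerate statistical input (undefined result)."""


@dataclass(frozen=True)
class EffectSize:
    region: str
    outcome: str
    d: float
    mean_a: float
    mean_b: float
    sd_a: float
    sd_b: float
    n_a: int
    n_b: int


@dataclass(frozen=True)
class RegressionSummary:
    predictor: str
    response: str
    stratum: str
    slope: float
    intercept: float
    r: float
    p: float
    n: int


def cohen_d(group_a, group_b) -> float:
    """Standardized mean difference (mean_a − mean_b)/s_pooled.

    s_pooled² = ((n_a−1)s_a² + (n_b−1)s_b²)/(n_a+n_b−2), with sample
    (ddof=1) variances. No small-sample correction (this is d, not
    Hedges g). Raises StatsError when the pooled SD is zero.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise StatsError("each group needs n >= 2")
    na, nb = len(a), len(b)
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    if sp2 <= 0:
        raise StatsError("pooled SD is zero; Cohen d undefined")
    return float((a.mean() - b.mean()) / np.sqrt(sp2))


def _group_effect(values: pd.Series, groups: pd.Series, region: str, outcome: str) -> EffectSize:
    a = values[groups == "CN"].to_numpy(dtype=float)
    b = values[groups == "AD"].to_numpy(dtype=float)
    return EffectSize(region=region, outcome=outcome, d=cohen_d(a, b),
                      mean_a=float(a.mean()), mean_b=float(b.mean()),
                      sd_a=float(a.std(ddof=1)), sd_b=float(b.std(ddof=1)),
                      n_a=len(a), n_b=len(b))


def regress_suvr_on_dvr(dvr, suvr, stratum: str = "all",
                        predictor: str = "DVR", response: str = "SUVR") -> RegressionSummary:
    """OLS of SUVR on DVR with Pearson r and two-tailed p (t transform, n−2 df)."""
    x = np.asarray(dvr, dtype=float)
    y = np.asarray(suvr, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise StatsError("regression needs >= 3 paired observations")
    if np.var(x) == 0:
        raise StatsError("degenerate predictor (zero variance)")
    res = sps.linregress(x, y)
    return RegressionSummary(predictor=predictor, response=response, stratum=stratum,
                             slope=float(res.slope), intercept=float(res.intercept),
                             r=float(res.rvalue), p=float(res.pvalue), n=len(x))


def identity_bias(reg: RegressionSummary, evaluation_range: tuple[float, float]) -> dict:
    """Deviation of the fitted line from the line of identity.

    Returns slope−1, the intercept, and the mean signed deviation
    (slope−1)·x̄ + intercept of the fitted line from y = x over the
    evaluation range (x̄ its midpoint, since the deviation is linear in x).
    """
    lo, hi = float(evaluation_range[0]), float(evaluation_range[1])
    xbar = (lo + hi) / 2.0
    return {
        "slope_minus_1": reg.slope - 1.0,
        "intercept": reg.intercept,
        "mean_deviation": (reg.slope - 1.0) * xbar + reg.intercept,
    }


def effect_size_table(outcomes: pd.DataFrame, windows: list[str]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-window effect-size summary against the DVR reference outcome.

    `outcomes` must have columns subject, group (CN/AD), region, outcome
    (window labels and "DVR"), value. Returns (summary, per_region):
    summary has one row per window plus a DVR row, in the given window
    order, with the Pearson r (and p) of region-wise Cohen d against DVR's
    region-wise d, and the mean ± SD of d across regions; per_region holds
    every region × outcome Cohen d.
    """
    required = {"subject", "group", "region", "outcome", "value"}
    if not required.issubset(outcomes.columns):
        raise StatsError(f"outcomes table missing columns {sorted(required - set(outcomes.columns))}")
    labels = list(windows) + ["DVR"]
    regions_by_outcome = {
        lab: set(outcomes.loc[outcomes["outcome"] == lab, "region"]) for lab in labels
    }
    ref_regions = regions_by_outcome["DVR"]
    for lab, regs in regions_by_outcome.items():
        if regs != ref_regions:
            missing = sorted(ref_regions ^ regs)
            raise StatsError(f"region mismatch for outcome {lab!r}: {missing}")
    regions = sorted(ref_regions)

    rows = []
    for lab in labels:
        sub = outcomes[outcomes["outcome"] == lab]
        for region in regions:
            cell = sub[sub["region"] == region]
            rows.append(_group_effect(cell["value"], cell["group"], region, lab))
    per_region = pd.DataFrame([vars(e) for e in rows])

    d_wide = per_region.pivot(index="region", columns="outcome", values="d").loc[regions]
    d_ref = d_wide["DVR"].to_numpy()
    summary_rows = []
    for lab in labels:
        d_vals = d_wide[lab].to_numpy()
        if lab == "DVR":
            r = p = np.nan
        else:
            res = sps.linregress(d_ref, d_vals)
            r, p = float(res.rvalue), float(res.pvalue)
        summary_rows.append({
            "outcome": lab, "pearson_r": r, "p": p,
            "mean_d": float(d_vals.mean()), "sd_d": float(d_vals.std(ddof=1)),
            "n_regions": len(regions),
        })
    return pd.DataFrame(summary_rows), per_region
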