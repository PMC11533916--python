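"""Perfusion-confound simulation for windowed SUVR.

Rescales AD-group target-region K1 to prescribed percentage differences
below the CN mean (co-scaling k2 so each subject's VT, hence true DVR, is
unchanged), simulates all TACs from a shared plasma input, and traces the
CN-vs-AD percentage difference in SUVR and its Cohen d as a function of
scan time. Early scan times track the relative-delivery (R1) group
difference; late times approach the true DVR group difference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import REFERENCE_REGION, CohortDataset
from .kinetics import KineticsError, OneTissueParams, add_noise, frame_average, tissue_curve
from .stats import StatsError, cohen_d
from .suvr import compute_suvr, standard_windows

__all__ = ["PerfusionScenario", "SimulationResult", "DEFAULT_SCENARIOS",
           "scale_k1", "group_r1_difference", "run_perfusion_simulation"]

DEFAULT_SCENARIOS = (0.0, 10.0, 20.0, 30.0, 40.0)


@dataclass(frozen=True)
class PerfusionScenario:
    """One K1-difference setting: AD target-region delivery scaled to sit
    `k1_pct_diff` percent below the CN group mean."""

    k1_pct_diff: float
    k1_scale_factor: float
    r1_pct_diff: float


@dataclass
class SimulationResult:
    """Instantaneous (per frame midpoint) and windowed group-difference tables."""

    timepoints: pd.DataFrame   # scenario_pct, time_min, mean_suvr_cn/ad, pct_diff, cohen_d, ...
    windows: pd.DataFrame      # scenario_pct, window, mean_suvr_cn/ad, pct_diff, cohen_d, ...
    scenarios: list[PerfusionScenario]
    dvr_pct_diff: float


def scale_k1(ad_params: list[OneTissueParams], cn_mean_k1: float,
             pct_diff: float, preserve_vt: bool = True) -> list[OneTissueParams]:
    """Multiplicatively rescale AD K1 so the group mean sits pct_diff% below CN.

    Each subject's relative deviation from the AD mean is preserved. With
    preserve_vt (default), k2 is co-scaled so VT = K1/k2 — and therefore
    DVR — is untouched, isolating the perfusion confound; otherwise k2 is
    left fixed and VT drifts with K1.
    """
    if cn_mean_k1 <= 0:
        raise KineticsError(f"cn_mean_k1 must be positive, got {cn_mean_k1}")
    if not (0.0 <= pct_diff < 100.0):
        raise KineticsError(f"pct_diff must lie in [0, 100), got {pct_diff}")
    if not ad_params:
        raise KineticsError("empty AD parameter list")
    ad_mean = float(np.mean([p.K1 for p in ad_params]))
    factor = cn_mean_k1 * (1.0 - pct_diff / 100.0) / ad_mean
    return [OneTissueParams(K1=p.K1 * factor,
                            k2=p.k2 * factor if preserve_vt else p.k2)
            for p in ad_params]


def group_r1_difference(params: pd.DataFrame, target_region: str = "hippocampus") -> float:
    """Percent CN-vs-AD difference in relative delivery R1 = K1_target/K1_ref.

    Computed as 100·(mean R1_CN − mean R1_AD)/mean R1_CN from a params
    table with columns subject, group, region, K1.
    """
    wide = params.pivot_table(index=["subject", "group"], columns="region",
                              values="K1", aggfunc="first").reset_index()
    for region in (target_region, REFERENCE_REGION):
        if region not in wide.columns or wide[region].isna().any():
            raise KineticsError(f"missing {region!r} K1 for some subjects")
    r1 = wide[target_region] / wide[REFERENCE_REGION]
    m_cn = r1[wide.group == "CN"].mean()
    m_ad = r1[wide.group == "AD"].mean()
    return float(100.0 * (m_cn - m_ad) / m_cn)


def _safe_d(cn_vals: np.ndarray, ad_vals: np.ndarray) -> float:
    try:
        return cohen_d(cn_vals, ad_vals)
    except StatsError:
        return float("nan")


def run_perfusion_simulation(cohort: CohortDataset,
                             scenarios=DEFAULT_SCENARIOS,
                             target_region: str = "hippocampus",
                             noise_scale: float = 0.0,
                             seed: int = 0,
                             preserve_vt: bool = True) -> SimulationResult:
    """Trace SUVR group differences over scan time for each K1 scenario.

    For every scenario the AD target-region K1 values are rescaled against
    the CN mean, all target and reference TACs are simulated (noiseless by
    default — group differences come from the parameter spread), and at
    each late-frame midpoint the target/reference activity ratio gives the
    per-subject SUVR whose CN-vs-AD percentage difference
    100·(CN − AD)/CN and Cohen d are tabulated, alongside the constant true
    DVR percentage difference and the scenario's R1 percentage difference.
    Windowed SUVRs over the nine standard windows are emitted as well.
    """
    p = cohort.params
    tgt = p[p.region == target_region].set_index("subject")
    ref = p[p.region == REFERENCE_REGION].set_index("subject")
    if tgt.empty or ref.empty:
        raise KineticsError(f"cohort lacks {target_region!r} or {REFERENCE_REGION!r} parameters")
    subjects = cohort.subjects
    cn_ids = list(subjects[subjects.group == "CN"].subject)
    ad_ids = list(subjects[subjects.group == "AD"].subject)
    cn_mean_k1 = float(tgt.loc[cn_ids, "K1"].mean())

    schedule = cohort.schedule
    late = schedule.durations == 5.0
    times = schedule.midpoints[late]

    # true DVR % difference is scenario-invariant when VT is preserved
    dvr = tgt["VT"] / ref["VT"]
    dvr_pct = float(100.0 * (dvr.loc[cn_ids].mean() - dvr.loc[ad_ids].mean())
                    / dvr.loc[cn_ids].mean())

    noise_seeds = np.random.SeedSequence(seed).generate_state(
        len(scenarios) * len(subjects) * 2) % (2**31)

    def simulate(par: OneTissueParams, region: str, nseed: int) -> np.ndarray:
        tac = frame_average(tissue_curve(par, cohort.plasma), schedule)
        tac.region = region
        return add_noise(tac, noise_scale, nseed)

    scen_objs: list[PerfusionScenario] = []
    tp_rows, win_rows = [], []
    wins = standard_windows()
    k = 0
    for pct in scenarios:
        ad_par = [OneTissueParams(tgt.loc[s, "K1"], tgt.loc[s, "k2"]) for s in ad_ids]
        scaled = scale_k1(ad_par, cn_mean_k1, pct, preserve_vt=preserve_vt)
        factor = scaled[0].K1 / ad_par[0].K1

        scen_params = pd.concat([
            pd.DataFrame({"subject": cn_ids + ad_ids, "group": ["CN"] * len(cn_ids) + ["AD"] * len(ad_ids),
                          "region": target_region,
                          "K1": [tgt.loc[s, "K1"] for s in cn_ids] + [q.K1 for q in scaled]}),
            p[p.region == REFERENCE_REGION][["subject", "group", "region", "K1"]],
        ], ignore_index=True)
        r1_pct = group_r1_difference(scen_params, target_region)
        scen_objs.append(PerfusionScenario(k1_pct_diff=float(pct),
                                           k1_scale_factor=float(factor),
                                           r1_pct_diff=r1_pct))

        ratios = {}
        suvr_by_win = {w.label: {} for w in wins}
        param_of = dict(zip(ad_ids, scaled))
        for subj in cn_ids + ad_ids:
            tp = param_of.get(subj) or OneTissueParams(tgt.loc[subj, "K1"], tgt.loc[subj, "k2"])
            rp = OneTissueParams(ref.loc[subj, "K1"], ref.loc[subj, "k2"])
            t_tac = simulate(tp, target_region, int(noise_seeds[k])); k += 1
            r_tac = simulate(rp, REFERENCE_REGION, int(noise_seeds[k])); k += 1
            ratios[subj] = t_tac.values[late] / r_tac.values[late]
            for w in wins:
                suvr_by_win[w.label][subj] = compute_suvr(t_tac, r_tac, w, subject=subj).value

        cn_mat = np.array([ratios[s] for s in cn_ids])
        ad_mat = np.array([ratios[s] for s in ad_ids])
        for j, t in enumerate(times):
            m_cn, m_ad = cn_mat[:, j].mean(), ad_mat[:, j].mean()
            tp_rows.append({"scenario_pct": float(pct), "time_min": float(t),
                            "mean_suvr_cn": m_cn, "mean_suvr_ad": m_ad,
                            "pct_diff": 100.0 * (m_cn - m_ad) / m_cn,
                            "cohen_d": _safe_d(cn_mat[:, j], ad_mat[:, j]),
                            "dvr_pct_diff": dvr_pct, "r1_pct_diff": r1_pct})
        for w in wins:
            vals = suvr_by_win[w.label]
            cn_v = np.array([vals[s] for s in cn_ids])
            ad_v = np.array([vals[s] for s in ad_ids])
            win_rows.append({"scenario_pct": float(pct), "window": w.label,
                             "mean_suvr_cn": cn_v.mean(), "mean_suvr_ad": ad_v.mean(),
                             "pct_diff": 100.0 * (cn_v.mean() - ad_v.mean()) / cn_v.mean(),
                             "cohen_d": _safe_d(cn_v, ad_v),
                             "dvr_pct_diff": dvr_pct, "r1_pct_diff": r1_pct})

    return SimulationResult(timepoints=pd.DataFrame(tp_rows),
                            windows=pd.DataFrame(win_rows),
                            scenarios=scen_objs, dvr_pct_diff=dvr_pct)
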