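"""Synthetic two-group PET cohorts with one-tissue kinetics.

Generates cognitively-normal (CN) and Alzheimer-disease (AD) groups with
per-subject, per-region 1TC parameters drawn lognormally around group
means, AD means reduced fractionally in both density (VT) and perfusion
(K1), and frame-averaged TACs simulated on the 27-frame 90-min schedule
with an optional count-statistics noise model. The default parameter
table is synthetic: chosen to mimic an SV2A-like tracer quantified
against a whole-cerebellum reference (regional DVR near one, perfusion
reductions in AD somewhat larger than density reductions), not taken
from any measured cohort.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .kinetics import (
    FrameSchedule,
    KineticsError,
    OneTissueParams,
    PlasmaInput,
    TimeActivityCurve,
    add_noise,
    default_frame_schedule,
    frame_average,
    tissue_curve,
)

__all__ = ["RegionKinetics", "CohortConfig", "CohortDataset", "REFERENCE_REGION",
           "default_region_table", "generate_cohort", "write_cohort", "read_cohort",
           "write_tac_tsv", "read_tac_tsv"]

REFERENCE_REGION = "whole cerebellum"


@dataclass(frozen=True)
class RegionKinetics:
    """Group-level kinetic settings for one region.

    k1_cn / vt_cn: CN group means; vt_reduction / k1_reduction: fractional
    AD reductions in [0, 1) applied to the group mean.
    """

    k1_cn: float
    vt_cn: float
    vt_reduction: float = 0.0
    k1_reduction: float = 0.0


def default_region_table() -> dict[str, RegionKinetics]:
    """Synthetic defaults for eight cortical/limbic targets plus the reference.

    VT means sit near the whole-cerebellum value (DVR ≈ 0.8–1.1). AD
    density (VT) reductions are moderate (5–12%); perfusion (K1)
    reductions are larger than density reductions in lateral/posterior
    cortex (consistent with group differences in perfusion/metabolism
    generally exceeding those in synaptic density) but smaller than
    density reductions medial-temporally, where synaptic loss leads. A
    tiny cerebellar perfusion reduction makes relative-delivery (R1)
    group differences differ from raw K1 differences.
    """
    return {
        "hippocampus": RegionKinetics(0.28, 11.0, 0.10, 0.06),
        "entorhinal cortex": RegionKinetics(0.26, 12.5, 0.12, 0.10),
        "lateral temporal cortex": RegionKinetics(0.30, 14.5, 0.10, 0.15),
        "prefrontal cortex": RegionKinetics(0.31, 14.0, 0.08, 0.12),
        "posterior cingulate/precuneus": RegionKinetics(0.33, 15.0, 0.09, 0.15),
        "lateral parietal cortex": RegionKinetics(0.31, 14.0, 0.08, 0.13),
        "lateral occipital cortex": RegionKinetics(0.32, 13.5, 0.06, 0.10),
        "medial occipital cortex": RegionKinetics(0.33, 13.0, 0.05, 0.08),
        REFERENCE_REGION: RegionKinetics(0.32, 14.0, 0.00, 0.01),
    }


@dataclass(frozen=True)
class CohortConfig:
    n_cn: int = 16
    n_ad: int = 31
    regions: dict[str, RegionKinetics] = field(default_factory=default_region_table)
    # between-subject lognormal spread, split into a whole-brain delivery
    # factor (cancels in DVR), regional delivery residuals, and efflux spread
    cv_delivery_global: float = 0.10
    cv_delivery_regional: float = 0.09
    cv_efflux: float = 0.05
    noise_scale: float = 0.02
    seed: int = 0
    plasma: PlasmaInput = field(default_factory=PlasmaInput)

    def validate(self) -> None:
        problems = []
        if self.n_cn < 2 or self.n_ad < 2:
            problems.append(f"group sizes must be >= 2 (got CN={self.n_cn}, AD={self.n_ad})")
        if REFERENCE_REGION not in self.regions:
            problems.append(f"region table must include {REFERENCE_REGION!r}")
        for name, rk in self.regions.items():
            if rk.k1_cn <= 0 or rk.vt_cn <= 0:
                problems.append(f"{name}: K1 and VT means must be > 0")
            if not (0.0 <= rk.vt_reduction < 1.0) or not (0.0 <= rk.k1_reduction < 1.0):
                problems.append(f"{name}: reductions must lie in [0, 1)")
        for attr in ("cv_delivery_global", "cv_delivery_regional", "cv_efflux"):
            if getattr(self, attr) < 0:
                problems.append(f"{attr} must be >= 0")
        if self.noise_scale < 0:
            problems.append("noise_scale must be >= 0")
        if problems:
            raise KineticsError("invalid cohort config: " + "; ".join(problems))

    def to_dict(self) -> dict:
        return {
            "n_cn": self.n_cn,
            "n_ad": self.n_ad,
            "cv_delivery_global": self.cv_delivery_global,
            "cv_delivery_regional": self.cv_delivery_regional,
            "cv_efflux": self.cv_efflux,
            "noise_scale": self.noise_scale,
            "seed": self.seed,
            "plasma": {k: getattr(self.plasma, k)
                       for k in ("model", "delay", "a1", "lam1", "a2", "lam2", "a3", "lam3")},
            "regions": {name: {"k1_cn": rk.k1_cn, "vt_cn": rk.vt_cn,
                               "vt_reduction": rk.vt_reduction,
                               "k1_reduction": rk.k1_reduction}
                        for name, rk in self.regions.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        plasma = d.get("plasma", {})
        return cls(
            n_cn=int(d["n_cn"]), n_ad=int(d["n_ad"]),
            regions={name: RegionKinetics(**rk) for name, rk in d["regions"].items()},
            cv_delivery_global=float(d["cv_delivery_global"]),
            cv_delivery_regional=float(d["cv_delivery_regional"]),
            cv_efflux=float(d["cv_efflux"]),
            noise_scale=float(d["noise_scale"]),
            seed=int(d["seed"]),
            plasma=PlasmaInput(**plasma) if plasma else PlasmaInput(),
        )

    def hash(self) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha256(text.encode()).hexdigest()[:16]


@dataclass
class CohortDataset:
    """Per-subject, per-region true parameters and TACs; the pipeline's unit."""

    subjects: pd.DataFrame          # columns: subject, group
    params: pd.DataFrame            # columns: subject, group, region, K1, k2, VT, DVR_true
    tacs: dict[str, pd.DataFrame]   # subject -> frame x region activity table
    schedule: FrameSchedule
    plasma: PlasmaInput
    config: CohortConfig
    seed: int

    def tac(self, subject: str, region: str) -> TimeActivityCurve:
        return TimeActivityCurve(schedule=self.schedule,
                                 values=self.tacs[subject][region].to_numpy(),
                                 region=region)

    def true_params(self, subject: str, region: str) -> OneTissueParams:
        row = self.params[(self.params.subject == subject) & (self.params.region == region)]
        if row.empty:
            raise KineticsError(f"no parameters for {subject}/{region}")
        return OneTissueParams(float(row.K1.iloc[0]), float(row.k2.iloc[0]))

    @property
    def regions(self) -> list[str]:
        return list(self.config.regions)

    def validate(self) -> None:
        have = set(map(tuple, self.params[["subject", "region"]].to_numpy()))
        for s in self.subjects.subject:
            if (s, REFERENCE_REGION) not in have:
                raise KineticsError(f"subject {s} lacks a {REFERENCE_REGION!r} entry")
            if s not in self.tacs:
                raise KineticsError(f"subject {s} lacks TACs")


def _lognormal_mean_cv(rng: np.random.Generator, mean: float, cv: float) -> float:
    if cv == 0.0:
        return mean
    sigma2 = np.log1p(cv * cv)
    mu = np.log(mean) - sigma2 / 2.0
    return float(rng.lognormal(mu, np.sqrt(sigma2)))


def generate_cohort(config: CohortConfig) -> CohortDataset:
    """Draw a cohort and simulate every TAC; bit-reproducible per seed.

    Per subject a whole-brain delivery factor (lognormal, mean 1) scales
    K1 in every region, emulating global blood-flow differences; regional
    K1 residuals and the efflux time 1/k2 are drawn lognormally per
    region so the between-subject *means* of K1 and VT = K1/k2 equal the
    configured group means (AD means = CN means × (1 − reduction)). The
    global delivery factor cancels in DVR, so DVR dispersion comes from
    the regional and efflux spreads only — mirroring the tighter
    between-subject spread of ratio outcomes relative to VT itself.
    Noise sub-seeds are derived per subject × region from the master seed.
    """
    config.validate()
    schedule = default_frame_schedule()
    root = np.random.SeedSequence(config.seed)
    draw_ss, noise_ss = root.spawn(2)
    rng = np.random.default_rng(draw_ss)

    subjects = ([(f"cn{i+1:03d}", "CN") for i in range(config.n_cn)]
                + [(f"ad{i+1:03d}", "AD") for i in range(config.n_ad)])
    noise_seeds = noise_ss.generate_state(len(subjects) * len(config.regions)) % (2**31)

    rows = []
    tacs: dict[str, pd.DataFrame] = {}
    k = 0
    for subj, group in subjects:
        cols = {"frame_start": schedule.starts, "frame_end": schedule.ends}
        global_delivery = _lognormal_mean_cv(rng, 1.0, config.cv_delivery_global)
        for region, rk in config.regions.items():
            red_vt = rk.vt_reduction if group == "AD" else 0.0
            red_k1 = rk.k1_reduction if group == "AD" else 0.0
            k1_mean = rk.k1_cn * (1 - red_k1)
            vt_mean = rk.vt_cn * (1 - red_vt)
            k1 = global_delivery * _lognormal_mean_cv(rng, k1_mean,
                                                      config.cv_delivery_regional)
            # efflux time τ = 1/k2 drawn so E[VT] = E[K1·τ] = vt_mean·E[global];
            # the global factor acts like a free-fraction effect, scaling K1
            # and VT together while leaving k2 = 1/τ untouched
            tau = _lognormal_mean_cv(rng, vt_mean / k1_mean, config.cv_efflux)
            vt = k1 * tau
            params = OneTissueParams(K1=k1, k2=1.0 / tau)
            tac = frame_average(tissue_curve(params, config.plasma), schedule)
            tac = add_noise(tac, config.noise_scale, int(noise_seeds[k]))
            k += 1
            cols[region] = tac.values
            rows.append({"subject": subj, "group": group, "region": region,
                         "K1": k1, "k2": params.k2, "VT": vt})
        tacs[subj] = pd.DataFrame(cols)

    params = pd.DataFrame(rows)
    vt_ref = params[params.region == REFERENCE_REGION].set_index("subject")["VT"]
    params["DVR_true"] = params["VT"].to_numpy() / vt_ref.loc[params["subject"]].to_numpy()

    ds = CohortDataset(
        subjects=pd.DataFrame(subjects, columns=["subject", "group"]),
        params=params, tacs=tacs, schedule=schedule,
        plasma=config.plasma, config=config, seed=config.seed,
    )
    ds.validate()
    return ds


# ---------------------------------------------------------------------------
# On-disk layout: manifest.yaml + config.yaml + params.tsv + tacs/<subject>.tsv
# ---------------------------------------------------------------------------


def write_tac_tsv(path: Path, tac_table: pd.DataFrame) -> None:
    """TAC TSV dialect: frame_start, frame_end, then one column per region."""
    tac_table.to_csv(path, sep="\t", index=False)


def read_tac_tsv(path: Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if list(df.columns[:2]) != ["frame_start", "frame_end"]:
        raise KineticsError(f"{path}: TAC TSV must start with frame_start, frame_end")
    return df


def write_cohort(dataset: CohortDataset, directory) -> None:
    directory = Path(directory)
    (directory / "tacs").mkdir(parents=True, exist_ok=True)
    cfg = dataset.config
    with open(directory / "config.yaml", "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True)
    with open(directory / "manifest.yaml", "w") as fh:
        yaml.safe_dump({"seed": dataset.seed, "config_hash": cfg.hash(),
                        "n_subjects": len(dataset.subjects),
                        "regions": list(cfg.regions)}, fh, sort_keys=True)
    dataset.params.to_csv(directory / "params.tsv", sep="\t", index=False)
    for subj, table in dataset.tacs.items():
        write_tac_tsv(directory / "tacs" / f"{subj}.tsv", table)


def read_cohort(directory) -> CohortDataset:
    directory = Path(directory)
    manifest_path = directory / "manifest.yaml"
    if not manifest_path.exists():
        raise KineticsError(f"cohort load error: missing manifest {manifest_path}")
    with open(manifest_path) as fh:
        manifest = yaml.safe_load(fh)
    with open(directory / "config.yaml") as fh:
        config = CohortConfig.from_dict(yaml.safe_load(fh))
    if manifest.get("config_hash") != config.hash():
        raise KineticsError(f"cohort load error: manifest hash mismatch in {manifest_path}")
    params = pd.read_csv(directory / "params.tsv", sep="\t")
    subjects = params[["subject", "group"]].drop_duplicates().reset_index(drop=True)
    tacs = {}
    schedule = None
    for subj in subjects.subject:
        table = read_tac_tsv(directory / "tacs" / f"{subj}.tsv")
        missing = [r for r in config.regions if r not in table.columns]
        if missing:
            raise KineticsError(f"{subj}: TAC file missing region columns {missing}")
        if schedule is None:
            schedule = FrameSchedule(list(zip(table.frame_start, table.frame_end)))
        tacs[subj] = table
    ds = CohortDataset(subjects=subjects, params=params, tacs=tacs,
                       schedule=schedule, plasma=config.plasma,
                       config=config, seed=int(manifest["seed"]))
    ds.validate()
    return ds
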