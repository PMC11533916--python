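import numpy as np
import pytest

from suvrkit import (
    CohortConfig,
    OneTissueParams,
    PipelineConfig,
    default_frame_schedule,
    default_plasma_input,
    generate_cohort,
)
from suvrkit.pipeline import run_full_validation


@pytest.fixture(scope="session")
def plasma():
    return default_plasma_input()


@pytest.fixture(scope="session")
def schedule():
    return default_frame_schedule()


@pytest.fixture(scope="session")
def typical_pair():
    """A representative target/reference 1TC parameter pair (DVR ~ 0.79)."""
    return OneTissueParams(0.28, 0.28 / 11.0), OneTissueParams(0.32, 0.32 / 14.0)


def small_cohort_config(seed: int = 0, **overrides) -> CohortConfig:
    """A reduced cohort (2 regions, 4+5 subjects) for fast pipeline tests."""
    full = CohortConfig().to_dict()
    regions = {name: full["regions"][name]
               for name in ("hippocampus", "lateral temporal cortex", "whole cerebellum")}
    d = {**full, "n_cn": 4, "n_ad": 5, "regions": regions, "seed": seed, **overrides}
    return CohortConfig.from_dict(d)


@pytest.fixture(scope="session")
def small_cohort():
    return generate_cohort(small_cohort_config(seed=7))


@pytest.fixture(scope="session")
def default_validation_run():
    """One full pipeline run on the default synthetic cohort (seed 1).

    Session-scoped because the run takes several seconds and several
    statistical checks share it.
    """
    return run_full_validation(PipelineConfig(seed=1))


def brute_force_1tc(params: OneTissueParams, plasma, t: float, dt: float = 0.001) -> float:
    """Independent discrete-convolution oracle for the 1TC tissue curve."""
    grid = np.arange(0.0, t + dt, dt)
    cp = np.asarray(plasma.as_expsum()(grid))
    return params.K1 * float(np.trapezoid(cp * np.exp(-params.k2 * (t - grid)), grid))
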