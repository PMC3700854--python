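import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import ildcox as ic
from ildcox.simulate import Baseline, CSpec, SimConfig, simulate_cohort

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[
        HealthCheck.too_slow,
        HealthCheck.function_scoped_fixture,
    ],
)
settings.load_profile("ci")


@pytest.fixture
def three_subject_intervals() -> pd.DataFrame:
    """The classic hand-checkable fixture: events at t=1 (z=1) and t=2 (z=0),
    one censored subject (z=1) at t=3.  Risk sets have sizes 3 then 2 and the
    MLE solves 1 = 2u/(2u+1) + u/(u+1), i.e. beta = -log(2)/2."""
    return pd.DataFrame(
        {
            "id": ["A", "B", "C"],
            "transition": ["13"] * 3,
            "start": [0.0, 0.0, 0.0],
            "stop": [1.0, 2.0, 3.0],
            "status": [1, 1, 0],
            "z": [1.0, 0.0, 1.0],
        }
    )


@pytest.fixture
def small_cohort() -> ic.SubjectTable:
    """Six hand-built subjects covering all illness-death paths."""
    df = pd.DataFrame(
        {
            "id": [1, 2, 3, 4, 5, 6],
            "entry": 0.0,
            "d": [2.0, np.nan, 1.0, np.nan, 0.5, np.nan],
            "dd_time": np.nan,
            "time": [5.0, 3.0, 4.0, 2.5, 1.5, 6.0],
            "status": [1, 0, 1, 1, 0, 1],
            "z": [1.0, 0.0, 1.0, 0.0, 1.0, 0.0],
        }
    )
    return ic.SubjectTable(df)


@pytest.fixture(scope="session")
def exp_decay_cohort() -> tuple:
    """One medium cohort generated under the exponential-decay relation
    c = exp(1.0 - 0.3 d + 1.5 exp(-(t-d))) with prognostic covariates."""
    cfg = SimConfig(
        n=1500,
        seed=42,
        c_spec=CSpec("exp_decay", b0=1.0, b1=-0.3, b2=1.5),
        gamma12=(0.2, 0.0),
        gamma13=(0.4, -0.3),
        gamma23=(0.4, -0.3),
    )
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def null_cohort() -> tuple:
    """Shared constant baselines, c = 1: the intermediate event changes
    nothing about the absorbing-event hazard."""
    cfg = SimConfig(
        n=3000,
        seed=7,
        baseline12=Baseline("constant", rate=0.06),
        baseline13=Baseline("constant", rate=0.08),
        baseline23=Baseline("constant", rate=0.08),
        c_spec=CSpec("none"),
    )
    return simulate_cohort(cfg)
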