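import numpy as np
import pandas as pd
import pytest

from aactask import Condition, SubjectParams, generate_session
from aactask.cohort import CohortConfig, simulate_cohort
from aactask.fitting import ModelSpec


@pytest.fixture(scope="session")
def default_params():
    return SubjectParams()


@pytest.fixture(scope="session")
def small_session():
    """One seeded session at a single repetition: 72 trials, 36 per condition."""
    return generate_session(n_reps=1, seed=11)


@pytest.fixture(scope="session")
def apav_cohort():
    """Small simulated Ap/Av cohort (loss-aversion + exploration-bonus agents)."""
    spec = ModelSpec(Condition.APAV, ("f", "w"))
    config = CohortConfig(
        spec=spec,
        group={"f": (-9.0, 1.5), "w": (1.0, 0.5), "beta": (np.log(2.0), 0.3)},
        n_subjects=4,
        n_reps=4,
        seed=7,
    )
    cohort, truths = simulate_cohort(config)
    return cohort, truths, config
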