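import numpy as np
import pandas as pd
import pytest

from touchbandit import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A small synthetic cohort shared across tests (4 mice/sex, 2 x 300)."""
    return generate_cohort(
        CohortConfig(n_per_sex=4, n_sessions=2), seed=11
    )


@pytest.fixture(scope="session")
def labeled_trials(small_cohort) -> pd.DataFrame:
    """Cohort trials carrying the generator's ground-truth state labels."""
    df = small_cohort.trials.copy()
    df["state"] = df["true_state"]
    df["state_side"] = df["true_state_side"]
    return df


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
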