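import warnings

import numpy as np
import pandas as pd
import pytest

from recoverlab import SimConfig, simulate_controls, simulate_patients
from recoverlab.atlas import JHU_ICBM_DTI_81

COLS96 = JHU_ICBM_DTI_81.metric_columns()


@pytest.fixture(scope="session")
def small_config():
    return SimConfig(n_patients=250, n_controls=120, n_scanners=3, seed=11)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    """One moderate synthetic cohort shared across tests (read-only)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cohort, tracts = simulate_patients(small_config)
    return cohort, tracts


@pytest.fixture(scope="session")
def small_controls(small_config):
    return simulate_controls(small_config)


@pytest.fixture(scope="session")
def complete_merged(small_cohort):
    """Complete-case cohort merged with its tract columns."""
    cohort, tracts = small_cohort
    merged = cohort.dropna(subset=["outcome"]).merge(
        tracts[["subject_id"] + COLS96], on="subject_id")
    # fill remaining clinical NaNs by column medians/modes for tests that
    # need complete data without exercising the imputation module
    for c in merged.columns:
        if merged[c].isna().any():
            if merged[c].dtype == object:
                merged[c] = merged[c].fillna(merged[c].mode()[0])
            else:
                merged[c] = merged[c].fillna(merged[c].median())
    return merged.reset_index(drop=True)


def noise_frame(n, p, n_events, seed, prefix="t"):
    """Outcome-independent predictor table used by null-model tests."""
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, p))
    y = np.zeros(n)
    y[:n_events] = 1
    rng.shuffle(y)
    df = pd.DataFrame(X, columns=[f"{prefix}{j}" for j in range(p)])
    df["outcome"] = y
    return df
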