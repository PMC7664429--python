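import numpy as np
import pandas as pd
import pytest

from edaffect.features import FeatureMatrix
from edaffect.io import DEFAULT_POSITIVE_ITEMS, polarity_from_positive_items
from edaffect.synthetic import SynthConfig, simulate_cohort


@pytest.fixture(scope="session")
def polarity():
    return polarity_from_positive_items(DEFAULT_POSITIVE_ITEMS)


@pytest.fixture(scope="session")
def cohort():
    """One default 41-participant synthetic cohort, shared across tests."""
    return simulate_cohort(SynthConfig(seed=7))


@pytest.fixture(scope="session")
def small_cohort():
    return simulate_cohort(SynthConfig(n_participants=8, seed=3))


def make_matrix(values, ids=None, columns=None, exercise_id=1):
    values = np.asarray(values, dtype=float)
    if ids is None:
        ids = [f"P{i + 1:03d}" for i in range(values.shape[0])]
    if columns is None:
        columns = [f"f{j + 1}" for j in range(values.shape[1])]
    df = pd.DataFrame(values, index=pd.Index(ids, name="participant_id"),
                      columns=columns)
    return FeatureMatrix(df, exercise_id=exercise_id)


@pytest.fixture
def two_cloud_matrix():
    rng = np.random.default_rng(0)
    a = rng.normal(0.0, 0.1, size=(5, 3))
    b = rng.normal(10.0, 0.1, size=(5, 3))
    return make_matrix(np.vstack([a, b]))
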