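import matplotlib

matplotlib.use("Agg")

import pandas as pd
import pytest

from tugpcm.features import build_feature_table
from tugpcm.synthetic import default_profiles, make_cohort, simulate_trial


@pytest.fixture(scope="session")
def profiles():
    return default_profiles()


@pytest.fixture(scope="session")
def nd_trial():
    """One ND trial with its ground truth (seed fixed)."""
    nd, _ = default_profiles()
    return simulate_trial(nd, seed=11)


@pytest.fixture(scope="session")
def small_cohort():
    """A 35/25 cohort, the study's group sizes."""
    return make_cohort(35, 25, seed=7)


@pytest.fixture(scope="session")
def feature_table(small_cohort):
    return build_feature_table(small_cohort)


@pytest.fixture(scope="session")
def group_labels(feature_table):
    return pd.Series(feature_table.attrs["group_labels"], name="group")
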