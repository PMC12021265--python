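import numpy as np
import pytest

import nifcast as nc
from nifcast.synthetic import SyntheticConfig, generate_strains


@pytest.fixture(scope="session")
def small_cohort():
    """40 synthetic strains with the default planted effects."""
    return generate_strains(SyntheticConfig(n_strains=40, seed=11))


@pytest.fixture(scope="session")
def small_features(small_cohort):
    records, _ = small_cohort
    return nc.build_feature_table(records)


@pytest.fixture(scope="session")
def small_labels(small_cohort):
    records, _ = small_cohort
    return nc.make_labels(records)


@pytest.fixture(scope="session")
def small_plan(small_labels):
    plan = nc.stratified_split(small_labels, seed=3)
    plan.folds = nc.make_cv_folds(plan.train_ids, small_labels, k=5, seed=3)
    return plan


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
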