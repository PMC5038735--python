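import numpy as np
import pytest

from mtjl.synthetic import SyntheticConfig, generate_cohort, impute_missing


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort (74 x 42 x 19) with its ground truth."""
    return generate_cohort(SyntheticConfig(seed=7))


@pytest.fixture(scope="session")
def imputed_cohort(default_cohort):
    data, truth = default_cohort
    return impute_missing(data, "train_mean"), truth


@pytest.fixture(scope="session")
def small_cohort():
    """A small, fast cohort for pipeline-level tests."""
    cfg = SyntheticConfig(n_participants=20, n_trials=5, seed=11)
    return generate_cohort(cfg)
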