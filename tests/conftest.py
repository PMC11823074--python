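import numpy as np
import pytest

from hemadr.synth_cohort import CohortConfig, build_default_panel, sample_cohort


@pytest.fixture(scope="session")
def panel():
    return build_default_panel()


@pytest.fixture(scope="session")
def small_cohort(panel):
    """2,000-sample default cohort, generated once per session."""
    return sample_cohort(panel, CohortConfig(n_samples=2_000, seed=7))


@pytest.fixture(scope="session")
def clean_cohort(panel):
    """Cohort without missingness or CLL injection, for oracle comparisons."""
    cfg = CohortConfig(n_samples=2_000, seed=11, cll_fraction=0.0,
                       missing_fraction_pre_cutoff=0.0)
    return sample_cohort(panel, cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
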