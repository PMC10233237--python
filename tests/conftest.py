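import numpy as np
import pytest

from eigenbrains import synthetic_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Fast cohort for unit tests: 16^3-ish grid, 3 factors, 12 patients."""
    return synthetic_cohort.make_cohort(
        shape=(16, 18, 16),
        k_true=3,
        n_per_cluster=(5, 4, 3),
        n_controls=8,
        smoothness_sigma=1.0,
        missing_rate=0.0,
        seed=7,
    )


@pytest.fixture(scope="session")
def default_cohort():
    """The full-size default cohort (52 patients / 52 controls)."""
    return synthetic_cohort.make_cohort(seed=11, missing_rate=0.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
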