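import numpy as np
import pandas as pd
import pytest

from csfsubtypes import synthetic


@pytest.fixture(scope="session")
def default_cohort():
    return synthetic.generate_cohort(synthetic.CohortConfig(seed=1))


@pytest.fixture(scope="session")
def small_cohort():
    return synthetic.generate_cohort(
        synthetic.CohortConfig(n_subjects=60, n_proteins=80, seed=2)
    )


@pytest.fixture(scope="session")
def clean_cohort():
    """Noise-free cohort with hard subtype membership."""
    return synthetic.generate_cohort(
        synthetic.CohortConfig(
            n_subjects=45,
            n_proteins=60,
            noise_sd=0.0,
            fragment_noise_sd=0.0,
            mixing_concentration=np.inf,
            seed=3,
        )
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def labelled_subjects():
    return pd.Series([1] * 17, index=[f"S{i:03d}" for i in range(17)], name="subtype")
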