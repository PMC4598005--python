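import warnings

import numpy as np
import pandas as pd
import pytest

from readmit_rsf.synthetic_ehr import GeneratorConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A 500-patient cohort shared by read-only tests."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return generate_cohort(GeneratorConfig(n_patients=500, seed=7))


@pytest.fixture(scope="session")
def small_features(small_cohort):
    from readmit_rsf.cohort import aggregate_features
    patients, encounters, index = small_cohort
    return aggregate_features(patients, encounters, index)


@pytest.fixture()
def toy_survival():
    """Small random right-censored sample for forest unit tests."""
    rng = np.random.default_rng(11)
    n = 60
    X = rng.standard_normal((n, 4))
    lp = 0.8 * X[:, 0]
    p = 1.0 / (1.0 + np.exp(-(np.log(0.05 / 0.95) + lp)))
    t = rng.geometric(p).astype(float)
    e = (t <= 30).astype(int)
    t = np.minimum(t, 30)
    return t, e, X
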