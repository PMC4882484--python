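import numpy as np
import pytest

import boubakit as bk
from boubakit import reference as ref


@pytest.fixture(scope="session")
def default_design():
    return bk.StimulusDesign()


@pytest.fixture(scope="session")
def us_trials_small():
    """30 simulated US participants, full 72-condition design."""
    return bk.simulate_group(ref.US_MODEL, 30, seed=101, group="US")


@pytest.fixture(scope="session")
def two_group_trials_small():
    """Small two-group table (24 US + 16 TW) for ladder fits."""
    return bk.simulate_two_groups(ref.TWO_GROUP_MODEL, None, 24, 16, seed=202)


@pytest.fixture(scope="session")
def us_fit_small(us_trials_small):
    return bk.fit_logistic_mixed(us_trials_small, "base")


@pytest.fixture(scope="session")
def tiny_mixed_data():
    """5 subjects x 10 trials with known parameters, for likelihood oracles."""
    rng = np.random.default_rng(3)
    S, T = 5, 10
    X = np.column_stack([np.ones(S * T), rng.normal(size=S * T)])
    subj = np.repeat(np.arange(S), T)
    beta = np.array([-0.5, 0.8])
    sigma = 1.2
    from scipy.special import expit

    b = rng.normal(0, sigma, S)
    y = (rng.random(S * T) < expit(X @ beta + b[subj])).astype(float)
    return X, y, subj, beta, sigma
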