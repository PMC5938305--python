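import warnings

import numpy as np
import pytest

import gambrct as g

warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="session")
def truth():
    return g.default_twopart_truth()


@pytest.fixture(scope="session")
def small_model_data(truth):
    """One exact-model dataset at trial scale (18 subjects, 14 weeks)."""
    weekly, design, info = g.generate_from_model(truth, g.TrialShape(18, 14), seed=42)
    return weekly, design, info


@pytest.fixture(scope="session")
def small_fit(small_model_data):
    """A short-chain fit shared across tests that only need *a* posterior."""
    weekly, design, _ = small_model_data
    return g.fit_twopart(weekly, design, config=g.McmcConfig().reduced(), seed=7)


@pytest.fixture(scope="session")
def behavioral_trial():
    return g.generate_trial(g.TrialConfig(n_pairs=18, seed=3))
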