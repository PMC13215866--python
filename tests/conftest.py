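import numpy as np
import pytest

from vepkit import synthetic


@pytest.fixture(scope="session")
def small_survey():
    """500-household synthetic survey, shared across read-only tests."""
    cfg = synthetic.default_config(n_households=500, seed=42)
    return synthetic.generate_survey(cfg)


@pytest.fixture(scope="session")
def medium_survey():
    """5,000-household survey for estimation tests."""
    cfg = synthetic.default_config(n_households=5000, seed=7)
    return synthetic.generate_survey(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(123)
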