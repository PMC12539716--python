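import numpy as np
import pytest

from depsim.config import default_config
from depsim.engine import build_panel
from depsim.synthetic import synthetic_truth_config


@pytest.fixture(scope="session")
def cfg():
    """Shipped default configuration (Bernoulli event mode)."""
    return default_config()


@pytest.fixture(scope="session")
def truth_cfg():
    """Synthetic France-like ground-truth configuration (threshold mode)."""
    return synthetic_truth_config()


@pytest.fixture(scope="session")
def small_truth_cfg():
    return synthetic_truth_config(n_per_cohort=200)


@pytest.fixture(scope="session")
def small_panel(small_truth_cfg):
    return build_panel(small_truth_cfg, 1234)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
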