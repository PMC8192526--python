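import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import cytoscreen as cs

settings.register_profile(
    "ci", derandomize=True, max_examples=40,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def taxonomy():
    return cs.default_taxonomy()


@pytest.fixture(scope="session")
def schema():
    return cs.default_schema()


@pytest.fixture(scope="session")
def small_corpus():
    """120-slide stratified synthetic corpus (fixed seed)."""
    return cs.make_corpus(120, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
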