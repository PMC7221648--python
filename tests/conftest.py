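import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "dxsum", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("dxsum")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def short_corpus():
    """Small pool of short labeled records for fast training tests."""
    from dxsum.synthetic import GeneratorParams, generate_corpus

    params = GeneratorParams(seed=7, min_items=1, max_items=1)
    return generate_corpus(40, 10, params)


@pytest.fixture(scope="session")
def short_labeled(short_corpus):
    return [r for r in short_corpus if r.label is not None]
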