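import numpy as np
import pytest

import corefucid as cf


@pytest.fixture(scope="session")
def small_benchmark():
    """A modest seeded benchmark reused by model-level tests."""
    return cf.make_benchmark(800, 800, cf_weight=0.3, seed=11)


@pytest.fixture(scope="session")
def trained_ae(small_benchmark):
    P = cf.feature_matrix(small_benchmark.tagged)
    return cf.train_ae(P, k=0.4, config=cf.AEConfig(seed=11))


@pytest.fixture(scope="session")
def trained_mc(small_benchmark):
    P = cf.feature_matrix(small_benchmark.tagged)
    U = cf.feature_matrix(small_benchmark.untagged)
    return cf.train_mc(P, U, cf.MCConfig(seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
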