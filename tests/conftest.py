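import numpy as np
import pytest

from ctiqa.corpus import (
    MixtureConfig,
    build_source_corpus,
    build_target_corpus,
    generate_pristine,
)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def phantom64():
    return generate_pristine("target", 1, 64, seed=7)[0]


@pytest.fixture(scope="session")
def texture64():
    return generate_pristine("source", 1, 64, seed=7)[0]


@pytest.fixture(scope="session")
def small_source_corpus():
    # 2 pristine x 3 types x 2 levels = 12 records, deterministic
    return build_source_corpus(2, 3, 2, size=64, seed=11, jitter_sd=0.0)


@pytest.fixture(scope="session")
def small_target_corpus():
    return build_target_corpus(48, 64, seed=11, mixture=MixtureConfig(jitter_sd=0.0))
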