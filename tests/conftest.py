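import numpy as np
import pytest

from seqdedup.features import compute_feature_table
from seqdedup.synth import SynthConfig, generate_corpus, generate_separable_set


@pytest.fixture(scope="session")
def small_corpus():
    """A mixed corpus covering all five pair classes."""
    config = SynthConfig(
        seed=11, n_pairs={"ES": 8, "EF": 8, "NS": 8, "DI": 8, "DI_hard": 8}
    )
    return generate_corpus(config)


@pytest.fixture(scope="session")
def small_features(small_corpus):
    return compute_feature_table(small_corpus.pairs)


@pytest.fixture(scope="session")
def separable_features():
    """Feature table of a cleanly separable 300-pair corpus."""
    pairs = generate_separable_set(300, seed=3)
    return compute_feature_table(pairs)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
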