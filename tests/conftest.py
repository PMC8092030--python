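"""Shared fixtures: a small synthetic corpus reused across module tests."""

import pytest

from emovista.preprocess import preprocess_corpus
from emovista.synth import (build_default_vocabulary, default_scenarios,
                            generate_corpus)


@pytest.fixture(scope="session")
def vocab():
    return build_default_vocabulary(seed=1)


@pytest.fixture(scope="session")
def small_corpus(vocab):
    """~1200 organic posts over the four phases, with a few bot accounts."""
    posts, truth = generate_corpus(
        vocab, default_scenarios(300), n_users=120, bot_fraction=0.03, seed=1)
    return posts, truth


@pytest.fixture(scope="session")
def small_clean(small_corpus):
    posts, _truth = small_corpus
    clean, removed = preprocess_corpus(posts)
    return clean, removed
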