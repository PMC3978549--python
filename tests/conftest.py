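import numpy as np
import pytest

from strokestories import CorpusConfig, generate_corpus, load_fixture_tables


@pytest.fixture(scope="session")
def fixture_tables():
    return load_fixture_tables()


@pytest.fixture(scope="session")
def small_corpus():
    """A small mixed corpus with planted stroke stories (seeded)."""
    cfg = CorpusConfig(n_stroke_stories=60, n_other_stories=120,
                       n_nonstory_posts=120, seed=11)
    return generate_corpus(cfg)


@pytest.fixture(scope="session")
def benchmark_corpus():
    """The standard 2000-post benchmark corpus (200 stroke stories)."""
    return generate_corpus(CorpusConfig(seed=42))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
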