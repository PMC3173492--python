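import pytest

from litnav.fixtures import load_agr2_fixture
from litnav.synthetic_corpus import GeneratorParams, generate


@pytest.fixture(scope="session")
def agr2():
    return load_agr2_fixture()


@pytest.fixture(scope="session")
def bundle():
    """Default-condition synthetic bundle, shared across read-only tests."""
    return generate(GeneratorParams(seed=42))


@pytest.fixture(scope="session")
def small_bundle():
    """A small bundle for fast end-to-end runs."""
    return generate(
        GeneratorParams(
            n_papers=12,
            n_topics=3,
            vocab_size=120,
            title_vocab_size=600,
            citations_per_paper_range=(5, 7),
            seed=7,
        )
    )
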