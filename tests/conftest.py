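import pytest

from chemnorm.bioc import Document, Mention, Passage, Span
from chemnorm.fixtures import FixtureConfig, generate_collection, generate_lexicon
from chemnorm.mtcr import LexiconBundle


@pytest.fixture
def tiny_doc() -> Document:
    """One-passage document with a single identified chemical mention."""
    return Document(
        doc_id="t1",
        passages=[Passage(offset=0, text="TPP was added to the cells.",
                          section_label="abstract")],
        mentions=[
            Mention(spans=[Span(0, 3)], text="TPP", identifiers={"MESH:D1"})
        ],
        metadata={"journal": "J Test"},
    )


@pytest.fixture(scope="session")
def fixture_config() -> FixtureConfig:
    return FixtureConfig(seed=7, n_docs=20, n_concepts=24)


@pytest.fixture(scope="session")
def fixture_lexicon(fixture_config):
    return generate_lexicon(fixture_config)


@pytest.fixture(scope="session")
def fixture_collection(fixture_config):
    return generate_collection(fixture_config)


@pytest.fixture(scope="session")
def fixture_bundle(fixture_lexicon) -> LexiconBundle:
    mesh, aux = fixture_lexicon
    return LexiconBundle(mesh, aux)
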