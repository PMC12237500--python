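import pytest

from litrex import (
    Document,
    Entity,
    EntityMention,
    FixtureConfig,
    HashedBowEncoder,
    generate_fixture_suite,
)
from litrex.templates import default_schema


@pytest.fixture(scope="session")
def cdr_schema():
    return default_schema("cdr")


@pytest.fixture(scope="session")
def suite():
    """The standard study-condition suite: 20 docs, 60 pairs, prevalence 0.5."""
    return generate_fixture_suite(FixtureConfig(), seed=7)


@pytest.fixture(scope="session")
def small_suite():
    return generate_fixture_suite(FixtureConfig(n_docs=4), seed=11)


@pytest.fixture(scope="session")
def encoder():
    return HashedBowEncoder()


def make_document(n_chem=1, n_dis=1, positives=(), doc_id="d1"):
    """A minimal document with chem/dis entities named c0.., d0..."""
    passages = []
    entities = []
    for i in range(n_chem):
        name = f"c{i}"
        passage = f"Treatment with {name} was given."
        passages.append(passage)
        start = passage.index(name)
        entities.append(
            Entity(name, "Chemical", (EntityMention(name, start, start + len(name), len(passages) - 1),))
        )
    for i in range(n_dis):
        name = f"d{i}"
        passage = f"Cases of {name} were noted."
        passages.append(passage)
        start = passage.index(name)
        entities.append(
            Entity(name, "Disease", (EntityMention(name, start, start + len(name), len(passages) - 1),))
        )
    gold = frozenset((h, t, "1:CID:2") for h, t in positives)
    return Document(doc_id=doc_id, title="T.", passages=tuple(passages), entities=tuple(entities), gold_labels=gold)


@pytest.fixture
def doc_2x3():
    return make_document(n_chem=2, n_dis=3, positives=[("c0", "d0")])
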