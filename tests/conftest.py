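import pytest

from ontomatch import GeneratorSpec, NormalizerConfig, Ontology, generate_pair


@pytest.fixture(scope="session")
def cfg() -> NormalizerConfig:
    return NormalizerConfig()


@pytest.fixture()
def chain() -> Ontology:
    """root -> mid -> leaf."""
    o = Ontology()
    o.add_isa("http://x#root", "http://x#mid")
    o.add_isa("http://x#mid", "http://x#leaf")
    for c in ("root", "mid", "leaf"):
        o.add_label(f"http://x#{c}", c, "en")
    return o


@pytest.fixture(scope="session")
def identity_pair():
    """A perturbation-free generated pair: the copy equals the source."""
    return generate_pair(
        GeneratorSpec(
            seed=11, n_concepts=60, p_permute=0, p_synonym=0, p_opaque=0, p_unmatched=0
        )
    )


def make_ontology(edges, labels=None, ns="http://t#") -> Ontology:
    """Tiny taxonomy builder: edges as (parent, child) local names."""
    o = Ontology()
    for parent, child in edges:
        o.add_isa(ns + parent, ns + child)
    for name, text in (labels or {}).items():
        o.add_concept(ns + name)
        o.add_label(ns + name, text, "en")
    for c in set(o.concepts):
        if c not in o.labels:
            o.add_label(c, c.rsplit("#", 1)[1].replace("_", " "), "en")
    return o
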