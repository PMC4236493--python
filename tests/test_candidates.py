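"""Lexical, property, extended and synonym candidate generation."""

import pytest

from ontomatch import (
    GeneratorSpec,
    LexicalConfig,
    NormalizerConfig,
    Ontology,
    build_m_exact,
    extended_search,
    generate_pair,
    index_ontology,
    lexical_similarity,
    match_properties,
    synonym_bridge,
    two_way_search,
)
from ontomatch.candidates import canonical_labels, load_lexicon

CFG = NormalizerConfig()
LEX = LexicalConfig()
NS1, NS2 = "http://a#", "http://b#"


def _onto(ns: str, labels: dict[str, str]) -> Ontology:
    o = Ontology()
    for name, text in labels.items():
        o.add_concept(ns + name)
        o.add_label(ns + name, text, "en")
    return o


def _indexes(o1, o2):
    return index_ontology(o1, CFG), index_ontology(o2, CFG)


def test_shared_unique_label_survives_intersection():
    o1 = _onto(NS1, {"h": "heart", "x": "liver"})
    o2 = _onto(NS2, {"h2": "heart", "y": "kidney"})
    i1, i2 = _indexes(o1, o2)
    pairs = two_way_search(o1, o2, i1, i2, CFG, LEX)
    assert (NS1 + "h", NS2 + "h2") in pairs
    assert all(p[0] != NS1 + "x" for p in pairs)


def test_label_on_one_side_only_gives_no_pair():
    o1 = _onto(NS1, {"x": "spleen"})
    o2 = _onto(NS2, {"y": "cornea"})
    i1, i2 = _indexes(o1, o2)
    assert two_way_search(o1, o2, i1, i2, CFG, LEX) == {}


def test_pair_below_best_k_in_reverse_direction_excluded():
    """A pair retrieved forward but ranked below Best-k backward is
    dropped by the strict intersection (verified by exhaustive search)."""
    lex = LexicalConfig(best_k=1)
    # o2's "q" matches o1's "t" exactly; o1 also has near-duplicates that
    # outrank "deep vein" for the reverse query of o2's "v".
    o1 = _onto(
        NS1,
        {"t": "deep vein", "d1": "deep vein thrombosis"},
    )
    o2 = _onto(NS2, {"q": "deep vein thrombosis", "v": "deep vein"})
    i1, i2 = _indexes(o1, o2)
    pairs = two_way_search(o1, o2, i1, i2, CFG, lex)
    # exhaustive check: each surviving pair is rank-1 in both directions
    for (e1, e2) in pairs:
        from ontomatch.documents import build_virtual_document

        q12 = build_virtual_document(o1, e1, CFG)
        q21 = build_virtual_document(o2, e2, CFG)
        top12 = [h.entity_id for h in i2.search(q12, k=1)]
        top21 = [h.entity_id for h in i1.search(q21, k=1)]
        assert e2 in top12 and e1 in top21


def test_direction_symmetry():
    pair = generate_pair(GeneratorSpec(seed=9, n_concepts=40))
    i1, i2 = _indexes(pair.o1, pair.o2)
    fwd = two_way_search(pair.o1, pair.o2, i1, i2, CFG, LEX)
    # swap inputs: unordered pairs must be identical
    rev = two_way_search(pair.o2, pair.o1, i2, i1, CFG, LEX)
    assert set(fwd) == {(b, a) for (a, b) in rev}


def test_theta_threshold_semantics():
    o1 = _onto(NS1, {"a": "heart"})
    o2 = _onto(NS2, {"b": "heart"})
    pairs = {(NS1 + "a", NS2 + "b"): 1.0}
    kept = build_m_exact(pairs, o1, o2, CFG, LexicalConfig(theta=1.0))
    assert len(kept) == 1 and next(iter(kept)).score == 1.0
    # a pair strictly below theta is dropped
    o2b = _onto(NS2, {"b": "hearty"})
    sim = lexical_similarity(
        canonical_labels(o1, NS1 + "a", CFG), canonical_labels(o2b, NS2 + "b", CFG)
    )
    kept = build_m_exact(
        {(NS1 + "a", NS2 + "b"): 1.0}, o1, o2b, CFG,
        LexicalConfig(theta=min(sim + 1e-6, 1.0)),
    )
    assert kept == set()


def test_m_exact_against_exhaustive_simlex_oracle():
    pair = generate_pair(GeneratorSpec(seed=13, n_concepts=30, p_permute=0.5))
    i1, i2 = _indexes(pair.o1, pair.o2)
    pairs = two_way_search(pair.o1, pair.o2, i1, i2, CFG, LEX)
    kept = {t.pair for t in build_m_exact(pairs, pair.o1, pair.o2, CFG, LEX)}
    expected = {
        p
        for p in pairs
        if lexical_similarity(
            canonical_labels(pair.o1, p[0], CFG),
            canonical_labels(pair.o2, p[1], CFG),
        )
        >= LEX.theta
    }
    assert kept == expected


def test_property_matching_respects_kind():
    o1, o2 = Ontology(), Ontology()
    for o, ns in ((o1, NS1), (o2, NS2)):
        o.add_concept(ns + "c")
        o.add_label(ns + "c", "cell", "en")
    # same name, different kinds -> never paired
    o1.object_properties.add(NS1 + "has_part")
    o1.add_label(NS1 + "has_part", "has part", "en")
    o2.datatype_properties.add(NS2 + "has_part")
    o2.add_label(NS2 + "has_part", "has part", "en")
    # same name, same kind -> paired
    o1.datatype_properties.add(NS1 + "code")
    o1.add_label(NS1 + "code", "code", "en")
    o2.datatype_properties.add(NS2 + "code")
    o2.add_label(NS2 + "code", "code", "en")
    i1, i2 = _indexes(o1, o2)
    m_prop = match_properties(o1, o2, i1, i2, CFG, LEX)
    assert {t.pair for t in m_prop} == {(NS1 + "code", NS2 + "code")}


def test_extended_search_uses_ancestor_text():
    o1, o2 = Ontology(), Ontology()
    # equal labels at the parents; children share only ancestor-derived text
    o1.add_isa(NS1 + "p", NS1 + "c")
    o2.add_isa(NS2 + "p", NS2 + "c")
    for o, ns in ((o1, NS1), (o2, NS2)):
        o.add_label(ns + "p", "cardiac muscle", "en")
    o1.add_label(NS1 + "c", "left portion cardiac muscle", "en")
    o2.add_label(NS2 + "c", "cardiac muscle left portion", "en")
    m_ext = extended_search(
        {NS1 + "c"}, {NS2 + "c"}, o1, o2, CFG, LexicalConfig(theta=0.7)
    )
    assert {t.pair for t in m_ext} == {(NS1 + "c", NS2 + "c")}
    assert all(t.provenance == "extended" for t in m_ext)


def test_synonym_bridge_whole_phrase():
    o1 = _onto(NS1, {"mi": "heart attack"})
    o2 = _onto(NS2, {"mi": "myocardial infarction"})
    lexicon = {"heart attack": {"myocardial infarction"}}
    out = synonym_bridge({NS1 + "mi"}, {NS2 + "mi"}, o1, o2, lexicon, CFG, LEX)
    assert {t.pair for t in out} == {(NS1 + "mi", NS2 + "mi")}
    t = next(iter(out))
    assert t.score >= LEX.theta_syn and t.provenance == "extended"


def test_synonym_bridge_no_overlap_and_no_chain():
    o1 = _onto(NS1, {"a": "alpha"})
    o2 = _onto(NS2, {"c": "gamma"})
    # chain alpha->beta, beta->gamma exists, but only one hop is allowed
    lexicon = {"alpha": {"beta"}, "beta": {"gamma"}}
    out = synonym_bridge({NS1 + "a"}, {NS2 + "c"}, o1, o2, lexicon, CFG, LEX)
    assert out == set()
    # and a missing lexicon skips the stage quietly
    assert synonym_bridge({NS1 + "a"}, {NS2 + "c"}, o1, o2, None, CFG, LEX) == set()


def test_lexicon_round_trip(tmp_path):
    path = tmp_path / "lex.tsv"
    path.write_text("heart attack\tmyocardial infarction\n")
    lex = load_lexicon(str(path))
    assert lex["heart attack"] == {"myocardial infarction"}
    assert lex["myocardial infarction"] == {"heart attack"}  # symmetric


def test_permutation_robustness_recall():
    """When every target label is a word permutation of its source label,
    the exact stage alone recovers the full reference."""
    pair = generate_pair(
        GeneratorSpec(seed=17, n_concepts=60, p_permute=1.0, p_synonym=0,
                      p_opaque=0, p_unmatched=0)
    )
    i1, i2 = _indexes(pair.o1, pair.o2)
    pairs = two_way_search(pair.o1, pair.o2, i1, i2, CFG, LEX)
    m_exact = {t.pair for t in build_m_exact(pairs, pair.o1, pair.o2, CFG, LEX)}
    concept_ref = {p for p in pair.reference if p[0] in pair.o1.concepts}
    assert concept_ref <= m_exact
    assert m_exact <= pair.reference | concept_ref
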