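"""Consistency filters, enrichment, greedy selection and evaluation."""

import pytest

from ontomatch import (
    LexicalConfig,
    MappingTriple,
    NormalizerConfig,
    Ontology,
    crisscross_filter,
    disjointness_filter,
    enrich,
    evaluate,
    greedy_select,
)
from ontomatch.postprocess import ONE_TO_MANY, AlignmentSet

CFG = NormalizerConfig()
NS1, NS2 = "http://a#", "http://b#"


def _t(e1, e2, score=1.0, prov="extended"):
    return MappingTriple(NS1 + e1, NS2 + e2, score, prov)


# ------------------------------------------------------------- selection


def test_greedy_select_one_to_one():
    cands = {
        MappingTriple("a", "x", 0.9, "exact"),
        MappingTriple("a", "y", 0.8, "exact"),
        MappingTriple("b", "y", 0.7, "exact"),
    }
    final = {(t.e1, t.e2) for t in greedy_select(cands)}
    assert final == {("a", "x"), ("b", "y")}
    assert greedy_select(set()) == set()
    assert len(greedy_select(cands, mode=ONE_TO_MANY)) == 3


def test_greedy_select_tie_breaks_prefer_exact():
    cands = {
        MappingTriple("a", "x", 0.9, "context"),
        MappingTriple("a", "y", 0.9, "exact"),
    }
    final = greedy_select(cands)
    assert {(t.e1, t.e2) for t in final} == {("a", "y")}


def test_one_to_one_endpoint_uniqueness():
    cands = {MappingTriple(f"e{i}", f"f{i % 3}", 0.5 + i / 100, "exact") for i in range(9)}
    final = greedy_select(cands)
    used1 = [t.e1 for t in final]
    used2 = [t.e2 for t in final]
    assert len(used1) == len(set(used1)) and len(used2) == len(set(used2))


# ------------------------------------------------------------- filters


def _disjoint_fixture():
    o1, o2 = Ontology(), Ontology()
    for name in ("c1", "c2"):
        o1.add_concept(NS1 + name)
    o1.add_disjoint(NS1 + "c1", NS1 + "c2")
    o2.add_concept(NS2 + "c3")
    return o1, o2


def test_disjointness_filter_removes_conflict():
    o1, o2 = _disjoint_fixture()
    m_exact = {_t("c1", "c3", prov="exact")}
    candidate = _t("c2", "c3")
    kept = disjointness_filter(m_exact | {candidate}, m_exact, o1, o2)
    assert candidate not in kept and m_exact <= kept


def test_disjointness_filter_needs_anchor():
    o1, o2 = _disjoint_fixture()
    candidate = _t("c2", "c3")
    # disjoint pair exists, but no anchored partner -> unchanged
    kept = disjointness_filter({candidate}, set(), o1, o2)
    assert kept == {candidate}
    # no disjointness axioms -> unchanged
    o1b = Ontology()
    o1b.add_concept(NS1 + "c1")
    o1b.add_concept(NS1 + "c2")
    m_exact = {_t("c1", "c3", prov="exact")}
    kept = disjointness_filter(m_exact | {candidate}, m_exact, o1b, o2)
    assert candidate in kept


def _crisscross_fixture():
    o1, o2 = Ontology(), Ontology()
    o1.add_isa(NS1 + "c1", NS1 + "child1")
    o1.add_isa(NS1 + "gp1", NS1 + "c1")
    o2.add_isa(NS2 + "c2", NS2 + "child2")
    o2.add_isa(NS2 + "gp2", NS2 + "c2")
    return o1, o2


def test_crisscross_filter_rules():
    o1, o2 = _crisscross_fixture()
    m_exact = {_t("c1", "c2", prov="exact")}
    up = _t("c1", "gp2")        # c1 with ancestor of c2: removed
    down = _t("child1", "c2")   # descendant of c1 with c2: removed
    parallel = _t("child1", "child2")  # parallel: kept
    kept = crisscross_filter(m_exact | {up, down, parallel}, m_exact, o1, o2)
    assert up not in kept and down not in kept
    assert parallel in kept and m_exact <= kept


def test_crisscross_uses_transitive_closure():
    o1, o2 = _crisscross_fixture()
    # two levels up on the target side
    o2.add_isa(NS2 + "ggp2", NS2 + "gp2")
    m_exact = {_t("c1", "c2", prov="exact")}
    deep = _t("c1", "ggp2")
    kept = crisscross_filter(m_exact | {deep}, m_exact, o1, o2)
    assert deep not in kept


def test_filters_only_remove():
    o1, o2 = _crisscross_fixture()
    m_exact = {_t("c1", "c2", prov="exact")}
    cands = m_exact | {_t("c1", "gp2"), _t("child1", "child2")}
    for filt in (disjointness_filter, crisscross_filter):
        out = filt(cands, m_exact, o1, o2)
        assert out <= cands


# ------------------------------------------------------------- enrichment


def test_enrich_child_pairs():
    o1, o2 = Ontology(), Ontology()
    o1.add_isa(NS1 + "p", NS1 + "k")
    o2.add_isa(NS2 + "p", NS2 + "k")
    o1.add_label(NS1 + "k", "left lobe", "en")
    o2.add_label(NS2 + "k", "left lobe", "en")
    mapped = {_t("p", "p", prov="exact")}
    added = enrich(mapped, o1, o2, CFG, LexicalConfig())
    assert {t.pair for t in added} == {(NS1 + "k", NS2 + "k")}
    t = next(iter(added))
    assert t.score == 1.0 and dict(t.component_scores).get("enriched")
    # lexically unrelated children are not added
    o2.labels[NS2 + "k"] = {("cornea", "en")}
    assert enrich(mapped, o1, o2, CFG, LexicalConfig()) == set()


def test_enrich_competing_children_resolved_by_selection():
    o1, o2 = Ontology(), Ontology()
    o1.add_isa(NS1 + "p", NS1 + "k1")
    o1.add_isa(NS1 + "p", NS1 + "k2")
    o2.add_isa(NS2 + "p", NS2 + "k")
    o1.add_label(NS1 + "k1", "left lobe", "en")
    o1.add_label(NS1 + "k2", "left lobe upper", "en")
    o2.add_label(NS2 + "k", "left lobe", "en")
    mapped = {_t("p", "p", prov="exact")}
    added = enrich(mapped, o1, o2, CFG, LexicalConfig())
    final = greedy_select(mapped | added)
    # only the best-scoring child pair survives one-to-one selection
    winners = {t.pair for t in final if t.e1.startswith(NS1 + "k")}
    assert winners == {(NS1 + "k1", NS2 + "k")}


# ------------------------------------------------------------- evaluation


def test_evaluate_hand_computed():
    ref = {(f"a{i}", f"b{i}") for i in range(10)}
    returned = {(f"a{i}", f"b{i}") for i in range(6)} | {("x1", "y1"), ("x2", "y2")}
    rep = evaluate(returned, ref)
    assert rep.precision == pytest.approx(0.75)
    assert rep.recall == pytest.approx(0.6)
    assert rep.f_measure == pytest.approx(2 / 3)
    assert (rep.n_returned, rep.n_reference, rep.n_correct) == (8, 10, 6)


def test_evaluate_boundaries():
    ten = {(f"a{i}", f"b{i}") for i in range(10)}
    perfect = evaluate(ten, ten)
    assert (perfect.precision, perfect.recall, perfect.f_measure) == (1.0, 1.0, 1.0)
    none = evaluate({("x", "y")}, ten)
    assert (none.precision, none.recall, none.f_measure) == (0.0, 0.0, 0.0)
    empty = evaluate(set(), ten)
    assert (empty.precision, empty.recall, empty.f_measure) == (0.0, 0.0, 0.0)
    # subset identities
    sub = {(f"a{i}", f"b{i}") for i in range(4)}
    assert evaluate(sub, ten).precision == 1.0
    assert evaluate(ten, sub).recall == 1.0


def test_alignment_set_stage_disjointness():
    aset = AlignmentSet(
        m_exact={_t("a", "x", prov="exact")},
        m_extended={_t("a", "x", prov="extended")},
    )
    with pytest.raises(ValueError):
        aset.validate_disjoint_stages()
    ok = AlignmentSet(
        m_exact={_t("a", "x", prov="exact")},
        m_extended={_t("b", "y", prov="extended")},
    )
    ok.validate_disjoint_stages()
    assert len(ok.m_candidate) == 2
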