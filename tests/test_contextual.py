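"""Contextual candidate generation, structural scoring and the decision tree."""

import numpy as np
import pytest

from ontomatch import GeneratorSpec, MappingTriple, NormalizerConfig, Ontology, generate_pair
from ontomatch.contextual import (
    FeatureVector,
    build_training_set,
    classify_pcc,
    context_scores,
    featurize,
    generate_pcc,
    train_classifier,
)

CFG = NormalizerConfig()
NS1, NS2 = "http://a#", "http://b#"


def _mirrored(edges, labels):
    """Two structurally identical taxonomies with the given labels."""
    o1, o2 = Ontology(), Ontology()
    for parent, child in edges:
        o1.add_isa(NS1 + parent, NS1 + child)
        o2.add_isa(NS2 + parent, NS2 + child)
    for name, text in labels.items():
        for o, ns in ((o1, NS1), (o2, NS2)):
            if ns + name not in o.concepts:
                o.add_concept(ns + name)
            o.add_label(ns + name, text, "en")
    return o1, o2


def _anchor(name1, name2=None):
    return MappingTriple(NS1 + name1, NS2 + (name2 or name1), 1.0, "exact")


def test_pcc_from_anchor_entourage():
    o1, o2 = _mirrored(
        [("r", "a"), ("r", "b"), ("a", "c")],
        {"r": "root", "a": "alpha", "b": "beta", "c": "gamma"},
    )
    m_exact = {_anchor("a")}
    pcc = generate_pcc(m_exact, o1, o2)
    # unmapped child pair and parent pair and sibling pair all proposed
    assert (NS1 + "c", NS2 + "c") in pcc
    assert (NS1 + "r", NS2 + "r") in pcc
    assert (NS1 + "b", NS2 + "b") in pcc
    # members already mapped never appear
    pcc2 = generate_pcc({_anchor("a"), _anchor("c"), _anchor("r"), _anchor("b")}, o1, o2)
    assert pcc2 == set()


def test_pcc_deduplicates_shared_neighbours():
    o1, o2 = _mirrored(
        [("r", "a"), ("r", "b"), ("r", "x")],
        {"r": "root", "a": "alpha", "b": "beta", "x": "chi"},
    )
    pcc = generate_pcc({_anchor("a"), _anchor("b")}, o1, o2)
    assert isinstance(pcc, set)
    assert (NS1 + "x", NS2 + "x") in pcc  # proposed by both anchors, once


def test_pcc_excludes_anchors():
    pair = generate_pair(GeneratorSpec(seed=21, n_concepts=50))
    anchors = {
        MappingTriple(a, b, 1.0, "exact")
        for a, b in sorted(pair.reference)[:20]
        if a in pair.o1.concepts
    }
    pcc = generate_pcc(anchors, pair.o1, pair.o2)
    assert pcc.isdisjoint({t.pair for t in anchors})


def test_context_scores_depth_weighting():
    o1, o2 = _mirrored(
        [("c", "d1"), ("d1", "d2")],
        {"c": "top", "d1": "mid", "d2": "deep"},
    )
    pair = (NS1 + "c", NS2 + "c")
    # no surrounding matches -> 0
    assert context_scores(pair, set(), o1, o2).total == 0.0
    # one matched direct-child pair -> score_sub = 1
    assert context_scores(pair, {_anchor("d1")}, o1, o2).score_sub == 1.0
    # one matched depth-2 descendant pair -> 1/2
    assert context_scores(pair, {_anchor("d2")}, o1, o2).score_sub == 0.5
    # ancestors mirror: from d2's perspective c sits at depth 2
    pair_up = (NS1 + "d2", NS2 + "d2")
    assert context_scores(pair_up, {_anchor("c")}, o1, o2).score_sup == 0.5


def test_context_scores_siblings():
    o1, o2 = _mirrored(
        [("r", "a"), ("r", "b")], {"r": "root", "a": "alpha", "b": "beta"}
    )
    ctx = context_scores((NS1 + "a", NS2 + "a"), {_anchor("b")}, o1, o2)
    assert ctx.score_sib == 1.0 and ctx.total == 1.0


def test_training_set_negative_rule_and_determinism():
    o1, o2 = _mirrored(
        [("p", "c"), ("c", "k")], {"p": "parent", "c": "core", "k": "kid"}
    )
    anchors = {_anchor("c")}
    rows = build_training_set(anchors, o1, o2, CFG, neg_per_pos=2, seed=5, min_positives=1)
    labels = sorted(r.label for r in rows)
    assert labels == ["no", "no", "yes"]
    negatives = {r.c2 for r in rows if r.label == "no"}
    assert negatives <= {NS2 + "p", NS2 + "k"}  # ancestor or descendant of c2
    rows2 = build_training_set(anchors, o1, o2, CFG, neg_per_pos=2, seed=5, min_positives=1)
    assert rows == rows2
    # isolated concept yields no negatives
    o1b, o2b = _mirrored([], {"solo": "alone"})
    rows3 = build_training_set(
        {_anchor("solo")}, o1b, o2b, CFG, neg_per_pos=2, seed=5, min_positives=1
    )
    assert [r.label for r in rows3] == ["yes"]


def test_too_few_positives_aborts():
    o1, o2 = _mirrored([("p", "c")], {"p": "parent", "c": "core"})
    assert build_training_set({_anchor("c")}, o1, o2, CFG, min_positives=10) == []


def test_train_classifier_separable_and_contradictory():
    yes = [FeatureVector("a", "b", (1.0,) * 5, "yes") for _ in range(10)]
    no = [FeatureVector("a", "b", (0.0,) * 5, "no") for _ in range(10)]
    clf = train_classifier(yes + no, seed=0)
    assert clf.training_accuracy == 1.0
    assert clf.predict((1.0,) * 5) == (True, 1.0)
    assert clf.predict((0.0,) * 5)[0] is False
    assert "class: yes" in clf.dump()  # readable tree dump names the classes
    # duplicated contradictory rows: accuracy < 1, no crash
    contradictory = yes + no + [FeatureVector("a", "b", (1.0,) * 5, "no")] * 3
    clf2 = train_classifier(contradictory, seed=0)
    assert clf2.training_accuracy < 1.0
    # single class aborts
    assert train_classifier(yes, seed=0) is None


def test_tree_recovers_generating_rule():
    """A 200-row synthetic set with a known threshold rule is reproduced
    on held-out rows at >= 95% (fixed seed)."""
    rng = np.random.default_rng(42)
    X = rng.random((260, 5))
    y = np.where((X[:, 1] > 0.55) & (X[:, 3] > 0.4), "yes", "no")
    rows = [
        FeatureVector("a", "b", tuple(x), lab) for x, lab in zip(X[:200], y[:200])
    ]
    clf = train_classifier(rows, seed=0)
    held_X, held_y = X[200:], y[200:]
    correct = sum(
        clf.predict(tuple(x))[0] == (lab == "yes") for x, lab in zip(held_X, held_y)
    )
    assert correct / len(held_y) >= 0.95


def test_classify_pcc_gating_and_recovery():
    o1, o2 = _mirrored(
        [("r", "a"), ("r", "b"), ("a", "c"), ("a", "d")],
        {"r": "root", "a": "alpha", "b": "beta", "c": "gamma", "d": "delta"},
    )
    anchors = {_anchor("a"), _anchor("c")}
    yes = [FeatureVector("x", "y", (1.0,) * 5, "yes") for _ in range(5)]
    no = [FeatureVector("x", "y", (0.2,) * 5, "no") for _ in range(5)]
    clf = train_classifier(yes + no, seed=0)
    pcc = generate_pcc(anchors, o1, o2)
    # (d, d) has identical neighbourhood text and matched sibling + parent
    out = classify_pcc(pcc, 0.5, clf, anchors, o1, o2, CFG)
    assert (NS1 + "d", NS2 + "d") in {t.pair for t in out}
    # with an impossibly high gate nothing is classified
    assert classify_pcc(pcc, 99.0, clf, anchors, o1, o2, CFG) == set()
    assert classify_pcc(pcc, 0.5, None, anchors, o1, o2, CFG) == set()


def test_identical_evd_features_are_one():
    o1, o2 = _mirrored([("p", "c")], {"p": "parent", "c": "core"})
    fv = featurize((NS1 + "c", NS2 + "c"), o1, o2, CFG)
    assert fv.features == (1.0,) * 5
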