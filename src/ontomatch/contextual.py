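"""Contextual similarity: recover mappings that are invisible to lexical
matching by exploiting the structure around already-matched anchor pairs.

The anchors (M_exact) are assumed correct.  Candidate pairs (*pcc*) are
drawn from the entourage of each anchor — cross pairs of the ancestors,
descendants and siblings of its two ends that are not themselves mapped.
Each candidate receives a structural score

    s = score_sub + score_sup + score_sib,

where matched descendant (resp. ancestor) pairs contribute 1/depth — the
further apart a supporting matched pair, the less it contributes — and
matched sibling pairs contribute 1 each.  Candidates with s > phi are
classified by a decision tree trained on auto-labelled data: anchors are
"yes" examples; "no" examples pair an anchor's left end with an ancestor
or descendant of its right end (a concept cannot map both a concept and
its ancestor/descendant).  Features are five string similarities (Q-gram,
Levenshtein, block distance, word Jaccard, Monge-Elkan) computed between
the concepts' neighbourhood label texts (properties excluded).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.tree import DecisionTreeClassifier, export_text

from .candidates import PROV_CONTEXT, MappingTriple
from .metrics import (
    block_distance_sim,
    jaccard_words,
    levenshtein_sim,
    monge_elkan,
    qgram_sim,
)
from .normalize import NormalizerConfig, normalize
from .ontology import Ontology

logger = logging.getLogger(__name__)

__all__ = [
    "ContextPair",
    "FeatureVector",
    "ContextClassifier",
    "generate_pcc",
    "context_scores",
    "feature_text",
    "featurize",
    "build_training_set",
    "train_classifier",
    "classify_pcc",
]

FEATURE_NAMES = ("qgram", "levenshtein", "block_distance", "jaccard", "monge_elkan")

MIN_POSITIVES = 10


@dataclass(frozen=True)
class ContextPair:
    """A pcc pair with its structural support scores."""

    c1: str
    c2: str
    score_sub: float
    score_sup: float
    score_sib: float

    @property
    def total(self) -> float:
        return self.score_sub + self.score_sup + self.score_sib


@dataclass(frozen=True)
class FeatureVector:
    """Five string-similarity features of a concept pair plus its label."""

    c1: str
    c2: str
    features: tuple[float, float, float, float, float]
    label: str = "unlabelled"  # yes | no | unlabelled


def generate_pcc(
    m_exact: set[MappingTriple], o1: Ontology, o2: Ontology
) -> set[tuple[str, str]]:
    """Cross pairs from the entourages of all anchors, minus any pair with
    an already-mapped member; deduplicated."""
    if not m_exact:
        logger.warning("empty anchor set: contextual stage is degenerate")
        return set()
    mapped1 = {t.e1 for t in m_exact}
    mapped2 = {t.e2 for t in m_exact}
    pcc: set[tuple[str, str]] = set()
    for t in m_exact:
        if t.e1 not in o1.concepts or t.e2 not in o2.concepts:
            continue
        neighbourhoods = (
            (o1.ancestors(t.e1), o2.ancestors(t.e2)),
            (o1.descendants(t.e1), o2.descendants(t.e2)),
            (o1.siblings(t.e1), o2.siblings(t.e2)),
        )
        for side1, side2 in neighbourhoods:
            for x in side1:
                if x in mapped1:
                    continue
                for y in side2:
                    if y not in mapped2:
                        pcc.add((x, y))
    return pcc


def context_scores(
    pair: tuple[str, str],
    m_exact: set[MappingTriple],
    o1: Ontology,
    o2: Ontology,
    depth_limit: int = 2,
) -> ContextPair:
    """Depth-weighted structural support of one candidate pair.

    A matched pair (x, y) with x within depth_limit below c1 and y below
    c2 adds 1/max(depth(x), depth(y)) to score_sub; ancestors contribute
    analogously to score_sup; matched direct-sibling pairs add 1 each to
    score_sib.
    """
    c1, c2 = pair
    if depth_limit < 1:
        raise ValueError("depth_limit must be >= 1")
    down1 = o1._bfs_depths(c1, depth_limit, down=True)
    down2 = o2._bfs_depths(c2, depth_limit, down=True)
    up1 = o1._bfs_depths(c1, depth_limit, down=False)
    up2 = o2._bfs_depths(c2, depth_limit, down=False)
    sib1, sib2 = o1.siblings(c1), o2.siblings(c2)

    score_sub = score_sup = score_sib = 0.0
    for t in m_exact:
        if t.e1 in down1 and t.e2 in down2:
            score_sub += 1.0 / max(down1[t.e1], down2[t.e2])
        if t.e1 in up1 and t.e2 in up2:
            score_sup += 1.0 / max(up1[t.e1], up2[t.e2])
        if t.e1 in sib1 and t.e2 in sib2:
            score_sib += 1.0
    return ContextPair(c1, c2, score_sub, score_sup, score_sib)


def feature_text(onto: Ontology, c: str, cfg: NormalizerConfig) -> str:
    """Neighbourhood label text of a concept: its own labels plus those of
    its direct ancestors, descendants and siblings (no properties), each
    section's tokens in sorted order for word-order stability."""
    sections = (
        {c},
        onto.ancestors(c),
        onto.descendants(c),
        onto.siblings(c),
    )
    parts: list[str] = []
    for group in sections:
        tokens: list[str] = []
        for entity in sorted(group):
            for text in onto.label_strings(entity):
                tokens.extend(normalize(text, cfg, stem=False))
        parts.extend(sorted(tokens))
    return " ".join(parts)


def featurize(
    pair: tuple[str, str],
    o1: Ontology,
    o2: Ontology,
    cfg: NormalizerConfig,
    label: str = "unlabelled",
    _cache: dict | None = None,
) -> FeatureVector:
    """Compute the five similarity features between neighbourhood texts."""

    def text(onto, c, key):
        if _cache is None:
            return feature_text(onto, c, cfg)
        if (key, c) not in _cache:
            _cache[(key, c)] = feature_text(onto, c, cfg)
        return _cache[(key, c)]

    t1 = text(o1, pair[0], 1)
    t2 = text(o2, pair[1], 2)
    feats = (
        qgram_sim(t1, t2),
        levenshtein_sim(t1, t2),
        block_distance_sim(t1, t2),
        jaccard_words(t1, t2),
        monge_elkan(t1, t2),
    )
    return FeatureVector(pair[0], pair[1], feats, label)


def build_training_set(
    m_exact: set[MappingTriple],
    o1: Ontology,
    o2: Ontology,
    cfg: NormalizerConfig,
    neg_per_pos: int = 2,
    seed: int = 0,
    depth_limit: int = 2,
    min_positives: int = MIN_POSITIVES,
) -> list[FeatureVector]:
    """Auto-labelled training data: one "yes" vector per anchor, and up to
    neg_per_pos "no" vectors pairing the anchor's left end with an
    ancestor/descendant of its right end (sampled with a fixed seed)."""
    anchors = sorted(
        (t for t in m_exact if t.e1 in o1.concepts and t.e2 in o2.concepts),
        key=lambda t: t.pair,
    )
    if len(anchors) < min_positives:
        logger.warning(
            "only %d anchors (< %d): contextual stage aborted", len(anchors), min_positives
        )
        return []
    rng = np.random.default_rng(seed)
    cache: dict = {}
    rows: list[FeatureVector] = []
    for t in anchors:
        rows.append(featurize(t.pair, o1, o2, cfg, label="yes", _cache=cache))
        neighbours = sorted(
            o2.desc_k(t.e2, depth_limit) | o2.anc_k(t.e2, depth_limit)
        )
        if not neighbours:
            logger.debug("anchor %s has no neighbours for negatives", (t.pair,))
            continue
        n_neg = min(neg_per_pos, len(neighbours))
        picks = rng.choice(len(neighbours), size=n_neg, replace=False)
        for i in sorted(picks):
            rows.append(
                featurize((t.e1, neighbours[i]), o1, o2, cfg, label="no", _cache=cache)
            )
    return rows


class ContextClassifier:
    """Decision tree over the five features with the tie->"no" rule."""

    def __init__(self, model: DecisionTreeClassifier, training_accuracy: float):
        self.model = model
        self.training_accuracy = training_accuracy
        self._yes_index = list(model.classes_).index("yes")

    def predict(self, features) -> tuple[bool, float]:
        """Return (is_yes, leaf confidence for "yes").

        A leaf split evenly between the classes predicts "no"
        (precision-first tie break).
        """
        proba = self.model.predict_proba(np.asarray(features).reshape(1, -1))[0]
        p_yes = float(proba[self._yes_index])
        return p_yes > 0.5, p_yes

    def dump(self) -> str:
        """Human-readable tree for inspection."""
        return export_text(self.model, feature_names=list(FEATURE_NAMES))


def train_classifier(
    training: list[FeatureVector], seed: int = 0
) -> ContextClassifier | None:
    """Fit an entropy-split decision tree on the auto-labelled vectors.

    Returns None (stage aborted) when the training set is empty or
    single-class.
    """
    if not training:
        return None
    labels = sorted({r.label for r in training})
    if len(labels) < 2:
        logger.warning("single-class training set: contextual stage aborted")
        return None
    X = np.array([r.features for r in training])
    y = np.array([r.label for r in training])
    model = DecisionTreeClassifier(
        criterion="entropy", min_samples_leaf=2, random_state=seed
    )
    model.fit(X, y)
    accuracy = float((model.predict(X) == y).mean())
    logger.info("contextual classifier trained; training accuracy %.3f", accuracy)
    return ContextClassifier(model, accuracy)


def classify_pcc(
    pcc: set[tuple[str, str]],
    phi: float,
    classifier: ContextClassifier | None,
    m_exact: set[MappingTriple],
    o1: Ontology,
    o2: Ontology,
    cfg: NormalizerConfig,
    depth_limit: int = 2,
) -> set[MappingTriple]:
    """M_context: pcc pairs with structural score s > phi that the tree
    classifies "yes"; the triple's score is the leaf confidence."""
    if classifier is None or not pcc:
        return set()
    cache: dict = {}
    out: set[MappingTriple] = set()
    for pair in sorted(pcc):
        ctx = context_scores(pair, m_exact, o1, o2, depth_limit)
        if ctx.total <= phi:
            continue
        fv = featurize(pair, o1, o2, cfg, _cache=cache)
        is_yes, confidence = classifier.predict(fv.features)
        if is_yes:
            out.add(
                MappingTriple(
                    pair[0],
                    pair[1],
                    score=confidence,
                    provenance=PROV_CONTEXT,
                    component_scores=tuple(zip(FEATURE_NAMES, fv.features))
                    + (("context_s", ctx.total),),
                )
            )
    return out
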