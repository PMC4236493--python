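"""Candidate-set union, consistency filtering, selection and evaluation.

The four candidate sets (exact, property, extended, contextual) are
unioned, then cleaned by two *trivial* consistency checks driven by the
high-precision anchor set M_exact: candidates pairing an anchor's partner
with a concept declared disjoint from the anchor are discarded, and
*criss-cross* candidates — pairing one end of an anchor with an ancestor
or descendant of the other end — are discarded.  Afterwards an enrichment
pass proposes lexically similar child pairs under mapped parents and a
greedy best-score selection produces the final (by default one-to-one)
alignment.  Standard precision/recall/F-measure evaluation against a
reference alignment closes the loop.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .candidates import (
    PROV_CONTEXT,
    PROVENANCE_RANK,
    LexicalConfig,
    MappingTriple,
    canonical_labels,
)
from .metrics import lexical_similarity
from .normalize import NormalizerConfig
from .ontology import Ontology

logger = logging.getLogger(__name__)

__all__ = [
    "AlignmentSet",
    "EvaluationReport",
    "enrich",
    "greedy_select",
    "disjointness_filter",
    "crisscross_filter",
    "evaluate",
]

ONE_TO_ONE = "one-to-one"
ONE_TO_MANY = "one-to-many"


@dataclass
class AlignmentSet:
    """The per-stage candidate sets and the final selection."""

    m_exact: set[MappingTriple] = field(default_factory=set)
    m_prop: set[MappingTriple] = field(default_factory=set)
    m_extended: set[MappingTriple] = field(default_factory=set)
    m_context: set[MappingTriple] = field(default_factory=set)
    final: set[MappingTriple] = field(default_factory=set)
    cardinality_mode: str = ONE_TO_ONE

    @property
    def m_candidate(self) -> set[MappingTriple]:
        return self.m_exact | self.m_prop | self.m_extended | self.m_context

    def stage_pairs(self) -> dict[str, set[tuple[str, str]]]:
        return {
            "exact": {t.pair for t in self.m_exact},
            "prop": {t.pair for t in self.m_prop},
            "extended": {t.pair for t in self.m_extended},
            "context": {t.pair for t in self.m_context},
        }

    def validate_disjoint_stages(self) -> None:
        """The four stages must not repeat an unordered entity pair."""
        stages = list(self.stage_pairs().items())
        for i, (name_a, pairs_a) in enumerate(stages):
            for name_b, pairs_b in stages[i + 1:]:
                overlap = pairs_a & pairs_b
                if overlap:
                    raise ValueError(
                        f"stages {name_a} and {name_b} share pairs: {sorted(overlap)[:3]}"
                    )


@dataclass(frozen=True)
class EvaluationReport:
    """Precision/recall/F-measure of a returned alignment."""

    precision: float
    recall: float
    f_measure: float
    n_returned: int
    n_reference: int
    n_correct: int


def _pairs(mappings) -> set[tuple[str, str]]:
    return {m.pair if isinstance(m, MappingTriple) else tuple(m) for m in mappings}


# ------------------------------------------------------------- filters


def disjointness_filter(
    candidates: set[MappingTriple],
    m_exact: set[MappingTriple],
    o1: Ontology,
    o2: Ontology,
) -> set[MappingTriple]:
    """Remove candidates that pair an anchor's partner with a concept
    declared disjoint from the anchor, on either side; anchors themselves
    are never removed."""
    anchor_pairs = {t.pair for t in m_exact}
    anchors_by_e2: dict[str, set[str]] = {}
    anchors_by_e1: dict[str, set[str]] = {}
    for a1, a2 in anchor_pairs:
        anchors_by_e2.setdefault(a2, set()).add(a1)
        anchors_by_e1.setdefault(a1, set()).add(a2)

    kept: set[MappingTriple] = set()
    for t in candidates:
        if t.pair in anchor_pairs:
            kept.add(t)
            continue
        conflict = any(
            o1.are_disjoint(t.e1, a1) for a1 in anchors_by_e2.get(t.e2, ())
        ) or any(o2.are_disjoint(t.e2, a2) for a2 in anchors_by_e1.get(t.e1, ()))
        if conflict:
            logger.debug("disjointness filter removes %s", t.pair)
        else:
            kept.add(t)
    return kept


def crisscross_filter(
    candidates: set[MappingTriple],
    m_exact: set[MappingTriple],
    o1: Ontology,
    o2: Ontology,
) -> set[MappingTriple]:
    """Remove candidates hierarchically in conflict with an anchor:
    (c1, y) with y an ancestor/descendant of c2, and (x, c2) with x an
    ancestor/descendant of c1, for every anchor (c1, c2).  Uses the full
    transitive closures; anchors are exempt."""
    anchor_pairs = {t.pair for t in m_exact}
    anchors_by_e1: dict[str, set[str]] = {}
    anchors_by_e2: dict[str, set[str]] = {}
    for a1, a2 in anchor_pairs:
        anchors_by_e1.setdefault(a1, set()).add(a2)
        anchors_by_e2.setdefault(a2, set()).add(a1)

    closure_cache: dict[tuple[int, str], set[str]] = {}

    def vertical(onto: Ontology, c: str, key: int) -> set[str]:
        if (key, c) not in closure_cache:
            closure_cache[(key, c)] = onto.all_ancestors(c) | onto.all_descendants(c)
        return closure_cache[(key, c)]

    kept: set[MappingTriple] = set()
    for t in candidates:
        if t.pair in anchor_pairs:
            kept.add(t)
            continue
        conflict = False
        for a2 in anchors_by_e1.get(t.e1, ()):
            if t.e2 in o2.concepts and a2 in o2.concepts and t.e2 in vertical(o2, a2, 2):
                conflict = True
                break
        if not conflict:
            for a1 in anchors_by_e2.get(t.e2, ()):
                if t.e1 in o1.concepts and a1 in o1.concepts and t.e1 in vertical(o1, a1, 1):
                    conflict = True
                    break
        if conflict:
            logger.debug("criss-cross filter removes %s", t.pair)
        else:
            kept.add(t)
    return kept


# ------------------------------------------------------------- enrichment


def enrich(
    candidates: set[MappingTriple],
    o1: Ontology,
    o2: Ontology,
    cfg: NormalizerConfig,
    lex: LexicalConfig,
) -> set[MappingTriple]:
    """Child-pair enrichment: under every mapped concept pair, propose the
    still-unmapped direct-child pairs whose Sim_lex passes theta.

    Added triples carry provenance "context" and an "enriched" marker; the
    downstream greedy selection arbitrates competing children.
    """
    mapped1 = {t.e1 for t in candidates}
    mapped2 = {t.e2 for t in candidates}
    existing = {t.pair for t in candidates}
    added: set[MappingTriple] = set()
    for t in sorted(candidates, key=lambda t: t.pair):
        if t.e1 not in o1.concepts or t.e2 not in o2.concepts:
            continue
        for x in sorted(o1.descendants(t.e1) - mapped1):
            labels_x = canonical_labels(o1, x, cfg)
            for y in sorted(o2.descendants(t.e2) - mapped2):
                if (x, y) in existing:
                    continue
                sim = lexical_similarity(
                    labels_x, canonical_labels(o2, y, cfg), lex.weights
                )
                if sim >= lex.theta:
                    added.add(
                        MappingTriple(
                            x,
                            y,
                            score=min(sim, 1.0),
                            provenance=PROV_CONTEXT,
                            component_scores=(("simlex", sim), ("enriched", 1.0)),
                        )
                    )
    return added


# ------------------------------------------------------------- selection


def greedy_select(
    candidates: set[MappingTriple], mode: str = ONE_TO_ONE
) -> set[MappingTriple]:
    """Greedy best-score selection.

    Triples are visited by descending score, breaking ties by provenance
    rank (exact > prop > extended > context) then by IRI pair; a triple is
    accepted when neither endpoint is already used (one-to-one) or always
    (one-to-many, distinct pairs).
    """
    ordered = sorted(
        candidates,
        key=lambda t: (-t.score, PROVENANCE_RANK.get(t.provenance, 9), t.pair),
    )
    if mode == ONE_TO_MANY:
        seen: set[tuple[str, str]] = set()
        out = set()
        for t in ordered:
            if t.pair not in seen:
                seen.add(t.pair)
                out.add(t)
        return out
    used1: set[str] = set()
    used2: set[str] = set()
    out: set[MappingTriple] = set()
    for t in ordered:
        if t.e1 in used1 or t.e2 in used2:
            continue
        used1.add(t.e1)
        used2.add(t.e2)
        out.add(t)
    return out


# ------------------------------------------------------------- evaluation


def evaluate(returned, reference) -> EvaluationReport:
    """P = |RM n CM| / |RM|, R = |RM n CM| / |CM|, F = 2PR/(P+R); both
    alignments compared on unordered entity-pair identity; empty
    denominators yield 0 with a warning."""
    rm = _pairs(returned)
    cm = _pairs(reference)
    correct = len(rm & cm)
    if not rm or not cm:
        logger.warning("empty returned or reference alignment in evaluation")
    precision = correct / len(rm) if rm else 0.0
    recall = correct / len(cm) if cm else 0.0
    f = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return EvaluationReport(
        precision=precision,
        recall=recall,
        f_measure=f,
        n_returned=len(rm),
        n_reference=len(cm),
        n_correct=correct,
    )
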