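"""Candidate mapping generation.

The lexical stage retrieves high-precision concept pairs (M_exact) by a
two-way search over the exact-mode indexes of the two ontologies: every
entity of one side queries the other side's index, the two directed
top-k result sets are intersected, and the surviving pairs are filtered by
the weighted lexical similarity Sim_lex >= theta.  The same pipeline
restricted to properties yields M_prop.  The extended stage (M_extended)
re-runs the search for the still-unmatched concepts over relaxed-mode
extended virtual documents (ancestor labels included) and additionally
bridges synonym vocabulary: a pair is proposed when substituting a synonym
from a lexicon into one side's label reproduces a label of the other side.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .documents import EXACT, RELAXED, build_virtual_document
from .index import InvertedIndex, index_ontology
from .metrics import LexWeights, lexical_similarity
from .normalize import NormalizerConfig, exact_forms, normalize
from .ontology import CONCEPT, DATATYPE_PROPERTY, OBJECT_PROPERTY, Ontology

logger = logging.getLogger(__name__)

__all__ = [
    "MappingTriple",
    "LexicalConfig",
    "canonical_labels",
    "two_way_search",
    "build_m_exact",
    "match_properties",
    "extended_search",
    "synonym_bridge",
    "load_lexicon",
]

PROV_EXACT = "exact"
PROV_PROP = "prop"
PROV_EXTENDED = "extended"
PROV_CONTEXT = "context"

PROVENANCE_RANK = {PROV_EXACT: 0, PROV_PROP: 1, PROV_EXTENDED: 2, PROV_CONTEXT: 3}


@dataclass(frozen=True)
class MappingTriple:
    """A scored correspondence <e1, e2, s> with its generating stage."""

    e1: str
    e2: str
    score: float
    provenance: str
    component_scores: tuple[tuple[str, float], ...] = field(
        default=(), compare=False
    )

    def __post_init__(self) -> None:
        if not 0.0 <= self.score <= 1.0 + 1e-12:
            raise ValueError(f"score outside [0, 1]: {self.score}")

    @property
    def pair(self) -> tuple[str, str]:
        return (self.e1, self.e2)


@dataclass(frozen=True)
class LexicalConfig:
    """Parameters of the lexical candidate retrieval.

    best_k:     directed top-k cut-off of the index search;
    max_score:  minimum engine (cosine) score of a directed hit;
    theta:      Sim_lex acceptance threshold;
    theta_syn:  floor score given to synonym-bridged pairs;
    require_both: keep a pair only if found in BOTH directed searches
                (the strict intersection); when False the union is kept.
    """

    best_k: int = 3
    max_score: float = 0.1
    theta: float = 0.75
    theta_syn: float = 0.75
    weights: LexWeights = field(default_factory=LexWeights)
    require_both: bool = True

    def __post_init__(self) -> None:
        if self.best_k < 1:
            raise ValueError("best_k must be >= 1")
        if not 0.0 <= self.theta <= 1.0:
            raise ValueError("theta must lie in [0, 1]")


def canonical_labels(onto: Ontology, entity: str, cfg: NormalizerConfig) -> list[str]:
    """Normalized pre-stem label strings with tokens in canonical (sorted)
    order — the strings Sim_lex is computed on.

    Canonical token order makes the theta filter word-order invariant, in
    line with the permutation-enriched whole-label matching of the index.
    Falls back to the local name when the entity carries no labels.
    """
    texts = onto.label_strings(entity) or [onto.local_name_of(entity)]
    out = set()
    for text in texts:
        tokens = normalize(text, cfg, stem=False)
        if tokens:
            out.add(" ".join(sorted(tokens)))
    return sorted(out)


_PROPERTY_KINDS = {OBJECT_PROPERTY, DATATYPE_PROPERTY}


def _directed_hits(
    source: Ontology,
    target_index: InvertedIndex,
    target: Ontology,
    cfg: NormalizerConfig,
    lex: LexicalConfig,
    kinds: set[str],
    entities=None,
) -> dict[tuple[str, str], float]:
    """Query the target index with every source entity's dVD; keep top-k
    hits above max_score, restricted to kind-compatible targets."""
    hits: dict[tuple[str, str], float] = {}
    pool = entities if entities is not None else source.entities()
    for e1 in pool:
        kind = source.kind_of(e1)
        if kind not in kinds:
            continue
        query = build_virtual_document(source, e1, cfg, mode=target_index.mode)
        kept = 0
        for hit in target_index.search(query, k=target_index.doc_count or 1):
            if kept >= lex.best_k:
                break
            if hit.score < lex.max_score:
                break
            if target.kind_of(hit.entity_id) != kind:
                continue
            hits[(e1, hit.entity_id)] = hit.score
            kept += 1
    return hits


def two_way_search(
    o1: Ontology,
    o2: Ontology,
    i1: InvertedIndex,
    i2: InvertedIndex,
    cfg: NormalizerConfig,
    lex: LexicalConfig,
    kind: str = CONCEPT,
    residual_1=None,
    residual_2=None,
) -> dict[tuple[str, str], float]:
    """Intersection (or union, per config) of the two directed retrievals;
    each unordered pair carries the mean of its directed engine scores."""
    kinds = {kind} if kind == CONCEPT else _PROPERTY_KINDS
    fwd = _directed_hits(o1, i2, o2, cfg, lex, kinds, residual_1)
    rev = _directed_hits(o2, i1, o1, cfg, lex, kinds, residual_2)
    rev_pairs = {(e1, e2): s for (e2, e1), s in rev.items()}
    if lex.require_both:
        keys = set(fwd) & set(rev_pairs)
    else:
        keys = set(fwd) | set(rev_pairs)
    out = {}
    for key in keys:
        scores = [s for s in (fwd.get(key), rev_pairs.get(key)) if s is not None]
        out[key] = sum(scores) / len(scores)
    return out


def build_m_exact(
    pairs: dict[tuple[str, str], float],
    o1: Ontology,
    o2: Ontology,
    cfg: NormalizerConfig,
    lex: LexicalConfig,
    provenance: str = PROV_EXACT,
) -> set[MappingTriple]:
    """Filter retrieved pairs by Sim_lex >= theta; the kept triple's score
    is its Sim_lex value."""
    out: set[MappingTriple] = set()
    for (e1, e2), engine_score in sorted(pairs.items()):
        sim = lexical_similarity(
            canonical_labels(o1, e1, cfg),
            canonical_labels(o2, e2, cfg),
            lex.weights,
        )
        if sim >= lex.theta:
            out.add(
                MappingTriple(
                    e1,
                    e2,
                    score=min(sim, 1.0),
                    provenance=provenance,
                    component_scores=(("engine", engine_score), ("simlex", sim)),
                )
            )
    return out


def match_properties(
    o1: Ontology,
    o2: Ontology,
    i1: InvertedIndex,
    i2: InvertedIndex,
    cfg: NormalizerConfig,
    lex: LexicalConfig,
) -> set[MappingTriple]:
    """M_prop: the exact pipeline restricted to kind-compatible property
    pairs (object<->object, datatype<->datatype)."""
    pairs = two_way_search(o1, o2, i1, i2, cfg, lex, kind=OBJECT_PROPERTY)
    return build_m_exact(pairs, o1, o2, cfg, lex, provenance=PROV_PROP)


def extended_search(
    residual_1: set[str],
    residual_2: set[str],
    o1: Ontology,
    o2: Ontology,
    cfg: NormalizerConfig,
    lex: LexicalConfig,
) -> set[MappingTriple]:
    """Repeat the two-way search for unmatched concepts over relaxed-mode
    extended virtual documents (ancestor labels/local names included)."""
    if not residual_1 or not residual_2:
        return set()

    def _sub_index(onto: Ontology, keep: set[str]) -> InvertedIndex:
        idx = InvertedIndex(mode=RELAXED)
        for e in sorted(keep):
            idx.add_document(
                build_virtual_document(onto, e, cfg, extended=True, mode=RELAXED)
            )
        return idx

    i1 = _sub_index(o1, residual_1)
    i2 = _sub_index(o2, residual_2)
    pairs = two_way_search(
        o1, o2, i1, i2, cfg, lex,
        kind=CONCEPT,
        residual_1=sorted(residual_1),
        residual_2=sorted(residual_2),
    )
    return build_m_exact(pairs, o1, o2, cfg, lex, provenance=PROV_EXTENDED)


# ------------------------------------------------------------- synonyms


def load_lexicon(path: str) -> dict[str, set[str]]:
    """Read a TSV synonym lexicon (columns: term, synonym; normalized
    forms) into a symmetric term -> synonyms map."""
    lex: dict[str, set[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            term, _, synonym = line.partition("\t")
            term, synonym = term.strip(), synonym.strip()
            if term and synonym:
                lex.setdefault(term, set()).add(synonym)
                lex.setdefault(synonym, set()).add(term)
    return lex


def _expansions(label_tokens: list[str], lexicon: dict[str, set[str]]) -> set[str]:
    """Single-hop whole-word/phrase synonym substitutions of one label."""
    out: set[str] = set()
    phrase = " ".join(label_tokens)
    for syn in lexicon.get(phrase, ()):
        out.add(syn)
    for i, tok in enumerate(label_tokens):
        for syn in lexicon.get(tok, ()):
            out.add(" ".join(label_tokens[:i] + [syn] + label_tokens[i + 1:]))
    return out


def synonym_bridge(
    residual_1: set[str],
    residual_2: set[str],
    o1: Ontology,
    o2: Ontology,
    lexicon: dict[str, set[str]] | None,
    cfg: NormalizerConfig,
    lex: LexicalConfig,
) -> set[MappingTriple]:
    """Propose pairs whose labels become equal (as exact whole-label
    forms) after one synonym substitution from the lexicon.

    The proposed score is Sim_lex of the original labels floored at
    theta_syn; substitution is single-hop — chains through an intermediate
    synonym are deliberately not followed.
    """
    if not lexicon:
        logger.warning("no synonym lexicon supplied; synonym stage skipped")
        return set()
    if not residual_1 or not residual_2:
        return set()

    def form_table(onto: Ontology, pool: set[str]) -> dict[str, set[str]]:
        table: dict[str, set[str]] = {}
        for e in sorted(pool):
            for text in onto.label_strings(e) or [onto.local_name_of(e)]:
                for f in exact_forms(text, cfg):
                    table.setdefault(f, set()).add(e)
        return table

    forms_2 = form_table(o2, residual_2)
    forms_1 = form_table(o1, residual_1)

    def bridge(onto_a, pool_a, forms_b, flip: bool):
        for ea in sorted(pool_a):
            for text in onto_a.label_strings(ea) or [onto_a.local_name_of(ea)]:
                tokens = normalize(text, cfg, stem=False)
                if not tokens:
                    continue
                for expanded in _expansions(tokens, lexicon):
                    for f in exact_forms(expanded, cfg):
                        for eb in forms_b.get(f, ()):
                            yield (eb, ea) if flip else (ea, eb)

    proposed: set[tuple[str, str]] = set()
    proposed.update(bridge(o1, residual_1, forms_2, flip=False))
    proposed.update(bridge(o2, residual_2, forms_1, flip=True))

    out: set[MappingTriple] = set()
    for e1, e2 in sorted(proposed):
        sim = lexical_similarity(
            canonical_labels(o1, e1, cfg),
            canonical_labels(o2, e2, cfg),
            lex.weights,
        )
        out.add(
            MappingTriple(
                e1,
                e2,
                score=min(max(sim, lex.theta_syn), 1.0),
                provenance=PROV_EXTENDED,
                component_scores=(("simlex", sim),),
            )
        )
    return out
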