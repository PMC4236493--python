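"""Fielded inverted index over virtual documents with tf-idf cosine scoring.

Each entity's virtual document is indexed per (field, term) dimension.
The retrieval score is the cosine of the tf-idf weighted vectors of the
query document and the indexed document:

    w(f, t) = sqrt(tf) * idf(f, t) * sqrt(boost(f)),
    idf(f, t) = 1 + ln(N / (1 + df(f, t))),
    score(q, e) = <w_q, w_e> / (|w_q| |w_e|),

which is word-order invariant by construction and, in exact mode, matches
whole labels through their permuted concatenated forms.  Scores lie in
[0, 1]; ties are broken by entity IRI so that retrieval is deterministic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .documents import EXACT, VirtualDocument, build_virtual_document
from .normalize import NormalizerConfig
from .ontology import CONCEPT, Ontology

__all__ = ["InvertedIndex", "ScoredHit", "index_ontology", "tfidf_cosine"]

#: Default per-field boosts; the uri field mostly repeats the local name so
#: it is down-weighted, comments are weak evidence.
DEFAULT_BOOSTS = {"uri": 0.5, "comments": 0.25}


@dataclass(frozen=True)
class ScoredHit:
    entity_id: str
    score: float
    matched_fields: frozenset[str]


class InvertedIndex:
    """In-memory fielded postings with tf-idf statistics."""

    def __init__(
        self,
        mode: str = EXACT,
        boosts: dict[str, float] | None = None,
    ) -> None:
        self.mode = mode
        self.boosts = dict(DEFAULT_BOOSTS)
        if boosts:
            self.boosts.update(boosts)
        #: (field, term) -> {entity_id: term frequency}
        self.postings: dict[tuple[str, str], dict[str, int]] = {}
        self.doc_table: dict[str, VirtualDocument] = {}
        self._norms: dict[str, float] | None = None

    # -- construction ----------------------------------------------------

    def add_document(self, doc: VirtualDocument) -> None:
        if doc.entity_id in self.doc_table:
            raise ValueError(f"duplicate document: {doc.entity_id}")
        self.doc_table[doc.entity_id] = doc
        for fname, terms in doc.fields.items():
            for term in terms:
                entry = self.postings.setdefault((fname, term), {})
                entry[doc.entity_id] = entry.get(doc.entity_id, 0) + 1
        self._norms = None

    # -- statistics ------------------------------------------------------

    @property
    def doc_count(self) -> int:
        return len(self.doc_table)

    def boost(self, fname: str) -> float:
        return self.boosts.get(fname, 1.0)

    def idf(self, fname: str, term: str) -> float:
        df = len(self.postings.get((fname, term), ()))
        return 1.0 + math.log(self.doc_count / (1.0 + df)) if self.doc_count else 0.0

    def _weight(self, fname: str, tf: int, idf: float) -> float:
        return math.sqrt(tf) * idf * math.sqrt(self.boost(fname))

    def _doc_norms(self) -> dict[str, float]:
        if self._norms is None:
            sq: dict[str, float] = {e: 0.0 for e in self.doc_table}
            for (fname, term), entry in self.postings.items():
                idf = self.idf(fname, term)
                for entity, tf in entry.items():
                    sq[entity] += self._weight(fname, tf, idf) ** 2
            self._norms = {e: math.sqrt(v) for e, v in sq.items()}
        return self._norms

    def _query_vector(self, query: VirtualDocument) -> dict[tuple[str, str], float]:
        counts: dict[tuple[str, str], int] = {}
        for fname, terms in query.fields.items():
            for term in terms:
                key = (fname, term)
                counts[key] = counts.get(key, 0) + 1
        return {
            (fname, term): self._weight(fname, tf, self.idf(fname, term))
            for (fname, term), tf in counts.items()
        }

    # -- retrieval -------------------------------------------------------

    def search(self, query: VirtualDocument, k: int = 10) -> list[ScoredHit]:
        """Top-k entities by tf-idf cosine against the query document."""
        if k < 1:
            raise ValueError("k must be >= 1")
        qvec = self._query_vector(query)
        qnorm = math.sqrt(sum(w * w for w in qvec.values()))
        if qnorm == 0:
            return []
        dots: dict[str, float] = {}
        fields_hit: dict[str, set[str]] = {}
        for (fname, term), wq in qvec.items():
            entry = self.postings.get((fname, term))
            if not entry:
                continue
            idf = self.idf(fname, term)
            for entity, tf in entry.items():
                dots[entity] = dots.get(entity, 0.0) + wq * self._weight(fname, tf, idf)
                fields_hit.setdefault(entity, set()).add(fname)
        norms = self._doc_norms()
        hits = [
            ScoredHit(e, dot / (qnorm * norms[e]), frozenset(fields_hit[e]))
            for e, dot in dots.items()
            if dot > 0.0
        ]
        hits.sort(key=lambda h: (-h.score, h.entity_id))
        return hits[:k]

    def score(self, query: VirtualDocument, entity: str) -> float:
        """Cosine score of the query against one indexed entity (0 if absent)."""
        if entity not in self.doc_table:
            return 0.0
        qvec = self._query_vector(query)
        qnorm = math.sqrt(sum(w * w for w in qvec.values()))
        if qnorm == 0:
            return 0.0
        doc = self.doc_table[entity]
        dot = 0.0
        for fname, terms in doc.fields.items():
            counts: dict[str, int] = {}
            for term in terms:
                counts[term] = counts.get(term, 0) + 1
            for term, tf in counts.items():
                wq = qvec.get((fname, term))
                if wq:
                    dot += wq * self._weight(fname, tf, self.idf(fname, term))
        return dot / (qnorm * self._doc_norms()[entity])


def tfidf_cosine(query: VirtualDocument, entity: str, index: InvertedIndex) -> float:
    """Module-level convenience wrapper around :meth:`InvertedIndex.score`."""
    return index.score(query, entity)


def index_ontology(
    onto: Ontology,
    cfg: NormalizerConfig,
    *,
    mode: str = EXACT,
    with_context: bool = False,
    extended: bool = False,
    kinds: set[str] | None = None,
    boosts: dict[str, float] | None = None,
    default_lang: str = "en",
) -> InvertedIndex:
    """Index every entity of an ontology (one document per entity).

    ``kinds`` restricts indexing to the given entity kinds (e.g. concepts
    only); ``extended`` indexes eVDs instead of dVDs.
    """
    idx = InvertedIndex(mode=mode, boosts=boosts)
    for entity in onto.entities():
        kind = onto.kind_of(entity)
        if kinds is not None and kind not in kinds:
            continue
        doc = build_virtual_document(
            onto,
            entity,
            cfg,
            extended=extended,
            mode=mode,
            with_context=with_context,
            default_lang=default_lang,
        )
        idx.add_document(doc)
    return idx
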