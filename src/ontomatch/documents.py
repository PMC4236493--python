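"""Virtual documents: the fielded terminological description of one entity.

Every concept and property becomes a *document* whose fields collect its
normalized terminological information — URI, local name, per-language
labels, comments, and for properties their domain/range labels, range
datatype and constraints.  The *direct* virtual document (dVD) holds only
the entity's own information; the *extended* document (eVD) adds the labels
and local names of its direct ancestors (for a property: the local names of
its super-properties).  Fields are generated dynamically: only features the
entity actually holds produce fields.

Two representations of label-like fields exist, matching the two indexing
strategies:

``exact``
    each label contributes the stemmed concatenations of every permutation
    of its (first four) normalized words as single whole-label terms —
    high-precision, word-order-invariant whole-label matching;
``relaxed``
    each label contributes its stemmed token stream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from ._porter import porter_stem
from .normalize import NormalizerConfig, concatenate, exact_forms, normalize
from .ontology import CONCEPT, DATATYPE_PROPERTY, OBJECT_PROPERTY, Ontology

logger = logging.getLogger(__name__)

__all__ = ["VirtualDocument", "build_virtual_document"]

EXACT = "exact"
RELAXED = "relaxed"

#: Field names a direct (non-extended) document may carry.
DVD_FIELDS = frozenset(
    {
        "uri", "directNameC", "directNameP", "comments", "dRange",
        "domainLabelsDP", "domainLabelsOP", "rangeLabelsOP", "propertyType",
    }
)
_EXTENDED_FIELDS = frozenset({"supLabels", "supLocalNames"})
_CONTEXT_FIELDS = frozenset({"sibLabels", "descLabels", "ancLabels"})


@dataclass
class VirtualDocument:
    """Bag of normalized terms for one entity, grouped into named fields."""

    entity_id: str
    kind: str
    fields: dict[str, list[str]] = field(default_factory=dict)
    extended: bool = False

    def add(self, name: str, terms: list[str]) -> None:
        if terms:
            self.fields.setdefault(name, []).extend(terms)

    def terms(self) -> list[str]:
        out: list[str] = []
        for name in sorted(self.fields):
            out.extend(self.fields[name])
        return out


def _label_field_name(kind: str, lang: str) -> str:
    base = "directLabelC" if kind == CONCEPT else "directLabelP"
    return base + (lang or "").upper()


def _label_terms(text: str, cfg: NormalizerConfig, mode: str) -> list[str]:
    if mode == EXACT:
        return sorted(exact_forms(text, cfg))
    return normalize(text, cfg)


def _labels_by_lang(
    onto: Ontology, entity: str, default_lang: str
) -> dict[str, list[str]]:
    by_lang: dict[str, list[str]] = {}
    for text, lang in sorted(onto.labels_of(entity)):
        by_lang.setdefault(lang or default_lang, []).append(text)
    return by_lang


def _concept_context_labels(onto: Ontology, neighbours, cfg) -> list[str]:
    terms: list[str] = []
    for n in sorted(neighbours):
        for text in onto.label_strings(n):
            terms.extend(normalize(text, cfg))
    return terms


def build_virtual_document(
    onto: Ontology,
    entity: str,
    cfg: NormalizerConfig,
    *,
    extended: bool = False,
    mode: str = EXACT,
    with_context: bool = False,
    default_lang: str = "en",
) -> VirtualDocument:
    """Build the dVD (or eVD, with ``extended=True``) of an entity.

    ``with_context`` additionally stores the labels of the concept's
    siblings, descendants and ancestors in dedicated fields (an indexing
    optimisation for structure-aware retrieval).
    """
    kind = onto.kind_of(entity)
    doc = VirtualDocument(entity_id=entity, kind=kind, extended=extended)
    doc.add("uri", [entity])

    loc = onto.local_name_of(entity)
    loc_tokens = normalize(loc, cfg, stem=False)
    if kind == CONCEPT:
        # Table-style convention: concept local names are concatenated
        # unstemmed, property local names stemmed then concatenated.
        if mode == EXACT:
            doc.add("directNameC", [concatenate(loc_tokens)] if loc_tokens else [])
        else:
            doc.add("directNameC", [porter_stem(t) for t in loc_tokens])
    else:
        stemmed = [porter_stem(t) for t in loc_tokens]
        if mode == EXACT:
            doc.add("directNameP", [concatenate(stemmed)] if stemmed else [])
        else:
            doc.add("directNameP", stemmed)

    labels = _labels_by_lang(onto, entity, default_lang)
    for lang, texts in sorted(labels.items()):
        terms: list[str] = []
        for text in texts:
            terms.extend(_label_terms(text, cfg, mode))
        doc.add(_label_field_name(kind, lang), terms)

    for comment in sorted(onto.comments.get(entity, ())):
        doc.add("comments", normalize(comment, cfg))

    if kind in (OBJECT_PROPERTY, DATATYPE_PROPERTY):
        dom_terms: list[str] = []
        for dom in sorted(onto.property_domains(entity)):
            for text in onto.label_strings(dom) or [onto.local_name_of(dom)]:
                dom_terms.extend(normalize(text, cfg))
        doc.add("domainLabelsOP" if kind == OBJECT_PROPERTY else "domainLabelsDP", dom_terms)
        if kind == OBJECT_PROPERTY:
            rng_terms: list[str] = []
            for rng in sorted(onto.property_ranges(entity)):
                for text in onto.label_strings(rng) or [onto.local_name_of(rng)]:
                    rng_terms.extend(normalize(text, cfg))
            doc.add("rangeLabelsOP", rng_terms)
        else:
            rng_terms = []
            for dtype in sorted(onto.property_ranges(entity)):
                rng_terms.extend(normalize(dtype, cfg, stem=False))
            doc.add("dRange", rng_terms)
        doc.add(
            "propertyType",
            [porter_stem(c) for c in sorted(onto.property_constraints.get(entity, ()))],
        )

    if extended:
        if kind == CONCEPT:
            sup_labels: list[str] = []
            sup_names: list[str] = []
            for anc in sorted(onto.ancestors(entity)):
                for text in onto.label_strings(anc):
                    sup_labels.extend(normalize(text, cfg))
                sup_names.extend(normalize(onto.local_name_of(anc), cfg))
            doc.add("supLabels", sup_labels)
            doc.add("supLocalNames", sup_names)
        else:
            sup_names = []
            for sup in sorted(onto.super_properties(entity)):
                sup_names.extend(normalize(onto.local_name_of(sup), cfg))
            doc.add("supLocalNames", sup_names)

    if with_context and kind == CONCEPT:
        doc.add("sibLabels", _concept_context_labels(onto, onto.siblings(entity), cfg))
        doc.add("descLabels", _concept_context_labels(onto, onto.descendants(entity), cfg))
        doc.add("ancLabels", _concept_context_labels(onto, onto.ancestors(entity), cfg))

    if len(doc.fields) == 1:  # only the uri field
        logger.warning("entity %s has no label and no usable local name", entity)
    return doc
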