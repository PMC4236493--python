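"""Parsers turning OWL / RDF(S) / SKOS / OBO files into :class:`Ontology`.

RDF-based formats go through rdflib; OBO 1.4 flat files through obonet.
Only IRI-named entities are kept — anonymous (blank-node) classes such as
OWL restrictions are not matchable and are skipped.  SKOS ``broader`` and
OBO ``is_a`` both populate the is-a taxonomy; SKOS ``related`` becomes a
transversal relation.
"""

from __future__ import annotations

import logging
import re

import rdflib
from rdflib import RDF, RDFS, OWL, URIRef, Literal
from rdflib.namespace import SKOS

from .ontology import Ontology

logger = logging.getLogger(__name__)

__all__ = ["load_ontology", "OntologyFormatError"]


class OntologyFormatError(ValueError):
    """The input file could not be parsed in the declared/sniffed format."""


_RDF_FORMATS = {"owl": None, "rdfs": None, "skos": None}
_SYNONYM_RE = re.compile(r'"((?:[^"\\]|\\.)*)"')


def load_ontology(path: str, fmt: str | None = None) -> Ontology:
    """Parse an ontology file.

    Parameters
    ----------
    path:
        File to read.
    fmt:
        One of ``owl``, ``rdfs``, ``skos``, ``obo`` or None to sniff from
        the file extension (.obo -> OBO, anything else -> RDF with
        rdflib's format guessing).
    """
    fmt = (fmt or "").lower() or None
    if fmt == "obo" or (fmt is None and str(path).endswith(".obo")):
        onto = _load_obo(path)
    elif fmt in _RDF_FORMATS or fmt is None:
        onto = _load_rdf(path)
    else:
        raise OntologyFormatError(f"unknown ontology format: {fmt!r}")
    if not onto.concepts:
        logger.warning("loaded ontology %s contains no concepts", path)
    onto.break_cycles()
    return onto


# ---------------------------------------------------------------- RDF


def _load_rdf(path: str) -> Ontology:
    graph = rdflib.Graph()
    guessed = rdflib.util.guess_format(str(path)) or "xml"
    last_error: Exception | None = None
    for rdf_format in dict.fromkeys([guessed, "xml", "turtle"]):
        try:
            graph.parse(str(path), format=rdf_format)
            break
        except Exception as exc:  # noqa: BLE001 - rdflib raises many types
            last_error = exc
    else:
        raise OntologyFormatError(f"cannot parse {path}: {last_error}") from last_error

    onto = Ontology(name=str(path))

    # Concepts: owl:Class, rdfs:Class, skos:Concept plus subclass endpoints.
    for cls_type in (OWL.Class, RDFS.Class, SKOS.Concept):
        for s in graph.subjects(RDF.type, cls_type):
            if isinstance(s, URIRef):
                onto.add_concept(str(s))
    for child, parent in graph.subject_objects(RDFS.subClassOf):
        if isinstance(child, URIRef) and isinstance(parent, URIRef):
            onto.add_isa(str(parent), str(child))
    for child, parent in graph.subject_objects(SKOS.broader):
        if isinstance(child, URIRef) and isinstance(parent, URIRef):
            onto.add_isa(str(parent), str(child))
    for a, b in graph.subject_objects(SKOS.related):
        if isinstance(a, URIRef) and isinstance(b, URIRef):
            onto.concepts.update((str(a), str(b)))
            onto.transversal_relations.add((str(a), str(b), "related"))

    # Properties.
    for s in graph.subjects(RDF.type, OWL.ObjectProperty):
        if isinstance(s, URIRef):
            onto.object_properties.add(str(s))
    for s in graph.subjects(RDF.type, OWL.DatatypeProperty):
        if isinstance(s, URIRef):
            onto.datatype_properties.add(str(s))
    for s in graph.subjects(RDF.type, OWL.FunctionalProperty):
        if isinstance(s, URIRef):
            onto.property_constraints.setdefault(str(s), set()).add("functional")
    for sub, sup in graph.subject_objects(RDFS.subPropertyOf):
        if isinstance(sub, URIRef) and isinstance(sup, URIRef):
            onto.property_hierarchy.add((str(sup), str(sub)))

    all_props = onto.object_properties | onto.datatype_properties
    for prop in all_props:
        p = URIRef(prop)
        domains = [str(d) for d in graph.objects(p, RDFS.domain) if isinstance(d, URIRef)]
        ranges = list(graph.objects(p, RDFS.range))
        if prop in onto.object_properties:
            rng_iris = [str(r) for r in ranges if isinstance(r, URIRef)]
            for dom in domains or [""]:
                for rng in rng_iris or [""]:
                    if dom or rng:
                        onto.transversal_relations.add((dom, rng, prop))
        else:
            for dom in domains or [""]:
                for rng in ranges or [None]:
                    dtype = _datatype_name(rng) if rng is not None else "xsd string"
                    onto.attributes.add((dom, dtype, prop))

    # Labels: rdfs:label, skos:prefLabel/altLabel.
    named = set(onto.concepts) | all_props
    for predicate in (RDFS.label, SKOS.prefLabel, SKOS.altLabel):
        for s, o in graph.subject_objects(predicate):
            if isinstance(s, URIRef) and isinstance(o, Literal) and str(s) in named:
                onto.add_label(str(s), str(o), o.language or "")
    for s, o in graph.subject_objects(RDFS.comment):
        if isinstance(s, URIRef) and isinstance(o, Literal) and str(s) in named:
            onto.comments.setdefault(str(s), set()).add(str(o))

    # Disjointness: explicit owl:disjointWith plus pairwise members of
    # owl:AllDisjointClasses; nothing is inferred.
    for a, b in graph.subject_objects(OWL.disjointWith):
        if isinstance(a, URIRef) and isinstance(b, URIRef):
            onto.add_disjoint(str(a), str(b))
    for axiom in graph.subjects(RDF.type, OWL.AllDisjointClasses):
        for members in graph.objects(axiom, OWL.members):
            items = [str(i) for i in graph.items(members) if isinstance(i, URIRef)]
            for i, a in enumerate(items):
                for b in items[i + 1:]:
                    onto.add_disjoint(a, b)

    return onto


def _datatype_name(rng) -> str:
    text = str(rng)
    if "#" in text:
        return "xsd " + text.rsplit("#", 1)[1]
    return text


# ---------------------------------------------------------------- OBO


def _load_obo(path: str) -> Ontology:
    import obonet

    try:
        graph = obonet.read_obo(str(path))
    except Exception as exc:  # noqa: BLE001
        raise OntologyFormatError(f"cannot parse OBO file {path}: {exc}") from exc

    onto = Ontology(name=str(path))
    prefix = "http://purl.obolibrary.org/obo/"

    def iri(term_id: str) -> str:
        return prefix + term_id.replace(":", "_")

    for term_id, data in graph.nodes(data=True):
        c = iri(term_id)
        onto.add_concept(c)
        if data.get("name"):
            onto.add_label(c, data["name"], "")
        for syn in data.get("synonym", ()):
            m = _SYNONYM_RE.search(syn)
            if m:
                onto.add_label(c, m.group(1), "")
        if data.get("def"):
            m = _SYNONYM_RE.search(data["def"])
            if m:
                onto.comments.setdefault(c, set()).add(m.group(1))

    # obonet edges run child -> parent with the relation as key.
    for child, parent, key in graph.edges(keys=True):
        if key == "is_a":
            onto.add_isa(iri(parent), iri(child))
        else:
            onto.concepts.update((iri(child), iri(parent)))
            onto.transversal_relations.add((iri(child), iri(parent), key))
    return onto
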