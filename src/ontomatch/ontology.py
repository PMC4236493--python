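"""In-memory ontology model and structural queries.

An ontology here is the 5-tuple view used throughout the matcher: a concept
set, an is-a taxonomy over it, transversal (object-property) relations,
datatype attributes, a property hierarchy, and the multilingual label map.
Any knowledge organisation system — thesaurus, controlled vocabulary or
formal ontology — is reduced to this shape on loading, which is all the
lexical/structural matching pipeline needs.

Entity identity is the full IRI; the local name is the fragment after '#'
or the last '/'.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field

logger = logging.getLogger(__name__)

CONCEPT = "concept"
OBJECT_PROPERTY = "object-property"
DATATYPE_PROPERTY = "datatype-property"


def local_name(iri: str) -> str:
    """Fragment after '#', else after the last '/'."""
    if "#" in iri:
        return iri.rsplit("#", 1)[1]
    return iri.rstrip("/").rsplit("/", 1)[-1]


class UnknownEntityError(KeyError):
    """Raised by structural queries on an entity not in the ontology."""


@dataclass
class Ontology:
    """Concepts, properties, taxonomy and labels of one input ontology."""

    name: str = ""
    concepts: set[str] = field(default_factory=set)
    #: (parent, child) pairs: parent subsumes child.
    isa_edges: set[tuple[str, str]] = field(default_factory=set)
    #: (subject concept, object concept, property IRI)
    transversal_relations: set[tuple[str, str, str]] = field(default_factory=set)
    #: (subject concept, primitive datatype, property IRI)
    attributes: set[tuple[str, str, str]] = field(default_factory=set)
    object_properties: set[str] = field(default_factory=set)
    datatype_properties: set[str] = field(default_factory=set)
    #: (super property, sub property)
    property_hierarchy: set[tuple[str, str]] = field(default_factory=set)
    #: entity -> {(label string, language tag)}
    labels: dict[str, set[tuple[str, str]]] = field(default_factory=dict)
    comments: dict[str, set[str]] = field(default_factory=dict)
    #: property -> {"functional", ...}
    property_constraints: dict[str, set[str]] = field(default_factory=dict)
    #: unordered pairs of concepts declared disjoint
    disjointness: set[frozenset[str]] = field(default_factory=set)

    def __post_init__(self) -> None:
        self._parents: dict[str, set[str]] | None = None
        self._children: dict[str, set[str]] | None = None

    # -- construction ----------------------------------------------------

    def add_concept(self, iri: str) -> None:
        self.concepts.add(iri)

    def add_isa(self, parent: str, child: str) -> None:
        self.concepts.add(parent)
        self.concepts.add(child)
        self.isa_edges.add((parent, child))
        self._parents = self._children = None

    def add_label(self, entity: str, text: str, lang: str = "en") -> None:
        if not text:
            return
        self.labels.setdefault(entity, set()).add((text, lang))

    def add_disjoint(self, c1: str, c2: str) -> None:
        if c1 != c2:
            self.disjointness.add(frozenset((c1, c2)))

    def break_cycles(self) -> int:
        """Drop is-a back-edges until the taxonomy is acyclic.

        Input taxonomies are assumed to be DAGs; a cycle is treated as a
        data defect and the edge encountered last in (sorted) load order is
        dropped with a warning.  Returns the number of edges removed.
        """
        removed = 0
        while True:
            cycle_edge = self._find_cycle_edge()
            if cycle_edge is None:
                return removed
            logger.warning("is-a cycle detected; dropping edge %s -> %s", *cycle_edge)
            self.isa_edges.discard(cycle_edge)
            self._parents = self._children = None
            removed += 1

    def _find_cycle_edge(self) -> tuple[str, str] | None:
        children = defaultdict(list)
        for parent, child in sorted(self.isa_edges):
            children[parent].append(child)
        WHITE, GREY, BLACK = 0, 1, 2
        colour: dict[str, int] = defaultdict(int)
        for root in sorted(children):
            if colour[root] != WHITE:
                continue
            stack: list[tuple[str, iter]] = [(root, iter(children[root]))]
            colour[root] = GREY
            while stack:
                node, it = stack[-1]
                advanced = False
                for nxt in it:
                    if colour[nxt] == GREY:
                        return (node, nxt)
                    if colour[nxt] == WHITE:
                        colour[nxt] = GREY
                        stack.append((nxt, iter(children[nxt])))
                        advanced = True
                        break
                if not advanced:
                    colour[node] = BLACK
                    stack.pop()
        return None

    # -- derived views ---------------------------------------------------

    def _adjacency(self) -> tuple[dict[str, set[str]], dict[str, set[str]]]:
        if self._parents is None or self._children is None:
            parents: dict[str, set[str]] = defaultdict(set)
            children: dict[str, set[str]] = defaultdict(set)
            for parent, child in self.isa_edges:
                parents[child].add(parent)
                children[parent].add(child)
            self._parents, self._children = dict(parents), dict(children)
        return self._parents, self._children

    def entities(self):
        """All matchable entities: concepts then properties, sorted."""
        yield from sorted(self.concepts)
        yield from sorted(self.object_properties)
        yield from sorted(self.datatype_properties)

    def kind_of(self, entity: str) -> str:
        if entity in self.concepts:
            return CONCEPT
        if entity in self.object_properties:
            return OBJECT_PROPERTY
        if entity in self.datatype_properties:
            return DATATYPE_PROPERTY
        raise UnknownEntityError(entity)

    def local_name_of(self, entity: str) -> str:
        return local_name(entity)

    def labels_of(self, entity: str) -> set[tuple[str, str]]:
        return self.labels.get(entity, set())

    def label_strings(self, entity: str) -> list[str]:
        """Label texts plus the local name, deduplicated, sorted."""
        texts = {text for text, _lang in self.labels.get(entity, ())}
        return sorted(texts)

    def property_domains(self, prop: str) -> set[str]:
        out = {s for (s, _o, p) in self.transversal_relations if p == prop} | {
            s for (s, _d, p) in self.attributes if p == prop
        }
        out.discard("")
        return out

    def property_ranges(self, prop: str) -> set[str]:
        """Concept IRIs for object properties, datatype names for attributes."""
        out = {o for (_s, o, p) in self.transversal_relations if p == prop} | {
            d for (_s, d, p) in self.attributes if p == prop
        }
        out.discard("")
        return out

    def super_properties(self, prop: str) -> set[str]:
        return {sup for (sup, sub) in self.property_hierarchy if sub == prop}

    # -- structural queries ----------------------------------------------

    def _require_concept(self, c: str) -> None:
        if c not in self.concepts:
            raise UnknownEntityError(c)

    def descendants(self, c: str) -> set[str]:
        """Direct (depth-1) children of c in the is-a taxonomy."""
        self._require_concept(c)
        _parents, children = self._adjacency()
        return set(children.get(c, ()))

    def ancestors(self, c: str) -> set[str]:
        """Direct (depth-1) parents of c in the is-a taxonomy."""
        self._require_concept(c)
        parents, _children = self._adjacency()
        return set(parents.get(c, ()))

    def siblings(self, c: str) -> set[str]:
        """Concepts sharing at least one direct parent with c, excluding c."""
        self._require_concept(c)
        out: set[str] = set()
        for parent in self.ancestors(c):
            out |= self.descendants(parent)
        out.discard(c)
        return out

    def _bfs_depths(self, c: str, max_depth: int, down: bool) -> dict[str, int]:
        parents, children = self._adjacency()
        adj = children if down else parents
        depths = {c: 0}
        frontier = [c]
        for depth in range(1, max_depth + 1):
            nxt = []
            for node in frontier:
                for nb in adj.get(node, ()):
                    if nb not in depths:
                        depths[nb] = depth
                        nxt.append(nb)
            frontier = nxt
        depths.pop(c)
        return depths

    def desc_k(self, c: str, k: int) -> set[str]:
        """Transitive descendants up to depth k."""
        self._require_concept(c)
        return set(self._bfs_depths(c, k, down=True))

    def anc_k(self, c: str, k: int) -> set[str]:
        """Transitive ancestors up to depth k."""
        self._require_concept(c)
        return set(self._bfs_depths(c, k, down=False))

    def depth_below(self, ancestor: str, c: str, max_depth: int) -> int | None:
        """Shortest is-a depth of c below ancestor, None if not within reach."""
        self._require_concept(ancestor)
        return self._bfs_depths(ancestor, max_depth, down=True).get(c)

    def depth_above(self, descendant: str, c: str, max_depth: int) -> int | None:
        """Shortest is-a depth of c above descendant, None if not within reach."""
        self._require_concept(descendant)
        return self._bfs_depths(descendant, max_depth, down=False).get(c)

    def all_descendants(self, c: str) -> set[str]:
        """Full transitive descendant closure."""
        return self.desc_k(c, len(self.concepts))

    def all_ancestors(self, c: str) -> set[str]:
        """Full transitive ancestor closure."""
        return self.anc_k(c, len(self.concepts))

    def are_disjoint(self, c1: str, c2: str) -> bool:
        return frozenset((c1, c2)) in self.disjointness

    def validate(self) -> None:
        """Check the model invariants; raises ValueError on violation."""
        for parent, child in self.isa_edges:
            if parent not in self.concepts or child not in self.concepts:
                raise ValueError(f"is-a edge endpoint not declared: {(parent, child)}")
        for entity, labs in self.labels.items():
            for text, _lang in labs:
                if not text:
                    raise ValueError(f"empty label on {entity}")
        if self._find_cycle_edge() is not None:
            raise ValueError("is-a taxonomy is cyclic")


@dataclass(frozen=True)
class MatchTaskProfile:
    """Size/language metadata computed before matching; both input
    ontologies under 500 concepts counts as a small task."""

    n_concepts_1: int
    n_concepts_2: int
    n_properties_1: int
    n_properties_2: int
    languages: frozenset[str]
    size_category: str
    level: str = "entity"

    SMALL_LIMIT = 500


def profile_task(o1: Ontology, o2: Ontology) -> MatchTaskProfile:
    """Compute counts, detected languages and the size category."""
    languages = set()
    for o in (o1, o2):
        for labs in o.labels.values():
            for _text, lang in labs:
                languages.add(lang or "en")
    if not languages:
        languages = {"en"}
    small = (
        len(o1.concepts) < MatchTaskProfile.SMALL_LIMIT
        and len(o2.concepts) < MatchTaskProfile.SMALL_LIMIT
    )
    return MatchTaskProfile(
        n_concepts_1=len(o1.concepts),
        n_concepts_2=len(o2.concepts),
        n_properties_1=len(o1.object_properties) + len(o1.datatype_properties),
        n_properties_2=len(o2.object_properties) + len(o2.datatype_properties),
        languages=frozenset(languages),
        size_category="small" if small else "large",
    )
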