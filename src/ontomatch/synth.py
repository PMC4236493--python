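"""Synthetic ontology-pair generator for evaluation and testing.

Real biomedical terminologies pair multi-word labels with UMLS-style
synonym lists (word-order permutations, alternative phrasings), is-a
taxonomies, object/datatype properties and occasional disjointness axioms.
The generator emulates exactly that: it builds a random is-a tree whose
concepts carry multi-word labels drawn from an anatomical/clinical word
pool, then derives a second ontology by copying the structure and
perturbing each concept's label — word-permuted, replaced by a synonym
phrase (recorded in an emitted lexicon), or replaced by an opaque random
string — and deleting a fraction of concepts.  The surviving copy pairs
form the reference alignment, so precision and recall of the matcher are
exactly measurable.

All randomness flows from the single seed in the spec; the same spec
yields byte-identical ontologies, lexicon and reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .ontology import Ontology

__all__ = ["GeneratorSpec", "GeneratedPair", "generate_pair", "write_turtle", "write_lexicon"]

#: Anatomical/clinical word pool used for labels.
WORD_POOL = (
    "thoracic vertebral foramen cardiac muscle tissue lung lobe bronchus "
    "artery vein capillary nerve ganglion cortex medulla membrane epithelium "
    "gland duct follicle node vessel chamber ventricle atrium valve septum "
    "bone cartilage joint ligament tendon fascia skull femur tibia rib "
    "sternum clavicle scapula humerus radius ulna carpal digit phalanx "
    "kidney nephron glomerulus ureter bladder urethra liver hepatic biliary "
    "pancreas islet spleen thymus marrow lymph plasma serum erythrocyte "
    "leukocyte platelet neuron axon dendrite synapse glia retina cornea "
    "lens iris cochlea tympanic mucosa serosa gastric duodenal ileal "
    "colonic rectal esophageal pharyngeal laryngeal tracheal pleural "
    "peritoneal pericardial synovial dermal epidermal subcutaneous "
    "squamous columnar cuboidal ciliated secretory sensory motor "
    "afferent efferent proximal distal medial lateral anterior posterior "
    "superior inferior dorsal ventral cranial caudal left right upper lower "
    "primary secondary accessory deep superficial internal external "
    "ascending descending transverse oblique circular longitudinal "
    "acute chronic benign malignant infarction carcinoma sarcoma lesion "
    "syndrome disorder deficiency stenosis atrophy hypertrophy edema "
    "fibrosis necrosis inflammation embolism thrombosis aneurysm"
)
WORD_POOL = tuple(WORD_POOL.split())


@dataclass(frozen=True)
class GeneratorSpec:
    """Parameters of one synthetic matching task.

    The label-perturbation probabilities partition the copied concepts:
    a concept's target-side label is word-permuted with p_permute,
    replaced by a lexicon synonym with p_synonym, replaced by an opaque
    random string with p_opaque, and kept verbatim otherwise; independent
    of that, a p_unmatched fraction of concepts is deleted from the copy.
    """

    seed: int = 0
    n_concepts: int = 200
    branching: float = 3.0
    label_lexicon: tuple[str, ...] = WORD_POOL
    p_permute: float = 0.2
    p_synonym: float = 0.1
    p_opaque: float = 0.1
    p_unmatched: float = 0.1
    n_properties: int = 8
    p_disjoint_siblings: float = 0.1
    p_extra_label: float = 0.3  # chance of a permuted alt-label (synonym list)

    def __post_init__(self) -> None:
        if self.n_concepts < 2:
            raise ValueError("n_concepts must be >= 2")
        probs = (
            self.p_permute, self.p_synonym, self.p_opaque,
            self.p_unmatched, self.p_disjoint_siblings, self.p_extra_label,
        )
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("probabilities must lie in [0, 1]")
        if self.p_permute + self.p_synonym + self.p_opaque > 1.0 + 1e-12:
            raise ValueError("p_permute + p_synonym + p_opaque must be <= 1")
        if self.branching <= 0:
            raise ValueError("branching must be positive")


@dataclass
class GeneratedPair:
    """A synthetic matching task: two ontologies, the gold alignment, the
    synonym lexicon used, and the per-concept perturbation record."""

    o1: Ontology
    o2: Ontology
    reference: set[tuple[str, str]] = field(default_factory=set)
    lexicon: dict[str, set[str]] = field(default_factory=dict)
    transforms: dict[str, str] = field(default_factory=dict)


SRC_NS = "http://example.org/source#"
TGT_NS = "http://example.org/target#"


def _sample_label(rng, pool, used: set[frozenset[str]]) -> list[str]:
    while True:
        k = int(rng.integers(2, 5))
        words = list(rng.choice(len(pool), size=k, replace=False))
        label = [pool[i] for i in words]
        key = frozenset(label)
        if key not in used and len(key) == k:
            used.add(key)
            return label


def _opaque_label(rng) -> list[str]:
    n = int(rng.integers(2, 4))
    return [
        "".join(chr(97 + c) for c in rng.integers(0, 26, size=int(rng.integers(5, 9))))
        for _ in range(n)
    ]


def _permuted(rng, words: list[str]) -> list[str]:
    if len(words) < 2:
        return list(words)
    while True:
        order = rng.permutation(len(words))
        out = [words[i] for i in order]
        if out != list(words):
            return out


def generate_pair(spec: GeneratorSpec) -> GeneratedPair:
    """Build the source/target ontology pair with its reference alignment."""
    rng = np.random.default_rng(spec.seed)
    pool = tuple(spec.label_lexicon)
    n = spec.n_concepts

    # --- is-a tree of O1: breadth-first, Poisson(branching) children.
    parent: list[int | None] = [None]
    frontier = [0]
    while len(parent) < n:
        nxt: list[int] = []
        for node in frontier:
            k = max(1, int(rng.poisson(spec.branching)))
            for _ in range(k):
                if len(parent) >= n:
                    break
                parent.append(node)
                nxt.append(len(parent) - 1)
        frontier = nxt or [int(rng.integers(0, len(parent)))]

    used_labels: set[frozenset[str]] = set()
    labels1 = [_sample_label(rng, pool, used_labels) for _ in range(n)]
    extra1: list[list[list[str]]] = []
    for i in range(n):
        alts = []
        if len(labels1[i]) >= 2 and rng.random() < spec.p_extra_label:
            alts.append(_permuted(rng, labels1[i]))
        extra1.append(alts)

    # --- per-concept perturbation of the copy.
    transforms: list[str] = []
    labels2: list[list[str]] = []
    lexicon: dict[str, set[str]] = {}
    for i in range(n):
        u = rng.random()
        if u < spec.p_permute:
            transforms.append("permuted")
            labels2.append(_permuted(rng, labels1[i]))
        elif u < spec.p_permute + spec.p_synonym:
            transforms.append("synonym")
            syn = _sample_label(rng, pool, used_labels)
            labels2.append(syn)
            lexicon.setdefault(" ".join(labels1[i]), set()).add(" ".join(syn))
        elif u < spec.p_permute + spec.p_synonym + spec.p_opaque:
            transforms.append("opaque")
            labels2.append(_opaque_label(rng))
        else:
            transforms.append("identity")
            labels2.append(list(labels1[i]))

    # --- deletions from the copy (root kept to preserve connectivity).
    deleted = [False] * n
    for i in range(1, n):
        if rng.random() < spec.p_unmatched:
            deleted[i] = True

    def surviving_parent(i: int) -> int | None:
        p = parent[i]
        while p is not None and deleted[p]:
            p = parent[p]
        return p

    # --- opaque, shuffled identifiers on both sides.
    ids1 = rng.permutation(10 * n)[:n]
    ids2 = rng.permutation(10 * n)[:n]
    iri1 = [f"{SRC_NS}A{ids1[i]:06d}" for i in range(n)]
    iri2 = [f"{TGT_NS}B{ids2[i]:06d}" for i in range(n)]

    o1 = Ontology(name="source")
    o2 = Ontology(name="target")
    for i in range(n):
        o1.add_concept(iri1[i])
        o1.add_label(iri1[i], " ".join(labels1[i]), "en")
        for alt in extra1[i]:
            o1.add_label(iri1[i], " ".join(alt), "en")
        if parent[i] is not None:
            o1.add_isa(iri1[parent[i]], iri1[i])
    for i in range(n):
        if deleted[i]:
            continue
        o2.add_concept(iri2[i])
        o2.add_label(iri2[i], " ".join(labels2[i]), "en")
        sp = surviving_parent(i)
        if sp is not None:
            o2.add_isa(iri2[sp], iri2[i])

    # --- disjoint sibling axioms, mirrored where both children survive.
    children: dict[int, list[int]] = {}
    for i in range(1, n):
        children.setdefault(parent[i], []).append(i)
    for p, kids in sorted(children.items()):
        if len(kids) >= 2 and rng.random() < spec.p_disjoint_siblings:
            a, b = kids[0], kids[1]
            o1.add_disjoint(iri1[a], iri1[b])
            if not deleted[a] and not deleted[b]:
                o2.add_disjoint(iri2[a], iri2[b])

    # --- properties: shared names, random domains/ranges.
    n_obj = spec.n_properties // 2
    for j in range(spec.n_properties):
        w1, w2 = (pool[i] for i in rng.choice(len(pool), size=2, replace=False))
        local = f"has_{w1}_{w2}"
        p1, p2 = SRC_NS + local, TGT_NS + local
        dom, rng_c = int(rng.integers(0, n)), int(rng.integers(0, n))
        if j < n_obj:
            o1.object_properties.add(p1)
            o1.transversal_relations.add((iri1[dom], iri1[rng_c], p1))
            o2.object_properties.add(p2)
            if not deleted[dom] and not deleted[rng_c]:
                o2.transversal_relations.add((iri2[dom], iri2[rng_c], p2))
        else:
            o1.datatype_properties.add(p1)
            o1.attributes.add((iri1[dom], "xsd string", p1))
            o2.datatype_properties.add(p2)
            if not deleted[dom]:
                o2.attributes.add((iri2[dom], "xsd string", p2))
        o1.add_label(p1, f"has {w1} {w2}", "en")
        o2.add_label(p2, f"has {w1} {w2}", "en")
        if rng.random() < 0.5:
            o1.property_constraints.setdefault(p1, set()).add("functional")
            o2.property_constraints.setdefault(p2, set()).add("functional")

    reference = {(iri1[i], iri2[i]) for i in range(n) if not deleted[i]}
    for p1 in sorted(o1.object_properties | o1.datatype_properties):
        p2 = TGT_NS + p1.rsplit("#", 1)[1]
        if p2 in o2.object_properties | o2.datatype_properties:
            reference.add((p1, p2))
    transform_map = {iri1[i]: ("unmatched" if deleted[i] else transforms[i]) for i in range(n)}
    return GeneratedPair(
        o1=o1, o2=o2, reference=reference, lexicon=lexicon, transforms=transform_map
    )


# ---------------------------------------------------------------- output


def _turtle_escape(s: str) -> str:
    return s.replace("\\", "\\\\").replace('"', '\\"')


def write_turtle(onto: Ontology, path: str, style: str = "owl") -> None:
    """Serialize a generated ontology as Turtle, OWL- or SKOS-flavoured,
    with sorted triples (byte-reproducible)."""
    if style not in ("owl", "skos"):
        raise ValueError("style must be 'owl' or 'skos'")
    lines = [
        "@prefix rdf: <http://www.w3.org/1999/02/22-rdf-syntax-ns#> .",
        "@prefix rdfs: <http://www.w3.org/2000/01/rdf-schema#> .",
        "@prefix owl: <http://www.w3.org/2002/07/owl#> .",
        "@prefix skos: <http://www.w3.org/2004/02/skos/core#> .",
        "@prefix xsd: <http://www.w3.org/2001/XMLSchema#> .",
        "",
    ]
    triples: list[tuple[str, str, str]] = []
    cls = "owl:Class" if style == "owl" else "skos:Concept"
    label_pred = "rdfs:label" if style == "owl" else "skos:prefLabel"
    alt_pred = "rdfs:label" if style == "owl" else "skos:altLabel"
    for c in sorted(onto.concepts):
        triples.append((f"<{c}>", "rdf:type", cls))
        first = True
        for text, lang in sorted(onto.labels_of(c)):
            pred = label_pred if first else alt_pred
            first = False
            tag = f"@{lang}" if lang else ""
            triples.append((f"<{c}>", pred, f'"{_turtle_escape(text)}"{tag}'))
    for p, c in sorted(onto.isa_edges):
        if style == "owl":
            triples.append((f"<{c}>", "rdfs:subClassOf", f"<{p}>"))
        else:
            triples.append((f"<{c}>", "skos:broader", f"<{p}>"))
    if style == "owl":
        for pair in sorted(tuple(sorted(d)) for d in onto.disjointness):
            triples.append((f"<{pair[0]}>", "owl:disjointWith", f"<{pair[1]}>"))
        for prop in sorted(onto.object_properties):
            triples.append((f"<{prop}>", "rdf:type", "owl:ObjectProperty"))
        for prop in sorted(onto.datatype_properties):
            triples.append((f"<{prop}>", "rdf:type", "owl:DatatypeProperty"))
        for prop in sorted(onto.object_properties | onto.datatype_properties):
            for text, lang in sorted(onto.labels_of(prop)):
                tag = f"@{lang}" if lang else ""
                triples.append((f"<{prop}>", "rdfs:label", f'"{_turtle_escape(text)}"{tag}'))
            for dom in sorted(onto.property_domains(prop)):
                triples.append((f"<{prop}>", "rdfs:domain", f"<{dom}>"))
            for rng in sorted(onto.property_ranges(prop)):
                if rng.startswith("http"):
                    triples.append((f"<{prop}>", "rdfs:range", f"<{rng}>"))
                elif rng.startswith("xsd "):
                    triples.append((f"<{prop}>", "rdfs:range", f"xsd:{rng.split()[1]}"))
            if "functional" in onto.property_constraints.get(prop, ()):
                triples.append((f"<{prop}>", "rdf:type", "owl:FunctionalProperty"))
    for s, p, o in sorted(triples):
        lines.append(f"{s} {p} {o} .")
    lines.append("")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines))


def write_lexicon(lexicon: dict[str, set[str]], path: str) -> None:
    """Emit the synonym lexicon as a two-column TSV (term, synonym)."""
    with open(path, "w", encoding="utf-8") as fh:
        for term in sorted(lexicon):
            for syn in sorted(lexicon[term]):
                fh.write(f"{term}\t{syn}\n")
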