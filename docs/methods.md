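# Methods

This note documents the models, parameters and numerical choices behind
`ontomatch`, the assumptions they rest on, and what the synthetic
evaluation does and does not show.

## The ontology model

An input is reduced to ⟨C°, R, H_r, T, Lex⟩: a set of concept IRIs, an
is-a taxonomy R_I (OWL `subClassOf`, SKOS `broader`, OBO `is_a` all map
here), transversal relations R_T and datatype attributes R_D with their
property hierarchy H_r, and a multilingual label map (rdfs:label, SKOS
pref/altLabel, OBO name/synonym). Only IRI-named entities are matchable;
anonymous classes (OWL restrictions) are skipped. Disjointness is taken
only from explicit `owl:disjointWith` and pairwise `AllDisjointClasses`
members — no reasoning is performed, matching the package's
no-classification scope. Is-a cycles are treated as data defects: the
back-edge encountered last in sorted load order is dropped with a
warning, since the downstream stages assume a taxonomy. Untagged label
literals default to English.

## Virtual documents and indexing

Every entity becomes a fielded document (uri, local name, per-language
labels, comments; property documents add domain/range labels, the range
datatype, and constraint flags). The extended document of a concept adds
its direct ancestors' labels and local names; for a property, its
super-properties' local names. Field generation is dynamic — an entity
without comments simply has no comments field.

The filter chain is: camelCase/underscore splitting → lowercasing →
non-alphanumeric removal → stopword removal → spelling out standalone
integers 0–999 ("T9" → "t nine", so a ninth vertebra and a T9 vertebra
share a token) → Porter stemming. Porter reproduces the stems biomedical
matchers conventionally show for this vocabulary ("thoracic vertebral
foramen" → `thoracvertebrforamen` in concatenated form). Permutation
enrichment generates all orderings of the first four words (4! = 24 at
most; labels longer than four words keep their tail in original order —
beyond four words the factorial cost buys nothing, as multi-word
biomedical terms rarely permute past that depth). Permutation applies
after stopword/symbol removal and before stemming. Stemming is applied
exactly once; the chain is not idempotent (Porter maps "synapse" →
"synaps" → "synap"), which is harmless because index-side and query-side
terms are produced by the identical single pass.

Two indexing strategies: *exact* stores each label's stemmed permuted
concatenations as single terms (high-precision whole-label matching);
*relaxed* stores token streams (used for extended documents). Retrieval
scoring is the true cosine of tf-idf-weighted fielded vectors,
w(f, t) = √tf · (1 + ln(N/(1+df))) · √boost(f); uri is down-weighted to
0.5 and comments to 0.25 since they mostly duplicate or dilute label
evidence. A pure cosine (rather than an engine-specific scoring function
with coordination factors and lossy length norms) keeps the sparse
inverted-index computation exactly rank-equivalent to a dense
linear-algebra evaluation of the same formula, which the test suite
verifies on random corpora; any per-query normalisation constant would
cancel in ranking anyway.

## Lexical candidate generation

Both ontologies are indexed in exact mode and searched both ways; the
directed top-k lists (k = 3, engine score ≥ 0.1) are intersected — the
strict both-directions reading, which sacrifices some recall for high
precision; `require_both=false` relaxes it to the union. Surviving pairs
pass Sim_lex ≥ θ with Sim_lex = α·ISub + β·QGram + γ·Levenshtein
(α=0.4, β=0.3, γ=0.3, θ=0.75 by default; ISub gets the largest weight as
the measure designed for ontology labels). Each component is the maximum
over the label-pair cross product, so multi-synonym entities match as
soon as one synonym pair agrees.

Sim_lex operates on normalized pre-stem label strings whose tokens are
put in canonical (sorted) order. Rationale: the index stage is word-order
invariant by construction, and UMLS-style synonym lists treat
permutations as the same term; computing the θ filter on raw order would
veto exactly the permuted matches the index was built to find. The metric
functions themselves remain order-sensitive; canonical ordering is a
pipeline decision.

ISub is implemented per its published structure — greedy removal of
longest common substrings (length ≥ 2), commonality minus a
Hamacher-normalised difference (p = 0.6) plus a Winkler prefix bonus —
and clamped from its native [−1, 1] to [0, 1] by (x+1)/2. The greedy
substring removal is tie-break dependent, so arguments are processed in a
fixed lexicographic order to make the measure symmetric. Q-gram uses
q = 3 with boundary padding and Dice normalisation. Levenshtein switches
to a row-vectorised numpy formulation above ~4k cell evaluations (same
recurrence, cross-checked against the scalar DP and against edlib).

Properties run the same two-way + θ pipeline, restricted to
kind-compatible pairs (object↔object, datatype↔datatype).

## Extended stage

Concepts missed by the exact stage are re-searched over relaxed-mode
extended documents, so ancestor-derived text can carry pairs whose own
labels differ modestly; the same θ filter applies. The synonym bridge
then substitutes lexicon entries (whole word or whole phrase, one
substitution per expansion, deliberately single-hop — chaining a→b→c
would compound lexicon noise) into each residual label and proposes a
pair when an expanded label equals a label of the other side as an
exact whole-label form. Bridged pairs score max(Sim_lex, θ_syn) with
θ_syn = θ: the lexicon asserts synonymy, so the pair should not enter
below the acceptance bar. The lexicon is pluggable (TSV term/synonym in
normalized form); a general-purpose dictionary such as WordNet can be
exported into this format, and the synthetic generator emits the lexicon
it used.

## Contextual stage

Anchors (M_exact) are assumed correct — the central assumption inherited
from the lexical stage's high precision; with lexically poor ontologies
the anchor set shrinks and the stage degrades gracefully (it aborts below
10 anchors). Candidate pairs (pcc) come from anchors' entourages with
already-mapped members excluded. Structural support is depth-weighted:
a matched descendant pair at depths (d1, d2) contributes
1/max(d1, d2) to score_sub (depth limit 2), analogously for ancestors;
matched sibling pairs contribute 1. The 1/depth kernel implements the
principle that remote supporting pairs count less, with the weight of a
direct child pair fixed at 1; siblings are not depth-weighted because
they sit at a fixed structural distance. Pairs with
s = score_sub + score_sup + score_sib > φ (default 0.5 — more than half
a direct-neighbour match of support) proceed to classification.

Training data is auto-labelled: each anchor is a "yes" row; for each
anchor, two concepts sampled (seeded) from the ancestors/descendants of
its right end form "no" rows — a concept cannot map both a concept and
its ancestor/descendant. Features are five string similarities (Q-gram,
Levenshtein, block distance, word Jaccard, Monge-Elkan) between the
concepts' neighbourhood texts: the normalized labels of the concept and
its direct ancestors, descendants and siblings, each section
token-sorted, properties excluded. Using the full direct neighbourhood
rather than ancestors alone is deliberate: with ancestor-only text, a
true pair whose own label is opaque and a negative (c1, parent(c2)) have
identical expected token overlap (each shares exactly the parent label),
leaving the features with no separating signal; descendant and sibling
labels break that tie because only the true pair's lower neighbourhood
aligns.

The classifier is an entropy-split decision tree (scikit-learn,
min_samples_leaf = 2, seeded) — the classical choice for this kind of
small, interpretable feature set; a human-readable dump is exposed. An
evenly split leaf predicts "no" (precision first). M_context triples
carry the leaf confidence as score.

## Post-processing

Filter order: disjointness → criss-cross → enrichment → greedy selection.
Both consistency checks are anchor-driven and never remove anchors
themselves (they define the constraints): a candidate pairing an
anchor's partner with a concept disjoint from the anchor is discarded,
and a candidate pairing one anchor end with a transitive ancestor or
descendant of the other end is discarded (full closures, not depth-1 —
a criss-cross two levels up is just as inconsistent). Enrichment proposes
still-unmapped direct-child pairs under mapped parents, gated by
Sim_lex ≥ θ rather than unconditionally, to preserve the pipeline's
precision-first character (config-removable). Greedy selection sorts by
score, breaking ties by provenance rank (exact > prop > extended >
context) then IRI pair, and enforces one-to-one unless 1:n is requested.
External logical-repair systems are a documented hook, not a dependency:
full coherence repair tends to discard correct mappings along with
incoherent ones, so the two trivial checks are the default.

## Synthetic evaluation: what it shows

The generator emulates the structure that makes biomedical matching
tractable for IR methods: a Poisson-branching is-a tree (mean 3 children),
2–4-word labels unique per ontology drawn from an anatomical/clinical
pool, optional permuted alt-labels (30% of concepts) imitating UMLS
synonym lists, shared properties, occasional disjoint-sibling axioms, and
opaque numeric identifiers so local names carry no matching signal. The
target copy perturbs labels per concept (defaults: 20% permuted, 10%
synonym-replaced with the substitution recorded in an emitted lexicon,
10% opaque random strings) and deletes 10% of concepts; survivors form
the reference alignment.

Default problem sizes in the tests and the acceptance script (300–500
concepts) exercise every stage at small-ontology scale. What passing
shows: exact recovery of unperturbed input, word-order invariance, the
synonym stage's recall contribution given a correct lexicon, the
contextual stage's ability to recover structurally anchored but lexically
opaque concepts, and filter soundness. What it does not show: behaviour
under the label ambiguity, polysemy, inconsistent taxonomies and
hundred-thousand-concept scale of real resources — real synonym lexicons
are noisy where the generated one is exact, and real hierarchies diverge
structurally where the generated copy differs only by deletions.

## Known limitations

The pipeline is anchored on lexical evidence end to end: ontologies with
poor terminological descriptions yield few anchors, which starves both
the contextual stage and the filters. Thresholds (θ, φ, MaxScore, k) are
fixed per run, not adapted to the task profile. Only equivalence mappings
are produced — no subsumption or disjointness orientation — and no
instance (ABox) matching is attempted. Cross-lingual matching is limited
to whatever shared tokens survive normalization; there is no translation
layer.
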