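"""End-to-end matching pipeline: load -> profile -> index -> lexical ->
extended -> contextual -> post-process -> evaluate.

Two profiles are provided.  The ``full`` profile indexes both ontologies,
matches concepts and properties through the two-way exact search, runs the
synonym-extended and contextual stages and emits one-to-one mappings.  The
``lt`` profile is the lightweight variant: only the larger ontology is
indexed, the other side's concepts are used as queries, best candidates
are chosen by Levenshtein similarity on local names, properties and the
contextual stage are skipped, and one-to-many mappings are allowed.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field

import numpy as np

from . import alignio
from .candidates import (
    LexicalConfig,
    MappingTriple,
    PROV_EXACT,
    build_m_exact,
    extended_search,
    load_lexicon,
    match_properties,
    synonym_bridge,
    two_way_search,
)
from .contextual import build_training_set, classify_pcc, generate_pcc, train_classifier
from .documents import EXACT, build_virtual_document
from .index import index_ontology
from .loaders import load_ontology
from .metrics import LexWeights, levenshtein_sim
from .normalize import NormalizerConfig
from .ontology import CONCEPT, MatchTaskProfile, Ontology, profile_task
from .postprocess import (
    ONE_TO_MANY,
    ONE_TO_ONE,
    AlignmentSet,
    EvaluationReport,
    crisscross_filter,
    disjointness_filter,
    enrich,
    evaluate,
    greedy_select,
)

logger = logging.getLogger(__name__)

__all__ = ["MatchConfig", "MatchResult", "match_ontologies", "run_match"]


@dataclass(frozen=True)
class ContextualConfig:
    """Parameters of the contextual (ML) stage."""

    enabled: bool = True
    phi: float = 0.5
    neg_per_pos: int = 2
    depth_limit: int = 2
    min_positives: int = 10


@dataclass(frozen=True)
class MatchConfig:
    """Full pipeline configuration; every threshold in one place."""

    profile: str = "full"  # full | lt
    normalizer: NormalizerConfig = field(default_factory=NormalizerConfig)
    lexical: LexicalConfig = field(default_factory=LexicalConfig)
    contextual: ContextualConfig = field(default_factory=ContextualConfig)
    cardinality: str = ONE_TO_ONE
    extended: bool = True
    enrichment: bool = True
    seed: int = 0

    @classmethod
    def from_dict(cls, data: dict) -> "MatchConfig":
        data = dict(data)
        norm = data.pop("normalizer", {})
        lexical = dict(data.pop("lexical", {}))
        if "weights" in lexical:
            lexical["weights"] = LexWeights(**lexical["weights"])
        ctx = data.pop("contextual", {})
        return cls(
            normalizer=NormalizerConfig(**norm),
            lexical=LexicalConfig(**lexical),
            contextual=ContextualConfig(**ctx),
            **data,
        )

    @classmethod
    def from_yaml(cls, path: str) -> "MatchConfig":
        import yaml

        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def echo(self) -> dict:
        d = asdict(self)
        d["normalizer"]["stopwords"] = sorted(d["normalizer"]["stopwords"])
        return d


@dataclass
class MatchResult:
    """Everything one matching run produced."""

    alignment: AlignmentSet
    profile: MatchTaskProfile
    report: dict
    evaluation: EvaluationReport | None = None

    @property
    def final_pairs(self) -> set[tuple[str, str]]:
        return {t.pair for t in self.alignment.final}


def _spawn_seeds(seed: int, n: int) -> list[int]:
    """Deterministic per-stage seeds fanned out from the top-level seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31 - 1) for s in ss.generate_state(n)]


def match_ontologies(
    o1: Ontology,
    o2: Ontology,
    config: MatchConfig | None = None,
    lexicon: dict[str, set[str]] | None = None,
    reference=None,
) -> MatchResult:
    """Run the complete matching pipeline on two loaded ontologies."""
    config = config or MatchConfig()
    if config.profile == "lt":
        return _match_lt(o1, o2, config, reference)

    cfg, lex = config.normalizer, config.lexical
    timings: dict[str, float] = {}
    t0 = time.perf_counter()

    profile = profile_task(o1, o2)
    timings["profile"] = time.perf_counter() - t0

    t = time.perf_counter()
    i1 = index_ontology(o1, cfg, mode=EXACT)
    i2 = index_ontology(o2, cfg, mode=EXACT)
    timings["indexing"] = time.perf_counter() - t

    # Lexical stage: M_exact and M_prop.
    t = time.perf_counter()
    pairs = two_way_search(o1, o2, i1, i2, cfg, lex, kind=CONCEPT)
    m_exact = build_m_exact(pairs, o1, o2, cfg, lex)
    m_prop = match_properties(o1, o2, i1, i2, cfg, lex)
    timings["lexical"] = time.perf_counter() - t

    # Extended stage on the residual concepts.
    t = time.perf_counter()
    mapped1 = {t_.e1 for t_ in m_exact}
    mapped2 = {t_.e2 for t_ in m_exact}
    residual_1 = o1.concepts - mapped1
    residual_2 = o2.concepts - mapped2
    m_extended: set[MappingTriple] = set()
    if config.extended:
        m_extended = extended_search(residual_1, residual_2, o1, o2, cfg, lex)
        bridged = synonym_bridge(residual_1, residual_2, o1, o2, lexicon, cfg, lex)
        known = {t_.pair for t_ in m_exact} | {t_.pair for t_ in m_extended}
        m_extended |= {t_ for t_ in bridged if t_.pair not in known}
    timings["extended"] = time.perf_counter() - t

    # Contextual ML stage.
    t = time.perf_counter()
    m_context: set[MappingTriple] = set()
    if config.contextual.enabled:
        seed_train, seed_tree = _spawn_seeds(config.seed, 2)
        training = build_training_set(
            m_exact,
            o1,
            o2,
            cfg,
            neg_per_pos=config.contextual.neg_per_pos,
            seed=seed_train,
            depth_limit=config.contextual.depth_limit,
            min_positives=config.contextual.min_positives,
        )
        classifier = train_classifier(training, seed=seed_tree)
        if classifier is not None:
            pcc = generate_pcc(m_exact, o1, o2)
            earlier = {t_.pair for t_ in m_exact | m_prop | m_extended}
            pcc = {p for p in pcc if p not in earlier}
            m_context = classify_pcc(
                pcc,
                config.contextual.phi,
                classifier,
                m_exact,
                o1,
                o2,
                cfg,
                depth_limit=config.contextual.depth_limit,
            )
            m_context = {t_ for t_ in m_context if t_.pair not in earlier}
    timings["contextual"] = time.perf_counter() - t

    # Post-processing: filters -> enrichment -> greedy selection.
    t = time.perf_counter()
    alignment = AlignmentSet(
        m_exact=m_exact,
        m_prop=m_prop,
        m_extended=m_extended,
        m_context=m_context,
        cardinality_mode=config.cardinality,
    )
    alignment.validate_disjoint_stages()
    candidates = alignment.m_candidate
    candidates = disjointness_filter(candidates, m_exact, o1, o2)
    candidates = crisscross_filter(candidates, m_exact, o1, o2)
    if config.enrichment:
        candidates |= enrich(candidates, o1, o2, cfg, lex)
    alignment.final = greedy_select(candidates, mode=config.cardinality)
    timings["postprocess"] = time.perf_counter() - t

    evaluation = evaluate(alignment.final, reference) if reference else None
    report = _build_report(config, profile, alignment, timings, evaluation)
    return MatchResult(alignment, profile, report, evaluation)


def _match_lt(
    o1: Ontology, o2: Ontology, config: MatchConfig, reference=None
) -> MatchResult:
    """Lightweight profile: index the larger ontology only, query with the
    smaller one, select best candidates by Levenshtein similarity of local
    names, allow 1:n; properties and the contextual stage are skipped."""
    cfg, lex = config.normalizer, config.lexical
    timings: dict[str, float] = {}
    t0 = time.perf_counter()
    profile = profile_task(o1, o2)
    timings["profile"] = time.perf_counter() - t0

    swap = len(o1.concepts) > len(o2.concepts)
    small, large = (o2, o1) if swap else (o1, o2)

    t = time.perf_counter()
    idx = index_ontology(large, cfg, mode=EXACT, kinds={CONCEPT})
    timings["indexing"] = time.perf_counter() - t

    t = time.perf_counter()
    m_exact: set[MappingTriple] = set()
    for e in sorted(small.concepts):
        query = build_virtual_document(small, e, cfg, mode=EXACT)
        hits = [
            h
            for h in idx.search(query, k=lex.best_k)
            if h.score >= lex.max_score
        ]
        if not hits:
            continue
        scored = [
            (levenshtein_sim(small.local_name_of(e), large.local_name_of(h.entity_id)), h)
            for h in hits
        ]
        best = max(s for s, _h in scored)
        for s, h in scored:
            if s == best:
                e1, e2 = (h.entity_id, e) if swap else (e, h.entity_id)
                m_exact.add(
                    MappingTriple(
                        e1,
                        e2,
                        score=min(h.score, 1.0),
                        provenance=PROV_EXACT,
                        component_scores=(("lev_localname", s),),
                    )
                )
    timings["lexical"] = time.perf_counter() - t

    alignment = AlignmentSet(m_exact=m_exact, cardinality_mode=ONE_TO_MANY)
    alignment.final = greedy_select(alignment.m_candidate, mode=ONE_TO_MANY)
    evaluation = evaluate(alignment.final, reference) if reference else None
    report = _build_report(config, profile, alignment, timings, evaluation)
    report["skipped_stages"] = ["properties", "extended", "contextual"]
    return MatchResult(alignment, profile, report, evaluation)


def _build_report(config, profile, alignment, timings, evaluation) -> dict:
    provenance_counts: dict[str, int] = {}
    for t in alignment.final:
        provenance_counts[t.provenance] = provenance_counts.get(t.provenance, 0) + 1
    report = {
        "config": config.echo(),
        "profile": {
            "n_concepts_1": profile.n_concepts_1,
            "n_concepts_2": profile.n_concepts_2,
            "n_properties_1": profile.n_properties_1,
            "n_properties_2": profile.n_properties_2,
            "languages": sorted(profile.languages),
            "size_category": profile.size_category,
        },
        "stage_sizes": {
            "m_exact": len(alignment.m_exact),
            "m_prop": len(alignment.m_prop),
            "m_extended": len(alignment.m_extended),
            "m_context": len(alignment.m_context),
            "m_candidate": len(alignment.m_candidate),
            "final": len(alignment.final),
        },
        "final_provenance_counts": provenance_counts,
        "timings_s": {k: round(v, 4) for k, v in timings.items()},
    }
    if evaluation is not None:
        report["evaluation"] = asdict(evaluation)
    return report


def run_match(
    source: str,
    target: str,
    output: str,
    config: MatchConfig | None = None,
    lexicon_path: str | None = None,
    reference_path: str | None = None,
    report_path: str | None = None,
    source_format: str | None = None,
    target_format: str | None = None,
) -> MatchResult:
    """File-level entry point: load the ontologies, run the pipeline,
    write the Alignment RDF output and a JSON run report."""
    o1 = load_ontology(source, source_format)
    o2 = load_ontology(target, target_format)
    lexicon = load_lexicon(lexicon_path) if lexicon_path else None
    reference = None
    if reference_path:
        reference = {(e1, e2) for e1, e2, _s in alignio.read_alignment(reference_path)}
    result = match_ontologies(o1, o2, config, lexicon, reference)
    alignio.write_alignment(result.alignment.final, output)
    if report_path:
        with open(report_path, "w", encoding="utf-8") as fh:
            json.dump(result.report, fh, indent=2, sort_keys=True)
            fh.write("\n")
    return result
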