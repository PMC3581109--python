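"""End-to-end mining pipeline: parse -> ages -> relate -> snip -> map -> populate.

The four mining steps are: (1) find age-related abstracts, (2) assign the
age-phenotype relationship type, (3) build the evidence snippet, (4) map the
snippet to phenotype concepts.  Candidates whose relationship cannot be
determined, or that map to no phenotype, are dropped — only fully linked
instances populate the store.  The run report accounts for every candidate:
``populated + dropped_undetermined + dropped_no_phenotype`` equals the
number of candidates that entered the relationship stage.
"""

from __future__ import annotations

from dataclasses import dataclass

from .age_extraction import AgePatternTable, extract_age_mentions, select_candidate_ranges
from .evidence_store import EvidenceStore, assemble_instance
from .lexicon_mapper import (
    ConceptIndex,
    OntologyIndex,
    detect_gender,
    flag_redundant,
    map_snippet,
)
from .medline_io import AbstractRecord, segment_sentences
from .relation_classifier import UNDETERMINED, CueTable, classify_relationship
from .snippet_builder import build_snippet

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Tunable behaviour of the mining pipeline."""

    age_patterns: AgePatternTable | None = None
    cue_table: CueTable | None = None
    include_titles: bool = False
    legacy_mean_priority: bool = False
    max_snippet_sentences: int = 3
    seed: int = 0  # recorded in the report; the pipeline itself is deterministic


def run_pipeline(
    records: list[AbstractRecord],
    ontology: OntologyIndex,
    concepts: ConceptIndex | None = None,
    config: PipelineConfig | None = None,
) -> tuple[EvidenceStore, dict]:
    """Mine a parsed corpus into an evidence store, with a count report."""
    config = config or PipelineConfig()
    store = EvidenceStore()
    report = {
        "records_in": len(records),
        "age_related": 0,
        "candidates": 0,
        "relationship_assigned": 0,
        "dropped_undetermined": 0,
        "snippets_built": 0,
        "dropped_no_phenotype": 0,
        "populated": 0,
        "multi_instance_abstracts": 0,
    }
    for record in records:
        if not record.sentences:
            record = segment_sentences(record)
        mentions = extract_age_mentions(
            record, config.age_patterns, include_title=config.include_titles
        )
        if not mentions:
            continue
        candidates = select_candidate_ranges(
            mentions, legacy_mean_priority=config.legacy_mean_priority
        )
        if not candidates:
            continue
        report["age_related"] += 1
        report["candidates"] += len(candidates)
        populated_here = 0
        for ordinal, mention in enumerate(candidates):
            rel = classify_relationship(record, mention, config.cue_table)
            if rel == UNDETERMINED:
                report["dropped_undetermined"] += 1
                continue
            report["relationship_assigned"] += 1
            snippet = build_snippet(
                record, mention, rel, config.cue_table,
                max_sentences=config.max_snippet_sentences,
            )
            report["snippets_built"] += 1
            hits = flag_redundant(map_snippet(snippet, ontology, concepts), ontology)
            gender = detect_gender(snippet)
            inst = assemble_instance(
                record, mention, rel, snippet, hits, gender, ordinal=ordinal
            )
            if inst is None:
                report["dropped_no_phenotype"] += 1
                continue
            store.add(inst)
            populated_here += 1
        report["populated"] += populated_here
        if populated_here >= 2:
            report["multi_instance_abstracts"] += 1
    return store, report
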