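"""The evidence knowledge base: assembly, persistence, and ontology-aware query.

An :class:`EvidenceInstance` is the unit of stored knowledge — one age range
from one abstract, linked to phenotype concepts through a text snippet and a
typed relationship.  The population filter is enforced at assembly and again
on load: instances whose relationship could not be determined, or that map to
no phenotype, are never stored.

Queries come in three modes — by age, by phenotype, or both — with
conjunctive refinement filters (year range, publication type, curation
status, relationship, gender).  Phenotype queries are ontology-aware: a query
term matches any instance mapped to the term itself or to any is_a
descendant, so searching a high-level term like "cancer" returns every
instance involving any specific cancer.  Age queries use interval
intersection by default (a strict containment mode is available).  The
``wiki_preset`` flag reproduces the public-subset filter: it excludes the
age-of-occurrence and age-of-evaluation relationships and all inferred age
ranges.  Results are grouped by relationship type.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from .age_extraction import AgeClass, AgeRange, assign_age_class
from .lexicon_mapper import ConceptHit, OntologyIndex
from .relation_classifier import RELATIONSHIP_TYPES, UNDETERMINED
from .snippet_builder import Snippet

__all__ = [
    "EvidenceInstance",
    "EvidenceStore",
    "QueryCriteria",
    "StoreFormatError",
    "assemble_instance",
    "query",
    "write_store",
    "read_store",
]

SCHEMA_VERSION = 1


class StoreFormatError(ValueError):
    """Raised when a store file is truncated, malformed, or wrong version."""


@dataclass(frozen=True)
class EvidenceInstance:
    instance_id: str
    pmid: str
    age_range: AgeRange
    age_class: str
    relationship: str
    snippet: Snippet
    hits: tuple[ConceptHit, ...]
    gender: str = "NONE"
    pub_year: int | None = None
    pub_types: tuple[str, ...] = ()
    curated: bool = False

    def __post_init__(self) -> None:
        if self.relationship not in RELATIONSHIP_TYPES:
            raise ValueError(f"invalid relationship {self.relationship!r}")
        if not self.hits:
            raise ValueError("an evidence instance requires at least one hit")
        expected = assign_age_class(self.age_range).name
        if self.age_class != expected:
            raise ValueError(
                f"age_class {self.age_class} does not match range (expect {expected})"
            )

    def ontology_terms(self, *, include_redundant: bool = False) -> set[str]:
        """Ontology terms this instance is mapped to (non-redundant by default)."""
        return {
            h.ontology_term
            for h in self.hits
            if h.ontology_term is not None and (include_redundant or not h.is_redundant)
        }

    def to_dict(self) -> dict:
        return {
            "instance_id": self.instance_id,
            "pmid": self.pmid,
            "age_range": {
                "low_years": self.age_range.low_years,
                "high_years": self.age_range.high_years,
                "inferred": self.age_range.inferred,
            },
            "age_class": self.age_class,
            "relationship": self.relationship,
            "snippet": self.snippet.to_dict(),
            "hits": [h.to_dict() for h in self.hits],
            "gender": self.gender,
            "pub_year": self.pub_year,
            "pub_types": list(self.pub_types),
            "curated": self.curated,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EvidenceInstance":
        return cls(
            instance_id=d["instance_id"],
            pmid=d["pmid"],
            age_range=AgeRange(**d["age_range"]),
            age_class=d["age_class"],
            relationship=d["relationship"],
            snippet=Snippet.from_dict(d["snippet"]),
            hits=tuple(ConceptHit.from_dict(h) for h in d["hits"]),
            gender=d.get("gender", "NONE"),
            pub_year=d.get("pub_year"),
            pub_types=tuple(d.get("pub_types", ())),
            curated=d.get("curated", False),
        )


def assemble_instance(
    record,
    mention,
    rel: str,
    snippet: Snippet,
    hits: list[ConceptHit],
    gender: str = "NONE",
    *,
    ordinal: int = 0,
) -> EvidenceInstance | None:
    """Apply the population filter and build an instance, or return None.

    None iff the relationship is undetermined or no phenotype hit was found.
    The instance id is deterministic: ``<pmid>:<ordinal>``.
    """
    if rel == UNDETERMINED or not hits:
        return None
    return EvidenceInstance(
        instance_id=f"{record.pmid}:{ordinal}",
        pmid=record.pmid,
        age_range=mention.range,
        age_class=assign_age_class(mention.range).name,
        relationship=rel,
        snippet=snippet,
        hits=tuple(hits),
        gender=gender,
        pub_year=record.pub_year,
        pub_types=tuple(record.pub_types),
    )


class EvidenceStore:
    """An ordered collection of evidence instances with unique ids."""

    def __init__(self, instances: Iterable[EvidenceInstance] = ()):
        self.instances: list[EvidenceInstance] = []
        self._ids: set[str] = set()
        for inst in instances:
            self.add(inst)

    def add(self, inst: EvidenceInstance) -> None:
        if inst.instance_id in self._ids:
            raise ValueError(f"duplicate instance id {inst.instance_id}")
        self._ids.add(inst.instance_id)
        self.instances.append(inst)

    def __len__(self) -> int:
        return len(self.instances)

    def __iter__(self):
        return iter(self.instances)


@dataclass
class QueryCriteria:
    """Search criteria for the data browser's three query modes."""

    mode: str  # BY_AGE | BY_PHENOTYPE | BY_AGE_AND_PHENOTYPE
    age: AgeRange | AgeClass | None = None
    phenotypes: tuple[str, ...] = ()
    year_range: tuple[int | None, int | None] | None = None
    pub_type: str | None = None
    curated: bool | None = None
    relationship: str | None = None
    gender: str | None = None
    wiki_preset: bool = False
    contained: bool = False  # strict age-containment instead of intersection
    include_redundant: bool = False

    def __post_init__(self) -> None:
        if self.mode not in ("BY_AGE", "BY_PHENOTYPE", "BY_AGE_AND_PHENOTYPE"):
            raise ValueError(f"unknown query mode {self.mode!r}")
        if self.mode in ("BY_AGE", "BY_AGE_AND_PHENOTYPE") and self.age is None:
            raise ValueError(f"{self.mode} requires an age")
        if self.mode in ("BY_PHENOTYPE", "BY_AGE_AND_PHENOTYPE") and not self.phenotypes:
            raise ValueError(f"{self.mode} requires at least one phenotype")


def _query_interval(age: AgeRange | AgeClass) -> AgeRange:
    if isinstance(age, AgeClass):
        return AgeRange(age.low, age.high)
    return age


def query(
    store: EvidenceStore,
    criteria: QueryCriteria,
    ontology: OntologyIndex | None = None,
) -> dict[str, list[EvidenceInstance]]:
    """Run a query; results are grouped by relationship type.

    Phenotype matching requires the ontology index (for descendant
    expansion); an unknown phenotype ID raises KeyError naming it.
    All filters are conjunctive.
    """
    closures: list[set[str]] = []
    if criteria.mode in ("BY_PHENOTYPE", "BY_AGE_AND_PHENOTYPE"):
        if ontology is None:
            raise ValueError("phenotype queries require an ontology index")
        for tid in criteria.phenotypes:
            if tid not in ontology.terms:
                raise KeyError(f"unknown phenotype ID {tid}")
            closures.append({tid} | ontology.descendants(tid))

    interval = None
    if criteria.mode in ("BY_AGE", "BY_AGE_AND_PHENOTYPE"):
        interval = _query_interval(criteria.age)

    results: dict[str, list[EvidenceInstance]] = {t: [] for t in RELATIONSHIP_TYPES}
    for inst in sorted(store, key=lambda i: i.instance_id):
        if criteria.wiki_preset:
            if inst.relationship in ("AGE_OF_OCCURRENCE", "AGE_OF_EVALUATION"):
                continue
            if inst.age_range.inferred:
                continue
        if interval is not None:
            ok = (
                interval.contains(inst.age_range)
                if criteria.contained
                else interval.intersects(inst.age_range)
            )
            if not ok:
                continue
        if closures:
            terms = inst.ontology_terms(include_redundant=criteria.include_redundant)
            if not all(terms & closure for closure in closures):
                continue
        if criteria.year_range is not None:
            lo, hi = criteria.year_range
            if inst.pub_year is None:
                continue
            if lo is not None and inst.pub_year < lo:
                continue
            if hi is not None and inst.pub_year > hi:
                continue
        if criteria.pub_type is not None and criteria.pub_type not in inst.pub_types:
            continue
        if criteria.curated is not None and inst.curated != criteria.curated:
            continue
        if criteria.relationship is not None and inst.relationship != criteria.relationship:
            continue
        if criteria.gender is not None and inst.gender != criteria.gender:
            continue
        results[inst.relationship].append(inst)
    return results


def flatten(results: dict[str, list[EvidenceInstance]]) -> list[EvidenceInstance]:
    return [inst for group in results.values() for inst in group]


def write_store(store: EvidenceStore, path: str | Path) -> None:
    """Persist as JSON lines: a header line, then instances sorted by id."""
    ordered = sorted(store, key=lambda i: i.instance_id)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(json.dumps({
            "format": "apk-store",
            "version": SCHEMA_VERSION,
            "count": len(ordered),
        }) + "\n")
        for inst in ordered:
            fh.write(json.dumps(inst.to_dict()) + "\n")


def read_store(path: str | Path) -> EvidenceStore:
    """Load a store file; validates schema version, count, and every instance.

    The population filter is re-checked through the EvidenceInstance
    constructor — an undetermined relationship or empty hit list in the file
    is a format error, and nothing is loaded partially.
    """
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    if not lines:
        raise StoreFormatError("empty store file")
    try:
        header = json.loads(lines[0])
    except json.JSONDecodeError as exc:
        raise StoreFormatError(f"bad header: {exc}") from exc
    if header.get("format") != "apk-store":
        raise StoreFormatError("not an apk-store file")
    if header.get("version") != SCHEMA_VERSION:
        raise StoreFormatError(
            f"schema version {header.get('version')} != {SCHEMA_VERSION}"
        )
    body = [ln for ln in lines[1:] if ln.strip()]
    if len(body) != header.get("count"):
        raise StoreFormatError(
            f"truncated store: header count {header.get('count')}, found {len(body)}"
        )
    instances = []
    for ln in body:
        try:
            instances.append(EvidenceInstance.from_dict(json.loads(ln)))
        except (json.JSONDecodeError, ValueError, KeyError) as exc:
            raise StoreFormatError(f"bad instance record: {exc}") from exc
    return EvidenceStore(instances)


def export_relational(store: EvidenceStore, outdir: str | Path) -> None:
    """Write a flat relational export: instance.tsv, hit.tsv, snippet.tsv."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ordered = sorted(store, key=lambda i: i.instance_id)
    with open(outdir / "instance.tsv", "w", encoding="utf-8") as fh:
        fh.write("instance_id\tpmid\tlow_years\thigh_years\tinferred\tage_class\t"
                 "relationship\tgender\tpub_year\tcurated\n")
        for i in ordered:
            fh.write("\t".join(map(str, [
                i.instance_id, i.pmid, i.age_range.low_years,
                i.age_range.high_years, i.age_range.inferred, i.age_class,
                i.relationship, i.gender, i.pub_year, i.curated,
            ])) + "\n")
    with open(outdir / "hit.tsv", "w", encoding="utf-8") as fh:
        fh.write("instance_id\tsource\tid\tmapped_ontology_id\tmatched_span\t"
                 "start\tend\tis_redundant\n")
        for i in ordered:
            for h in i.hits:
                fh.write("\t".join(map(str, [
                    i.instance_id, h.source, h.id, h.mapped_ontology_id,
                    h.matched_span, h.start, h.end, h.is_redundant,
                ])) + "\n")
    with open(outdir / "snippet.tsv", "w", encoding="utf-8") as fh:
        fh.write("instance_id\tsentence_indices\ttext\n")
        for i in ordered:
            fh.write("\t".join([
                i.instance_id,
                ",".join(map(str, i.snippet.sentence_indices)),
                i.snippet.text.replace("\t", " "),
            ]) + "\n")
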