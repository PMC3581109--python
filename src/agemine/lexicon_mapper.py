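"""Dictionary-based mapping of snippets to diseases and other concepts.

Two lexicons are searched with perfect-match (exact, case-insensitive)
string lookup on token boundaries:

1. a disease ontology in OBO format (names, synonyms, is_a hierarchy,
   cross-references to external concept IDs), loaded via :mod:`obonet`;
2. a concept-subset lexicon in TSV (concept ID, semantic type, string),
   restricted by default to disease/drug/finding semantic types.  This is a
   neutral stand-in format for licensed vocabularies such as the UMLS
   Metathesaurus; users populate it from whatever source they hold.

The ontology is searched first, then the concept subset.  A concept hit of
semantic type *disease* is cross-mapped to the ontology term that lists its
concept ID as a cross-reference, so disease evidence always lands in the
ontology's hierarchy.  Nested or ancestral hits ("carcinoma" inside
"squamous cell carcinoma") are kept but flagged as *redundant* — they add
harmless, not erroneous, mapping.  Gender is assigned when terms of exactly
one gender occur in the snippet.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable

import networkx as nx
import obonet

from ._tables import load_gender_terms
from .snippet_builder import Snippet

__all__ = [
    "OntologyTerm",
    "OntologyIndex",
    "ConceptEntry",
    "ConceptIndex",
    "ConceptHit",
    "LexiconError",
    "normalize",
    "load_ontology",
    "load_concept_subset",
    "map_snippet",
    "flag_redundant",
    "detect_gender",
]


class LexiconError(ValueError):
    """Raised for malformed ontology or concept-subset input."""


_NONWORD_RUN = re.compile(r"[^0-9a-z]+")


def normalize(s: str) -> str:
    """Normalization used for perfect matching.

    Lowercase; every run of non-alphanumeric characters (whitespace, hyphens,
    punctuation) collapses to a single space; leading/trailing runs are
    stripped.  Idempotent.  No stemming, no fuzzy matching.
    """
    return _NONWORD_RUN.sub(" ", s.lower()).strip()


@dataclass(frozen=True)
class OntologyTerm:
    term_id: str
    name: str
    synonyms: tuple[str, ...] = ()
    parents: tuple[str, ...] = ()
    xrefs: tuple[str, ...] = ()


_SYNONYM_TEXT = re.compile(r'"([^"]*)"')


class OntologyIndex:
    """String lookup plus is_a hierarchy over an OBO disease ontology."""

    def __init__(self, terms: dict[str, OntologyTerm]):
        self.terms = terms
        self.graph = nx.DiGraph()  # edge child -> parent
        for t in terms.values():
            self.graph.add_node(t.term_id)
            for p in t.parents:
                if p not in terms:
                    raise LexiconError(f"term {t.term_id} has unknown parent {p}")
                self.graph.add_edge(t.term_id, p)
        if not nx.is_directed_acyclic_graph(self.graph):
            cycle = nx.find_cycle(self.graph)
            raise LexiconError(f"is_a cycle: {' -> '.join(a for a, _ in cycle)}")
        self.string_index: dict[str, tuple[str, ...]] = {}
        idx: dict[str, set[str]] = {}
        for t in terms.values():
            for s in (t.name, *t.synonyms):
                key = normalize(s)
                if key:
                    idx.setdefault(key, set()).add(t.term_id)
        self.string_index = {k: tuple(sorted(v)) for k, v in idx.items()}
        # xrefs indexed both verbatim ("UMLS_CUI:C0007137") and by the bare
        # external ID ("C0007137"), since concept lexicons carry the latter
        self.xref_index: dict[str, str] = {}
        for t in sorted(terms.values(), key=lambda t: t.term_id):
            for x in t.xrefs:
                self.xref_index.setdefault(x, t.term_id)
                if ":" in x:
                    self.xref_index.setdefault(x.rsplit(":", 1)[1], t.term_id)

    def __len__(self) -> int:
        return len(self.terms)

    def lookup(self, s: str) -> tuple[str, ...]:
        return self.string_index.get(normalize(s), ())

    def ancestors(self, term_id: str) -> set[str]:
        """Strict is_a ancestors (parents, grandparents, ...)."""
        return set(nx.descendants(self.graph, term_id))

    def descendants(self, term_id: str) -> set[str]:
        if term_id not in self.graph:
            raise KeyError(f"unknown ontology term {term_id}")
        return set(nx.ancestors(self.graph, term_id))

    def is_ancestor(self, a: str, b: str) -> bool:
        """True iff ``a`` is a strict ancestor of ``b``."""
        return a != b and a in self.ancestors(b) if b in self.graph else False


def _check_duplicate_ids(text: str) -> None:
    seen: set[str] = set()
    in_term = False
    for line in text.splitlines():
        line = line.strip()
        if line.startswith("["):
            in_term = line == "[Term]"
        elif in_term and line.startswith("id:"):
            tid = line[3:].strip()
            if tid in seen:
                raise LexiconError(f"duplicate term id {tid}")
            seen.add(tid)


def load_ontology(path: str | Path) -> OntologyIndex:
    """Load an OBO ontology into an :class:`OntologyIndex`.

    Honors name, synonym, is_a and xref tags.  Raises :class:`LexiconError`
    on duplicate term IDs or an is_a cycle.  An empty ontology yields an
    empty index (with a warning from the caller's perspective: len() == 0).
    """
    text = Path(path).read_text(encoding="utf-8")
    _check_duplicate_ids(text)
    graph = obonet.read_obo(str(path))
    terms: dict[str, OntologyTerm] = {}
    for node, data in graph.nodes(data=True):
        synonyms = []
        for raw in data.get("synonym", []):
            m = _SYNONYM_TEXT.search(raw)
            if m:
                synonyms.append(m.group(1))
        parents = [v for _u, v, k in graph.out_edges(node, keys=True) if k == "is_a"]
        terms[node] = OntologyTerm(
            term_id=node,
            name=data.get("name", ""),
            synonyms=tuple(synonyms),
            parents=tuple(sorted(parents)),
            xrefs=tuple(data.get("xref", [])),
        )
    return OntologyIndex(terms)


@dataclass(frozen=True)
class ConceptEntry:
    concept_id: str
    semantic_type: str
    strings: tuple[str, ...]


DEFAULT_SEMANTIC_TYPES = frozenset({"disease", "drug", "finding"})


class ConceptIndex:
    def __init__(self, entries: dict[str, ConceptEntry], dropped_rows: int = 0):
        self.entries = entries
        self.dropped_rows = dropped_rows
        idx: dict[str, set[str]] = {}
        for e in entries.values():
            for s in e.strings:
                key = normalize(s)
                if key:
                    idx.setdefault(key, set()).add(e.concept_id)
        self.string_index = {k: tuple(sorted(v)) for k, v in idx.items()}

    def __len__(self) -> int:
        return len(self.entries)


def load_concept_subset(
    path: str | Path,
    *,
    allowed_types: frozenset[str] | set[str] = DEFAULT_SEMANTIC_TYPES,
) -> ConceptIndex:
    """Load the concept-subset TSV (concept_id, semantic_type, string).

    Rows with a semantic type outside ``allowed_types`` are dropped and
    counted; duplicate (id, string) rows collapse; an empty string field is a
    hard error naming the line.
    """
    strings: dict[str, set[str]] = {}
    types: dict[str, str] = {}
    dropped = 0
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        required = ["concept_id", "semantic_type", "string"]
        if header[:3] != required:
            raise LexiconError(
                f"concept subset must have columns {required}, got {header}"
            )
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise LexiconError(f"line {lineno}: expected 3 columns")
            cid, stype, s = parts[0].strip(), parts[1].strip(), parts[2].strip()
            if not s:
                raise LexiconError(f"line {lineno}: empty string field")
            if stype not in allowed_types:
                dropped += 1
                continue
            types[cid] = stype
            strings.setdefault(cid, set()).add(s)
    entries = {
        cid: ConceptEntry(cid, types[cid], tuple(sorted(strs)))
        for cid, strs in strings.items()
    }
    return ConceptIndex(entries, dropped_rows=dropped)


@dataclass(frozen=True)
class ConceptHit:
    source: str  # ONTOLOGY | CONCEPT_SUBSET
    id: str
    mapped_ontology_id: str | None
    matched_span: str
    start: int
    end: int
    is_redundant: bool = False

    @property
    def ontology_term(self) -> str | None:
        return self.id if self.source == "ONTOLOGY" else self.mapped_ontology_id

    def to_dict(self) -> dict:
        return {
            "source": self.source,
            "id": self.id,
            "mapped_ontology_id": self.mapped_ontology_id,
            "matched_span": self.matched_span,
            "start": self.start,
            "end": self.end,
            "is_redundant": self.is_redundant,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ConceptHit":
        return cls(**d)


def _occurrences(text: str, lexicon_string: str) -> Iterable[tuple[int, int]]:
    """All token-boundary occurrences of a normalized lexicon string."""
    tokens = normalize(lexicon_string).split()
    if not tokens:
        return
    pat = (
        r"(?<![0-9A-Za-z])"
        + r"[^0-9A-Za-z]+".join(re.escape(t) for t in tokens)
        + r"(?![0-9A-Za-z])"
    )
    for m in re.finditer(pat, text, re.IGNORECASE):
        yield m.start(), m.end()


def map_snippet(
    snippet: Snippet | str,
    ontology: OntologyIndex,
    concepts: ConceptIndex | None = None,
) -> list[ConceptHit]:
    """Perfect-match search of both lexicons over the snippet text.

    Every occurrence of every lexicon string is reported (nested matches
    included; see :func:`flag_redundant`).  Ontology hits come first, then
    concept-subset hits; within a source, hits are ordered by position.
    """
    text = snippet.text if isinstance(snippet, Snippet) else snippet
    hits: list[ConceptHit] = []
    seen: set[tuple[str, str, int, int]] = set()

    for key in ontology.string_index:
        for start, end in _occurrences(text, key):
            for tid in ontology.string_index[key]:
                sig = ("ONTOLOGY", tid, start, end)
                if sig in seen:
                    continue
                seen.add(sig)
                hits.append(
                    ConceptHit("ONTOLOGY", tid, None, text[start:end], start, end)
                )
    n_onto = len(hits)
    if concepts is not None:
        for key in concepts.string_index:
            for start, end in _occurrences(text, key):
                for cid in concepts.string_index[key]:
                    sig = ("CONCEPT_SUBSET", cid, start, end)
                    if sig in seen:
                        continue
                    seen.add(sig)
                    entry = concepts.entries[cid]
                    mapped = None
                    if entry.semantic_type == "disease":
                        mapped = ontology.xref_index.get(cid)
                    hits.append(
                        ConceptHit("CONCEPT_SUBSET", cid, mapped,
                                   text[start:end], start, end)
                    )
    hits[:n_onto] = sorted(hits[:n_onto], key=lambda h: (h.start, h.end, h.id))
    hits[n_onto:] = sorted(hits[n_onto:], key=lambda h: (h.start, h.end, h.id))
    return hits


def flag_redundant(hits: list[ConceptHit], ontology: OntologyIndex) -> list[ConceptHit]:
    """Mark harmless hits: span-nested matches and ontological ancestors.

    A hit is redundant iff (a) its matched span is a proper sub-span of
    another hit's span, or (b) its ontology term is a strict is_a ancestor of
    another hit's ontology term.  Exact duplicates are dropped first.
    """
    unique: list[ConceptHit] = []
    seen: set[tuple[str, str, int, int]] = set()
    for h in hits:
        sig = (h.source, h.id, h.start, h.end)
        if sig not in seen:
            seen.add(sig)
            unique.append(h)

    out: list[ConceptHit] = []
    for h in unique:
        redundant = False
        for other in unique:
            if other is h:
                continue
            nested = (
                other.start <= h.start
                and h.end <= other.end
                and (other.end - other.start) > (h.end - h.start)
            )
            ancestral = False
            ht, ot = h.ontology_term, other.ontology_term
            if ht is not None and ot is not None and ht != ot:
                ancestral = ontology.is_ancestor(ht, ot)
            if nested or ancestral:
                redundant = True
                break
        out.append(replace(h, is_redundant=redundant))
    return out


_GENDER_TERMS: dict[str, set[str]] | None = None


def detect_gender(snippet: Snippet | str) -> str:
    """MALE / FEMALE when exactly one gender's terms occur, else NONE.

    Terms are matched on token boundaries so "human" never triggers "man".
    """
    global _GENDER_TERMS
    if _GENDER_TERMS is None:
        _GENDER_TERMS = load_gender_terms()
    text = snippet.text if isinstance(snippet, Snippet) else snippet
    tokens = set(normalize(text).split())
    male = bool(tokens & _GENDER_TERMS["MALE"])
    female = bool(tokens & _GENDER_TERMS["FEMALE"])
    if male and not female:
        return "MALE"
    if female and not male:
        return "FEMALE"
    return "NONE"
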