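"""Assignment of the age-phenotype relationship type.

Five relationship types link an age to a phenotype: age of onset, age of
diagnosis, age of observation, age of occurrence and age of evaluation.  A
cue-word table (TSV, user-overridable) is scanned in widening windows around
the age mention — the mention's own sentence, then the adjacent sentences,
then the whole abstract.  The first window containing any cue decides; within
a window the highest-priority cue wins (onset > diagnosis > observation >
occurrence > evaluation), ties going to the cue nearest the age mention and
then to the earlier text position.  Requiring a cue to co-occur with the age
within a window makes the assignment stricter than keyword co-occurrence
anywhere in the abstract; when no cue fires the mention is UNDETERMINED and
the candidate instance is discarded downstream.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

from ._tables import load_relation_cue_rows
from .age_extraction import AgeMention
from .medline_io import AbstractRecord

__all__ = [
    "RELATIONSHIP_TYPES",
    "UNDETERMINED",
    "CueTable",
    "classify_relationship",
]

RELATIONSHIP_TYPES = (
    "AGE_OF_ONSET",
    "AGE_OF_DIAGNOSIS",
    "AGE_OF_OBSERVATION",
    "AGE_OF_OCCURRENCE",
    "AGE_OF_EVALUATION",
)
UNDETERMINED = "UNDETERMINED"


@dataclass(frozen=True)
class _Cue:
    cue: str
    type: str
    priority: int
    rx: re.Pattern


class CueTable:
    """Compiled relationship cues matched on token boundaries."""

    def __init__(self, rows: list[dict] | None = None):
        if rows is None:
            rows = load_relation_cue_rows()
        self.cues: list[_Cue] = []
        for row in rows:
            if row["type"] not in RELATIONSHIP_TYPES:
                raise ValueError(f"unknown relationship type {row['type']!r}")
            tokens = row["cue"].split()
            pat = r"\b" + r"\s+".join(re.escape(t) for t in tokens) + r"\b"
            self.cues.append(
                _Cue(row["cue"], row["type"], row["priority"],
                     re.compile(pat, re.IGNORECASE))
            )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CueTable":
        return cls(load_relation_cue_rows(path))

    def cues_for(self, rel_type: str) -> list[str]:
        return [c.cue for c in self.cues if c.type == rel_type]


_DEFAULT_CUES: CueTable | None = None


def default_cue_table() -> CueTable:
    global _DEFAULT_CUES
    if _DEFAULT_CUES is None:
        _DEFAULT_CUES = CueTable()
    return _DEFAULT_CUES


def _firing(table: CueTable, text: str, offset: int) -> list[tuple[int, int, str]]:
    """(priority, absolute position, type) for every cue occurrence in text."""
    hits = []
    for cue in table.cues:
        for m in cue.rx.finditer(text):
            hits.append((cue.priority, offset + m.start(), cue.type))
    return hits


def classify_relationship(
    record: AbstractRecord,
    mention: AgeMention,
    table: CueTable | None = None,
) -> str:
    """Return the relationship type for an age mention, or UNDETERMINED."""
    table = table or default_cue_table()
    if not record.sentences:
        raise ValueError("record must be sentence-segmented")

    n = len(record.sentences)
    si = mention.sentence_index
    windows: list[list[int]] = [[si]]
    adjacent = [i for i in (si - 1, si + 1) if 0 <= i < n]
    if adjacent:
        windows.append(adjacent)
    rest = [i for i in range(n) if i != si and i not in adjacent]
    if rest:
        windows.append(rest)

    for window in windows:
        hits: list[tuple[int, int, str]] = []
        for i in window:
            s = record.sentences[i]
            hits.extend(_firing(table, s.text, s.start))
        if not hits:
            continue
        best_priority = min(h[0] for h in hits)
        top = [h for h in hits if h[0] == best_priority]
        # nearest to the age mention, then earliest in text
        top.sort(key=lambda h: (abs(h[1] - mention.start), h[1]))
        return top[0][2]
    return UNDETERMINED
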