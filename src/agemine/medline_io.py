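"""MEDLINE flat-file I/O and sentence segmentation.

Abstracts exported from PubMed in the MEDLINE format (``PMID- ``, ``TI  - ``,
``AB  - `` ... tag lines with indented continuation lines) are parsed into
:class:`AbstractRecord` objects.  Structured abstracts are split into labelled
sections (OBJECTIVE, METHODS, RESULTS, ...), and a deterministic rule-based
segmenter cuts the abstract body into sentences with character offsets.  The
sentence is the unit every downstream stage works with: age mentions are
located per sentence, relationship cues are searched sentence-windows at a
time, and evidence snippets are built from whole sentences only.

Parsing of the tag/continuation syntax is delegated to :mod:`Bio.Medline`;
this module adds strict validation (malformed lines, duplicate PMIDs),
record filtering (abstracts only), section splitting and segmentation.
"""

from __future__ import annotations

import io
import json
import re
from dataclasses import dataclass, replace
from typing import Iterable, TextIO

from Bio import Medline

from ._tables import load_section_labels

__all__ = [
    "AbstractRecord",
    "Section",
    "Sentence",
    "MedlineParseError",
    "parse_medline",
    "write_medline",
    "segment_sentences",
    "records_to_jsonl",
    "records_from_jsonl",
]


class MedlineParseError(ValueError):
    """Raised for malformed MEDLINE input (bad line, duplicate PMID)."""


@dataclass(frozen=True)
class Sentence:
    """One whole sentence of the abstract body.

    ``start``/``end`` are 0-based half-open offsets into
    ``AbstractRecord.abstract_text`` so that ``abstract_text[start:end] == text``.
    """

    index: int
    text: str
    section_label: str | None
    start: int
    end: int


@dataclass(frozen=True)
class Section:
    """A labelled region of the abstract; label is None for unstructured text."""

    label: str | None
    body: str
    start: int
    end: int


@dataclass(frozen=True)
class AbstractRecord:
    pmid: str
    title: str
    abstract_text: str
    sections: tuple[Section, ...]
    pub_year: int | None = None
    pub_types: tuple[str, ...] = ()
    sentences: tuple[Sentence, ...] = ()

    def to_dict(self) -> dict:
        return {
            "pmid": self.pmid,
            "title": self.title,
            "abstract_text": self.abstract_text,
            "sections": [
                {"label": s.label, "body": s.body, "start": s.start, "end": s.end}
                for s in self.sections
            ],
            "pub_year": self.pub_year,
            "pub_types": list(self.pub_types),
            "sentences": [
                {
                    "index": s.index,
                    "text": s.text,
                    "section_label": s.section_label,
                    "start": s.start,
                    "end": s.end,
                }
                for s in self.sentences
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AbstractRecord":
        return cls(
            pmid=d["pmid"],
            title=d["title"],
            abstract_text=d["abstract_text"],
            sections=tuple(Section(**s) for s in d["sections"]),
            pub_year=d.get("pub_year"),
            pub_types=tuple(d.get("pub_types", ())),
            sentences=tuple(Sentence(**s) for s in d.get("sentences", ())),
        )


# A tag line is 1-4 alphanumerics left-justified in a 4-char field, then "- ".
_TAG_LINE = re.compile(r"^[A-Z0-9]{1,4}\s{0,3}- ")
_CONTINUATION = re.compile(r"^\s{6}")

_YEAR = re.compile(r"\b(1[5-9]\d{2}|20\d{2})\b")


def _validate_lines(text: str) -> None:
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        if _TAG_LINE.match(line) or _CONTINUATION.match(line):
            continue
        raise MedlineParseError(
            f"malformed MEDLINE line {lineno}: {line[:60]!r}"
        )


def _split_sections(text: str, labels: list[str]) -> tuple[Section, ...]:
    """Split an abstract into labelled sections.

    A section label is an uppercase phrase from ``labels`` followed by a colon,
    standing at the start of the text or right after a sentence boundary.
    Unlabelled text (or the whole abstract when no label is found) becomes a
    single section with label None.
    """
    alts = "|".join(re.escape(lab) for lab in sorted(labels, key=len, reverse=True))
    pattern = re.compile(r"(?:^|(?<=[.?!]\s))(" + alts + r"):\s*")
    matches = list(pattern.finditer(text))
    if not matches:
        return (Section(None, text, 0, len(text)),)
    sections: list[Section] = []
    if matches[0].start() > 0:
        lead = text[: matches[0].start()]
        if lead.strip():
            sections.append(Section(None, lead.rstrip(), 0, matches[0].start()))
    for i, m in enumerate(matches):
        body_start = m.end()
        body_end = matches[i + 1].start() if i + 1 < len(matches) else len(text)
        body = text[body_start:body_end].rstrip()
        sections.append(Section(m.group(1), body, body_start, body_start + len(body)))
    return tuple(sections)


def parse_medline(
    stream: TextIO | str,
    *,
    section_labels: list[str] | None = None,
) -> tuple[list[AbstractRecord], int]:
    """Parse MEDLINE-format records into :class:`AbstractRecord` objects.

    Records lacking a PMID or an AB (abstract) field are dropped; the count of
    dropped records is returned alongside the parsed list.  Raises
    :class:`MedlineParseError` on a malformed line or a duplicate PMID.
    """
    text = stream if isinstance(stream, str) else stream.read()
    _validate_lines(text)
    labels = section_labels if section_labels is not None else load_section_labels()

    records: list[AbstractRecord] = []
    seen: set[str] = set()
    dropped = 0
    for raw in Medline.parse(io.StringIO(text)):
        pmid = raw.get("PMID")
        abstract = raw.get("AB")
        if not pmid or not abstract:
            dropped += 1
            continue
        if pmid in seen:
            raise MedlineParseError(f"duplicate PMID {pmid}")
        seen.add(pmid)
        year = None
        dp = raw.get("DP")
        if dp:
            m = _YEAR.search(dp)
            if m:
                year = int(m.group(1))
        records.append(
            AbstractRecord(
                pmid=pmid,
                title=raw.get("TI", ""),
                abstract_text=abstract,
                sections=_split_sections(abstract, labels),
                pub_year=year,
                pub_types=tuple(raw.get("PT", [])),
            )
        )
    return records, dropped


def write_medline(records: Iterable[AbstractRecord]) -> str:
    """Render records back to MEDLINE flat-file text (single-line fields)."""

    def line(tag: str, value: str) -> str:
        return f"{tag:<4}- {value}"

    blocks = []
    for rec in records:
        lines = [line("PMID", rec.pmid)]
        if rec.title:
            lines.append(line("TI", rec.title))
        lines.append(line("AB", rec.abstract_text))
        if rec.pub_year is not None:
            lines.append(line("DP", str(rec.pub_year)))
        for pt in rec.pub_types:
            lines.append(line("PT", pt))
        blocks.append("\n".join(lines))
    return "\n\n".join(blocks) + ("\n" if blocks else "")


# ---------------------------------------------------------------------------
# Sentence segmentation

_ABBREVIATIONS = {
    "e.g", "i.e", "vs", "cf", "ca", "resp", "approx", "etc",
    "dr", "mr", "mrs", "ms", "prof", "st",
    "fig", "figs", "no", "al", "et al",
}

_BOUNDARY = re.compile(r"[.?!]+(?=\s)")
_TRAILING_WORD = re.compile(r"([A-Za-z][A-Za-z.]*?)\.?$")


def _is_abbreviation(prefix: str) -> bool:
    m = _TRAILING_WORD.search(prefix)
    if not m:
        return False
    word = m.group(1).lower().rstrip(".")
    return word in _ABBREVIATIONS


def _split_region(text: str, offset: int) -> list[tuple[int, int]]:
    """Sentence spans (absolute offsets) within one section body."""
    spans: list[tuple[int, int]] = []
    start = 0
    for m in _BOUNDARY.finditer(text):
        end = m.end()
        rest = text[end:]
        stripped = rest.lstrip()
        if not stripped:
            continue
        nxt = stripped[0]
        if not (nxt.isupper() or nxt.isdigit() or nxt in "(\"'["):
            continue
        if _is_abbreviation(text[start:m.start() + 1]):
            continue
        spans.append((start, end))
        start = end + (len(rest) - len(stripped))
    if text[start:].strip():
        spans.append((start, len(text)))
    out = []
    for s, e in spans:
        # trim surrounding whitespace while keeping offsets exact
        seg = text[s:e]
        lead = len(seg) - len(seg.lstrip())
        trail = len(seg) - len(seg.rstrip())
        out.append((offset + s + lead, offset + e - trail))
    return out


def segment_sentences(record: AbstractRecord) -> AbstractRecord:
    """Return a copy of ``record`` with ``sentences`` populated.

    Sentences never cross section boundaries; each carries the label of the
    section containing it.  Offsets index into ``abstract_text``.
    """
    sentences: list[Sentence] = []
    idx = 0
    for section in record.sections:
        body = record.abstract_text[section.start:section.end]
        for s, e in _split_region(body, section.start):
            sentences.append(
                Sentence(
                    index=idx,
                    text=record.abstract_text[s:e],
                    section_label=section.label,
                    start=s,
                    end=e,
                )
            )
            idx += 1
    return replace(record, sentences=tuple(sentences))


def records_to_jsonl(records: Iterable[AbstractRecord]) -> str:
    return "".join(json.dumps(r.to_dict()) + "\n" for r in records)


def records_from_jsonl(text: str) -> list[AbstractRecord]:
    return [
        AbstractRecord.from_dict(json.loads(line))
        for line in text.splitlines()
        if line.strip()
    ]
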