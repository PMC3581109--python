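"""Numeric age-mention detection and normalization.

Age mentions are found with a table of regular expressions (shipped as TSV,
user-overridable) and normalized to a year interval ``[low, high]``.  Only
numerically expressed ages are recognized; spelled-out ages ("two to five
years old") are deliberately ignored.  Open-ended expressions ("30 years or
less") are completed to a full interval using the 0- and 120-year bounds and
flagged *inferred*.  Months, weeks and days convert to fractional years.

Each normalized range is then assigned the most specific age-ontology class
whose interval contains it — e.g. [18, 24] is YOUNG_ADULT rather than ADULT
because the YOUNG_ADULT interval is narrower.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from pathlib import Path

from ._tables import load_age_pattern_rows
from .medline_io import AbstractRecord

__all__ = [
    "AgeRange",
    "AgeMention",
    "AgeClass",
    "AGE_CLASSES",
    "MAX_AGE_YEARS",
    "AgePatternTable",
    "extract_age_mentions",
    "select_candidate_ranges",
    "assign_age_class",
]

MAX_AGE_YEARS = 120.0

_UNIT_YEARS = {
    "year": 1.0, "years": 1.0, "yr": 1.0, "yrs": 1.0,
    "month": 1 / 12, "months": 1 / 12,
    "week": 1 / 52, "weeks": 1 / 52,
    "day": 1 / 365, "days": 1 / 365,
}

_NUM1 = r"(?P<n1>\d{1,3}(?:\.\d+)?)"
_NUM2 = r"(?P<n2>\d{1,3}(?:\.\d+)?)"
_UNIT = r"(?P<u>years?|yrs?|months?|weeks?|days?)"


@dataclass(frozen=True)
class AgeRange:
    """A normalized age interval in years; ``inferred`` marks a filled bound."""

    low_years: float
    high_years: float
    inferred: bool = False

    def __post_init__(self) -> None:
        if not (0 <= self.low_years <= self.high_years <= MAX_AGE_YEARS):
            raise ValueError(
                f"invalid age range [{self.low_years}, {self.high_years}]"
            )

    def intersects(self, other: "AgeRange") -> bool:
        return self.low_years <= other.high_years and other.low_years <= self.high_years

    def contains(self, other: "AgeRange") -> bool:
        return self.low_years <= other.low_years and other.high_years <= self.high_years


@dataclass(frozen=True)
class AgeMention:
    raw_span: str
    start: int
    end: int
    sentence_index: int
    range: AgeRange
    role: str  # range | open_low | open_high | point | mean


@dataclass(frozen=True)
class AgeClass:
    name: str
    low: float
    high: float

    @property
    def width(self) -> float:
        return self.high - self.low

    def contains(self, r: AgeRange) -> bool:
        return self.low <= r.low_years and r.high_years <= self.high


#: The age-ontology classes, most specific assignment by smallest width.
AGE_CLASSES: tuple[AgeClass, ...] = (
    AgeClass("INFANT_NEWBORN", 0.0, 1 / 12),
    AgeClass("INFANT", 0.0, 2.0),
    AgeClass("PRESCHOOL_CHILD", 2.0, 6.0),
    AgeClass("CHILD", 2.0, 12.0),
    AgeClass("ADOLESCENT", 12.0, 18.0),
    AgeClass("YOUNG_ADULT", 18.0, 24.0),
    AgeClass("ADULT", 18.0, 120.0),
    AgeClass("MIDDLE_AGED", 45.0, 64.0),
    AgeClass("AGED", 64.0, 120.0),
    AgeClass("AGED_80_OVER", 80.0, 120.0),
    AgeClass("PERSON_ALL", 0.0, 120.0),
)

_PERSON_ALL = AGE_CLASSES[-1]


def assign_age_class(r: AgeRange) -> AgeClass:
    """Most specific class containing the whole range (smallest interval width).

    Falls back to PERSON_ALL when no narrower class contains the range, e.g.
    for ranges straddling the child/adolescent boundary.
    """
    best = _PERSON_ALL
    for cls in AGE_CLASSES[:-1]:
        if cls.contains(r) and cls.width < best.width:
            best = cls
    return best


class AgePatternTable:
    """Compiled age-mention patterns with role and priority."""

    def __init__(self, rows: list[dict] | None = None):
        if rows is None:
            rows = load_age_pattern_rows()
        self.patterns: list[tuple[str, str, int, re.Pattern]] = []
        for row in rows:
            pat = (
                row["pattern"]
                .replace("{N1}", _NUM1)
                .replace("{N2}", _NUM2)
                .replace("{U}", _UNIT)
            )
            self.patterns.append(
                (row["name"], row["role"], row["priority"],
                 re.compile(pat, re.IGNORECASE))
            )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "AgePatternTable":
        return cls(load_age_pattern_rows(path))


_DEFAULT_TABLE: AgePatternTable | None = None


def _default_table() -> AgePatternTable:
    global _DEFAULT_TABLE
    if _DEFAULT_TABLE is None:
        _DEFAULT_TABLE = AgePatternTable()
    return _DEFAULT_TABLE


def _clamp(x: float) -> float:
    return min(max(x, 0.0), MAX_AGE_YEARS)


def _normalize(role: str, m: re.Match) -> AgeRange:
    unit = (m.groupdict().get("u") or "years").lower()
    factor = _UNIT_YEARS[unit]
    n1 = float(m.group("n1")) * factor
    if role == "range":
        n2 = float(m.group("n2")) * factor
        lo, hi = sorted((n1, n2))
        return AgeRange(_clamp(lo), _clamp(hi), inferred=False)
    if role == "open_low":
        return AgeRange(0.0, _clamp(n1), inferred=True)
    if role == "open_high":
        return AgeRange(_clamp(n1), MAX_AGE_YEARS, inferred=True)
    # point or mean
    v = _clamp(n1)
    return AgeRange(v, v, inferred=False)


def extract_age_mentions(
    record: AbstractRecord,
    table: AgePatternTable | None = None,
    *,
    include_title: bool = False,
) -> list[AgeMention]:
    """Find all numeric age mentions in the abstract body.

    Overlapping matches are resolved by pattern priority (explicit range >
    open-ended > point > mean age), then by span length, then position.
    Returns mentions ordered by text position; an empty list means the record
    is not age-related.
    """
    if not record.sentences:
        raise ValueError("record must be sentence-segmented first")
    table = table or _default_table()

    text = record.abstract_text
    candidates: list[tuple[int, int, int, int, str, AgeRange]] = []
    for _name, role, priority, rx in table.patterns:
        for m in rx.finditer(text):
            rng = _normalize(role, m)
            candidates.append(
                (-(m.end() - m.start()), priority, m.start(), m.end(), role, rng)
            )
    # greedy selection: longest match first (so "mean age of 52" beats the
    # nested "age of 52"), then pattern priority, then leftmost; drop overlaps
    candidates.sort()
    chosen: list[tuple[int, int, str, AgeRange]] = []
    for _nl, _p, start, end, role, rng in candidates:
        if any(start < e and s < end for s, e, _r, _g in chosen):
            continue
        chosen.append((start, end, role, rng))
    chosen.sort()

    mentions: list[AgeMention] = []
    for start, end, role, rng in chosen:
        sent_idx = 0
        for s in record.sentences:
            if s.start <= start < s.end:
                sent_idx = s.index
                break
        mentions.append(
            AgeMention(
                raw_span=text[start:end],
                start=start,
                end=end,
                sentence_index=sent_idx,
                range=rng,
                role=role,
            )
        )

    if include_title and record.title:
        for _name, role, priority, rx in table.patterns:
            for m in rx.finditer(record.title):
                rng = _normalize(role, m)
                mentions.append(
                    AgeMention(m.group(0), m.start(), m.end(), -1, rng, role)
                )
    return mentions


def select_candidate_ranges(
    mentions: list[AgeMention],
    *,
    legacy_mean_priority: bool = False,
) -> list[AgeMention]:
    """Reduce mentions to candidate instances: one per distinct normalized range.

    By default an explicit age or age range outranks a mean/median age found
    elsewhere in the same abstract, so mean-age mentions are dropped whenever
    a non-mean mention exists.  ``legacy_mean_priority`` inverts this and
    keeps only the mean-age mentions, reproducing the historical behaviour of
    preferring a cohort's mean age over its full range.
    """
    if not mentions:
        return []
    means = [m for m in mentions if m.role == "mean"]
    others = [m for m in mentions if m.role != "mean"]
    if legacy_mean_priority and means:
        pool = means
    elif others:
        pool = others
    else:
        pool = means
    seen: set[tuple[float, float, bool]] = set()
    out: list[AgeMention] = []
    for m in pool:
        key = (round(m.range.low_years, 6), round(m.range.high_years, 6), m.range.inferred)
        if key in seen:
            continue
        seen.add(key)
        out.append(m)
    return out


def expand_to_integer_ages(r: AgeRange) -> range:
    """Integer ages covered by a range, rounding fractional bounds outward."""
    lo = int(math.floor(r.low_years))
    hi = int(math.ceil(r.high_years))
    return range(lo, hi + 1)
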