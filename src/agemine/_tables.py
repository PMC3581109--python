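"""Loaders for the package's rule tables.

Every behavioural table (age patterns, relationship cues, section labels,
gender terms, subject terms) is plain TSV data under ``agemine/data``.  Each
loader accepts an optional path so users can override any table without
touching code.
"""

from __future__ import annotations

import csv
from importlib import resources
from pathlib import Path
from typing import Iterable


def _open_default(name: str):
    return resources.files("agemine").joinpath("data", name).open("r", encoding="utf-8")


def _rows(name: str, path: str | Path | None) -> Iterable[dict]:
    handle = open(path, encoding="utf-8") if path is not None else _open_default(name)
    with handle:
        yield from csv.DictReader(handle, delimiter="\t")


def load_age_pattern_rows(path: str | Path | None = None) -> list[dict]:
    rows = list(_rows("age_patterns.tsv", path))
    for row in rows:
        row["priority"] = int(row["priority"])
    return rows


def load_relation_cue_rows(path: str | Path | None = None) -> list[dict]:
    rows = list(_rows("relation_cues.tsv", path))
    for row in rows:
        row["priority"] = int(row["priority"])
    return rows


def load_section_labels(path: str | Path | None = None) -> list[str]:
    return [row["label"] for row in _rows("section_labels.tsv", path)]


def load_gender_terms(path: str | Path | None = None) -> dict[str, set[str]]:
    table: dict[str, set[str]] = {"MALE": set(), "FEMALE": set()}
    for row in _rows("gender_terms.tsv", path):
        table[row["gender"]].add(row["term"].lower())
    return table


def load_subject_terms(path: str | Path | None = None) -> set[str]:
    return {row["term"].lower() for row in _rows("subject_terms.tsv", path)}
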