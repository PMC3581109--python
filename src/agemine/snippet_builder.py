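"""Evidence-snippet construction.

The snippet is the piece of text stored with each evidence instance: one to
three whole sentences, possibly non-consecutive, chosen to best capture the
phenotype information tied to the captured age.  The sentence containing the
age mention is always included.  Up to two companion sentences are added by a
transparent score:

* +3 if the sentence sits in a CONCLUSION(S)-type section, or is the final
  sentence of an unstructured abstract (the "concluding sentence");
* +2 if it mentions patients/subjects/cases/participants;
* +2 if it contains a cue word of the assigned relationship type;
* +1 if it is adjacent to the age sentence.

The two highest-scoring sentences with positive score are kept, ties broken
by earlier position.  Sentences are never truncated.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from ._tables import load_subject_terms
from .age_extraction import AgeMention
from .medline_io import AbstractRecord
from .relation_classifier import CueTable, default_cue_table

__all__ = ["Snippet", "build_snippet"]

_CONCLUSION_LABELS = {"CONCLUSION", "CONCLUSIONS", "INTERPRETATION"}

_SUBJECT_TERMS: set[str] | None = None


def _subject_rx() -> re.Pattern:
    global _SUBJECT_TERMS
    if _SUBJECT_TERMS is None:
        _SUBJECT_TERMS = load_subject_terms()
    return re.compile(
        r"\b(?:" + "|".join(re.escape(t) for t in sorted(_SUBJECT_TERMS)) + r")\b",
        re.IGNORECASE,
    )


@dataclass(frozen=True)
class Snippet:
    pmid: str
    sentence_indices: tuple[int, ...]
    text: str

    def to_dict(self) -> dict:
        return {
            "pmid": self.pmid,
            "sentence_indices": list(self.sentence_indices),
            "text": self.text,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Snippet":
        return cls(d["pmid"], tuple(d["sentence_indices"]), d["text"])


def build_snippet(
    record: AbstractRecord,
    mention: AgeMention,
    rel: str,
    cue_table: CueTable | None = None,
    *,
    max_sentences: int = 3,
) -> Snippet:
    """Build the evidence snippet for one (record, mention, relationship)."""
    if rel == "UNDETERMINED":
        raise ValueError("cannot build a snippet for an undetermined relationship")
    if not record.sentences:
        raise ValueError("record must be sentence-segmented")
    cue_table = cue_table or default_cue_table()

    age_idx = mention.sentence_index
    sentences = record.sentences
    structured = any(s.section_label is not None for s in sentences)
    rel_cues = [
        re.compile(r"\b" + r"\s+".join(re.escape(t) for t in cue.split()) + r"\b",
                   re.IGNORECASE)
        for cue in cue_table.cues_for(rel)
    ]
    subj = _subject_rx()

    scored: list[tuple[int, int]] = []  # (-score, index)
    for s in sentences:
        if s.index == age_idx:
            continue
        score = 0
        if s.section_label in _CONCLUSION_LABELS:
            score += 3
        elif not structured and s.index == len(sentences) - 1:
            score += 3
        if subj.search(s.text):
            score += 2
        if any(rx.search(s.text) for rx in rel_cues):
            score += 2
        if abs(s.index - age_idx) == 1:
            score += 1
        if score > 0:
            scored.append((-score, s.index))
    scored.sort()
    companions = [idx for _neg, idx in scored[: max_sentences - 1]]

    indices = tuple(sorted({age_idx, *companions}))
    text = " ".join(sentences[i].text for i in indices)
    return Snippet(pmid=record.pmid, sentence_indices=indices, text=text)
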