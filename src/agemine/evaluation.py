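"""Scoring harness for the four pipeline-quality tasks.

Pipeline outputs are compared against gold annotations produced by a human
reader for (1) age-related abstract detection, (2) relationship-type
assignment, (3) snippet quality, and (4) phenotype mapping.  Quality is
reported as precision (fraction of retrieved instances that are relevant),
sensitivity (fraction of relevant instances retrieved) and their harmonic
mean, the F-score.

Phenotype mapping supports two scoring modes for *harmless* extra mappings —
redundant or overly general concepts that add no erroneous information
(e.g. "carcinoma" alongside "squamous cell carcinoma").  In
``HARMLESS_EXCLUDED`` mode such extras are removed before false positives
are counted; in ``HARMLESS_AS_FP`` they count against precision.  Gold
phenotypes absent from both lexicons are true negatives and excluded from
the denominator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

__all__ = [
    "PRF",
    "GoldAnnotation",
    "f_score",
    "evaluate_age_detection",
    "evaluate_relationship",
    "evaluate_snippet_quality",
    "evaluate_mapping",
    "HARMLESS_EXCLUDED",
    "HARMLESS_AS_FP",
]

HARMLESS_EXCLUDED = "HARMLESS_EXCLUDED"
HARMLESS_AS_FP = "HARMLESS_AS_FP"


def f_score(precision: float, sensitivity: float) -> float:
    """Harmonic mean of precision and sensitivity; 0 when both are 0."""
    if not (0 <= precision <= 1) or not (0 <= sensitivity <= 1):
        raise ValueError("precision and sensitivity must lie in [0, 1]")
    denom = precision + sensitivity
    if denom == 0:
        return 0.0
    return 2 * precision * sensitivity / denom


@dataclass(frozen=True)
class PRF:
    precision: float
    sensitivity: float

    @property
    def f(self) -> float:
        return f_score(self.precision, self.sensitivity)


@dataclass(frozen=True)
class GoldAnnotation:
    """One gold record; fields beyond ``is_age_related`` apply per task."""

    pmid: str
    is_age_related: bool
    gold_low: float | None = None
    gold_high: float | None = None
    gold_inferred: bool = False
    gold_relationship: str | None = None
    gold_snippet_quality: str | None = None  # COMPLETE | MISSING_INFO | ERRONEOUS
    gold_phenotypes: frozenset[str] = field(default_factory=frozenset)
    harmless_ids: frozenset[str] = field(default_factory=frozenset)
    out_of_lexicon: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.is_age_related and self.gold_low is None:
            raise ValueError(f"gold record {self.pmid}: age-related but no range")


@dataclass(frozen=True)
class AgeDetectionResult:
    prf: PRF
    perfect_range_fraction: float | None
    tp: int
    fp: int
    fn: int


def evaluate_age_detection(
    predictions: dict[str, tuple[float, float] | None],
    gold: dict[str, GoldAnnotation],
) -> AgeDetectionResult:
    """Score age-related-abstract detection plus range exactness.

    ``predictions`` maps pmid -> (low, high) for records the pipeline deemed
    age-related, or None.  Both dicts must cover the same pmids.  The
    perfect-range fraction is computed over true positives with exact
    [low, high] agreement.
    """
    if set(predictions) != set(gold):
        missing = set(predictions) ^ set(gold)
        raise ValueError(f"pmid mismatch between predictions and gold: {sorted(missing)[:5]}")
    tp = fp = fn = 0
    perfect = 0
    for pmid, g in gold.items():
        pred = predictions[pmid]
        if pred is not None and g.is_age_related:
            tp += 1
            if pred[0] == g.gold_low and pred[1] == g.gold_high:
                perfect += 1
        elif pred is not None:
            fp += 1
        elif g.is_age_related:
            fn += 1
    if tp + fp == 0:
        if tp + fn > 0:
            warnings.warn("nothing retrieved; precision reported as 0")
        precision = 0.0
    else:
        precision = tp / (tp + fp)
    sensitivity = tp / (tp + fn) if tp + fn else 0.0
    return AgeDetectionResult(
        prf=PRF(precision, sensitivity),
        perfect_range_fraction=(perfect / tp) if tp else None,
        tp=tp, fp=fp, fn=fn,
    )


@dataclass(frozen=True)
class RelationshipResult:
    correct: float
    undetermined: float
    incorrect_of_assigned: float | None
    n_evaluated: int


def evaluate_relationship(
    predictions: dict[str, str],
    gold: dict[str, GoldAnnotation],
) -> RelationshipResult:
    """Score relationship-type assignment on gold age-related records.

    ``correct`` and ``undetermined`` are fractions of all evaluated records;
    ``incorrect_of_assigned`` is a fraction of records that received a
    non-UNDETERMINED prediction (None when nothing was assigned).
    """
    evaluated = [g for g in gold.values() if g.is_age_related]
    if not evaluated:
        raise ValueError("no age-related gold records to evaluate")
    n = len(evaluated)
    correct = undetermined = incorrect = 0
    for g in evaluated:
        pred = predictions.get(g.pmid, "UNDETERMINED")
        if pred == "UNDETERMINED":
            undetermined += 1
        elif pred == g.gold_relationship:
            correct += 1
        else:
            incorrect += 1
    assigned = n - undetermined
    return RelationshipResult(
        correct=correct / n,
        undetermined=undetermined / n,
        incorrect_of_assigned=(incorrect / assigned) if assigned else None,
        n_evaluated=n,
    )


def evaluate_snippet_quality(gold: dict[str, GoldAnnotation]) -> dict[str, float]:
    """Fractions of snippets judged complete / missing info / erroneous.

    Operates on gold records carrying a snippet-quality judgement (the
    human reader's comparison of the machine snippet to their own).
    """
    judged = [g for g in gold.values() if g.gold_snippet_quality is not None]
    if not judged:
        raise ValueError("no snippet-quality judgements in gold")
    n = len(judged)
    counts = {"COMPLETE": 0, "MISSING_INFO": 0, "ERRONEOUS": 0}
    for g in judged:
        if g.gold_snippet_quality not in counts:
            raise ValueError(
                f"unknown snippet quality {g.gold_snippet_quality!r}"
            )
        counts[g.gold_snippet_quality] += 1
    return {k.lower(): v / n for k, v in counts.items()}


def evaluate_mapping(
    predicted: dict[str, frozenset[str] | set[str]],
    gold: dict[str, GoldAnnotation],
    mode: str = HARMLESS_EXCLUDED,
) -> PRF:
    """Score phenotype mapping per instance, pooled over all instances.

    For each instance: TP = predicted ∩ gold; FN = gold \\ predicted
    (gold phenotypes flagged out-of-lexicon are excluded first — they are
    true negatives); extras = predicted \\ gold.  In HARMLESS_EXCLUDED mode
    extras listed as harmless are discarded before FP counting; in
    HARMLESS_AS_FP they count as false positives.
    """
    if mode not in (HARMLESS_EXCLUDED, HARMLESS_AS_FP):
        raise ValueError(f"unknown mode {mode!r}")
    tp = fp = fn = 0
    for key, pred in predicted.items():
        g = gold[key]
        gold_set = set(g.gold_phenotypes) - set(g.out_of_lexicon)
        pred_set = set(pred)
        tp += len(pred_set & gold_set)
        fn += len(gold_set - pred_set)
        extras = pred_set - gold_set
        if mode == HARMLESS_EXCLUDED:
            extras -= set(g.harmless_ids)
        fp += len(extras)
    if tp + fp == 0:
        if tp + fn > 0:
            warnings.warn("nothing retrieved; precision reported as 0")
        precision = 0.0
    else:
        precision = tp / (tp + fp)
    sensitivity = tp / (tp + fn) if tp + fn else 0.0
    return PRF(precision, sensitivity)


# ---------------------------------------------------------------------------
# Gold TSV I/O

_GOLD_COLUMNS = [
    "pmid", "is_age_related", "low", "high", "inferred", "relationship",
    "snippet_quality", "phenotypes", "harmless", "out_of_lexicon",
]


def write_gold_tsv(gold: dict[str, GoldAnnotation], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(_GOLD_COLUMNS) + "\n")
        for pmid in sorted(gold, key=str):
            g = gold[pmid]
            fh.write("\t".join([
                g.pmid,
                "1" if g.is_age_related else "0",
                "" if g.gold_low is None else repr(g.gold_low),
                "" if g.gold_high is None else repr(g.gold_high),
                "1" if g.gold_inferred else "0",
                g.gold_relationship or "",
                g.gold_snippet_quality or "",
                ",".join(sorted(g.gold_phenotypes)),
                ",".join(sorted(g.harmless_ids)),
                ",".join(sorted(g.out_of_lexicon)),
            ]) + "\n")


def read_gold_tsv(path) -> dict[str, GoldAnnotation]:
    gold: dict[str, GoldAnnotation] = {}
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _GOLD_COLUMNS:
            raise ValueError(f"gold TSV must have columns {_GOLD_COLUMNS}")
        for line in fh:
            if not line.strip():
                continue
            (pmid, rel_flag, low, high, inferred, rel, quality,
             phen, harmless, out_of_lex) = line.rstrip("\n").split("\t")
            gold[pmid] = GoldAnnotation(
                pmid=pmid,
                is_age_related=rel_flag == "1",
                gold_low=float(low) if low else None,
                gold_high=float(high) if high else None,
                gold_inferred=inferred == "1",
                gold_relationship=rel or None,
                gold_snippet_quality=quality or None,
                gold_phenotypes=frozenset(p for p in phen.split(",") if p),
                harmless_ids=frozenset(p for p in harmless.split(",") if p),
                out_of_lexicon=frozenset(p for p in out_of_lex.split(",") if p),
            )
    return gold
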