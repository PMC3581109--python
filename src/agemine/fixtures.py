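"""Seeded synthetic corpora, mini-ontology, concept lexicon and gold files.

Real inputs to the mining pipeline — millions of PubMed abstracts, the
Disease Ontology, a licensed concept vocabulary — cannot ship with a test
suite, so this module generates small, fully-known substitutes.  Every
abstract is templated English ("{Disease} was diagnosed in a {age}-year-old
{noun}.") with a planted age (rendered through one of the package's own
extraction patterns), relationship cue, disease name and gender mix, and a
gold file records every planted value.  A fixed seed gives byte-identical
output, so recovery of the planted values is an exact, repeatable check.

The generator emulates the structural features the pipeline keys on
(numeric ages, open-ended ranges, structured abstracts, cue verbs, gendered
nouns); it does not attempt linguistic realism or PubMed's topic
distribution, so pipeline accuracy on it bounds template-level behaviour
only, not performance on free text.

:func:`generate_two_group_fixture` plants two disease groups whose
literature age profiles peak in the early 20s and around age 60 — the
classic STD-versus-cancer/cardiovascular contrast — for exercising the
clustering stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .age_extraction import AgeRange, assign_age_class
from .evaluation import GoldAnnotation, write_gold_tsv
from .evidence_store import EvidenceInstance, EvidenceStore
from .lexicon_mapper import ConceptHit, normalize
from .snippet_builder import Snippet

__all__ = [
    "DiseaseSpec",
    "FixtureSpec",
    "FixtureCorpus",
    "default_disease_pool",
    "build_mini_obo",
    "build_concept_tsv",
    "generate_corpus",
    "generate_two_group_fixture",
    "YOUNG_GROUP",
    "OLD_GROUP",
]


@dataclass(frozen=True)
class DiseaseSpec:
    term_id: str
    name: str
    parent: str | None = None
    synonyms: tuple[str, ...] = ()
    xref: str | None = None
    mean_age: float = 40.0
    sd_age: float = 8.0
    mineable: bool = True  # used in generated abstracts (leaves only)


def default_disease_pool() -> list[DiseaseSpec]:
    """A 17-term mini disease ontology with two age-localized groups."""
    return [
        DiseaseSpec("DOID:0001", "disease", None, mineable=False),
        DiseaseSpec("DOID:0050", "infectious disease", "DOID:0001", mineable=False),
        DiseaseSpec("DOID:0200", "cancer", "DOID:0001",
                    synonyms=("malignant neoplasm",), mineable=False),
        DiseaseSpec("DOID:0201", "carcinoma", "DOID:0200",
                    xref="UMLS_CUI:C0007137", mineable=False),
        DiseaseSpec("DOID:0300", "cardiovascular system disease", "DOID:0001",
                    mineable=False),
        # young-peaking group (sexually transmitted infections)
        DiseaseSpec("DOID:0100", "gonorrhea", "DOID:0050", mean_age=19, sd_age=2.5),
        DiseaseSpec("DOID:0101", "chlamydia", "DOID:0050", mean_age=20, sd_age=2.5),
        DiseaseSpec("DOID:0102", "genital herpes", "DOID:0050",
                    synonyms=("herpes genitalis",), mean_age=21, sd_age=2.5),
        DiseaseSpec("DOID:0103", "syphilis", "DOID:0050", mean_age=21, sd_age=2.5),
        DiseaseSpec("DOID:0104", "hiv infection", "DOID:0050", mean_age=22, sd_age=2.5),
        # old-peaking group (cancers, cardiovascular)
        DiseaseSpec("DOID:0202", "squamous cell carcinoma", "DOID:0201",
                    synonyms=("SCC",), xref="UMLS_CUI:C0751362",
                    mean_age=58, sd_age=4),
        DiseaseSpec("DOID:0204", "lung carcinoma", "DOID:0201", mean_age=63, sd_age=4),
        DiseaseSpec("DOID:0301", "myocardial infarction", "DOID:0300",
                    mean_age=61, sd_age=4),
        DiseaseSpec("DOID:0302", "hypertension", "DOID:0300", mean_age=60, sd_age=4),
        DiseaseSpec("DOID:0402", "parkinson disease", "DOID:0001",
                    mean_age=60, sd_age=4),
        # mid-life extras
        DiseaseSpec("DOID:0203", "leukemia", "DOID:0200",
                    xref="UMLS_CUI:C0023418", mean_age=10, sd_age=5),
        DiseaseSpec("DOID:0401", "obesity", "DOID:0001", mean_age=40, sd_age=8),
    ]


YOUNG_GROUP = ("DOID:0100", "DOID:0101", "DOID:0102", "DOID:0103", "DOID:0104")
OLD_GROUP = ("DOID:0202", "DOID:0204", "DOID:0301", "DOID:0302", "DOID:0402")


def build_mini_obo(pool: list[DiseaseSpec] | None = None) -> str:
    pool = pool if pool is not None else default_disease_pool()
    names = {d.term_id: d.name for d in pool}
    lines = ["format-version: 1.2", "ontology: agemine-fixture", ""]
    for d in pool:
        lines.append("[Term]")
        lines.append(f"id: {d.term_id}")
        lines.append(f"name: {d.name}")
        for syn in d.synonyms:
            lines.append(f'synonym: "{syn}" EXACT []')
        if d.parent is not None:
            lines.append(f"is_a: {d.parent} ! {names[d.parent]}")
        if d.xref is not None:
            lines.append(f"xref: {d.xref}")
        lines.append("")
    return "\n".join(lines)


def build_concept_tsv() -> str:
    """A mini concept-subset lexicon (synthetic stand-in for a licensed
    vocabulary): disease synonym spellings, drugs, findings, and one
    out-of-scope gene row that loaders must drop."""
    rows = [
        ("C0023418", "disease", "leukaemia"),
        ("C0041296", "disease", "tuberculosis"),
        ("C0004057", "drug", "aspirin"),
        ("C0025598", "drug", "metformin"),
        ("C0015967", "finding", "fever"),
        ("C0018681", "finding", "headache"),
        ("G0001", "gene", "brca1"),
    ]
    return "concept_id\tsemantic_type\tstring\n" + "".join(
        "\t".join(r) + "\n" for r in rows
    )


def _harmless_map(pool: list[DiseaseSpec]) -> dict[str, frozenset[str]]:
    """For each mineable disease, the pool terms whose name/synonym occurs
    inside its name on token boundaries (these will surface as harmless
    redundant hits when the longer name is matched)."""
    out: dict[str, frozenset[str]] = {}
    for d in pool:
        tokens = normalize(d.name).split()
        nested = set()
        for other in pool:
            if other.term_id == d.term_id:
                continue
            for s in (other.name, *other.synonyms):
                stoks = normalize(s).split()
                n = len(stoks)
                if n == 0 or n >= len(tokens):
                    continue
                if any(tokens[i:i + n] == stoks for i in range(len(tokens) - n + 1)):
                    nested.add(other.term_id)
        out[d.term_id] = frozenset(nested)
    return out


@dataclass
class FixtureSpec:
    """Parameters of the synthetic corpus generator."""

    seed: int
    n_abstracts: int = 200
    disease_pool: list[DiseaseSpec] = field(default_factory=default_disease_pool)
    relationship_mix: dict[str, float] = field(default_factory=lambda: {
        "AGE_OF_ONSET": 0.18,
        "AGE_OF_DIAGNOSIS": 0.18,
        "AGE_OF_OBSERVATION": 0.18,
        "AGE_OF_OCCURRENCE": 0.18,
        "AGE_OF_EVALUATION": 0.18,
        "NONE": 0.10,
    })
    inferred_fraction: float = 0.10
    range_fraction: float = 0.25
    age_free_fraction: float = 0.0
    gender_mix: dict[str, float] = field(default_factory=lambda: {
        "MALE": 0.30, "FEMALE": 0.30, "NONE": 0.40,
    })
    structured_fraction: float = 0.30

    def __post_init__(self) -> None:
        if not self.disease_pool or not any(d.mineable for d in self.disease_pool):
            raise ValueError("disease pool must contain at least one mineable disease")
        for name, weights in (("relationship_mix", self.relationship_mix),
                              ("gender_mix", self.gender_mix)):
            total = sum(weights.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"{name} weights must sum to 1, got {total}")
        for name, frac in (("inferred_fraction", self.inferred_fraction),
                           ("range_fraction", self.range_fraction),
                           ("age_free_fraction", self.age_free_fraction),
                           ("structured_fraction", self.structured_fraction)):
            if not 0 <= frac <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if any(d.sd_age <= 0 for d in self.disease_pool):
            raise ValueError("age profile sd must be positive")


@dataclass
class FixtureCorpus:
    medline_text: str
    obo_text: str
    concept_tsv: str
    gold: dict[str, GoldAnnotation]
    planted: dict[str, dict]

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "corpus.medline").write_text(self.medline_text, encoding="utf-8")
        (outdir / "ontology.obo").write_text(self.obo_text, encoding="utf-8")
        (outdir / "concepts.tsv").write_text(self.concept_tsv, encoding="utf-8")
        write_gold_tsv(self.gold, outdir / "gold.tsv")


_NOUNS = {
    "MALE": ("man", "men"),
    "FEMALE": ("woman", "women"),
    "NONE": ("patient", "patients"),
}


def _sample_age(rng: np.random.Generator, mean: float, sd: float) -> int:
    while True:
        a = rng.normal(mean, sd)
        if 0 <= a <= 120:
            return int(round(a))


def _weighted_choice(rng: np.random.Generator, weights: dict[str, float]) -> str:
    keys = sorted(weights)
    p = np.array([weights[k] for k in keys], dtype=float)
    return keys[rng.choice(len(keys), p=p / p.sum())]


def _age_phrase(rng, form, age, lo, hi, inferred_high, noun_sg, noun_pl):
    if form == "point":
        variant = rng.integers(4)
        if variant == 0:
            return f"a {age}-year-old {noun_sg}"
        if variant == 1:
            return f"a {noun_sg} aged {age} years"
        if variant == 2:
            return f"a {noun_sg} at age {age}"
        return f"a {noun_sg} of {age} years of age"
    if form == "range":
        variant = rng.integers(3)
        if variant == 0:
            return f"{noun_pl} between {lo} and {hi} years of age"
        if variant == 1:
            return f"{noun_pl} aged {lo} to {hi} years"
        return f"{noun_pl} {lo} to {hi} years old"
    # inferred
    if inferred_high:
        if rng.integers(2) == 0:
            return f"{noun_pl} older than {lo} years"
        return f"{noun_pl} aged {lo} years or more"
    if rng.integers(2) == 0:
        return f"{noun_pl} aged {hi} years or less"
    return f"{noun_pl} younger than {hi} years"


_CUE_SENTENCE = {
    "AGE_OF_ONSET": "Onset of {disease} was noted in {phrase}.",
    "AGE_OF_DIAGNOSIS": "{Disease} was diagnosed in {phrase}.",
    "AGE_OF_OBSERVATION": "{Disease} was observed in {phrase}.",
    "AGE_OF_OCCURRENCE": "{Disease} occurred in {phrase}.",
    "AGE_OF_EVALUATION": "{Disease} was evaluated in {phrase}.",
    "NONE": "{Disease} was reported in {phrase}.",
}


def generate_corpus(spec: FixtureSpec) -> FixtureCorpus:
    """Generate a MEDLINE corpus plus ontology, concept lexicon and gold files.

    Identical seeds give byte-identical output.  Every abstract plants one
    age expression (unless age-free), at most one relationship cue, one
    disease name and a controlled gender mix, all recorded in ``gold`` and
    ``planted``.
    """
    rng = np.random.default_rng(spec.seed)
    leaves = [d for d in spec.disease_pool if d.mineable]
    harmless = _harmless_map(spec.disease_pool)

    blocks: list[str] = []
    gold: dict[str, GoldAnnotation] = {}
    planted: dict[str, dict] = {}

    for i in range(spec.n_abstracts):
        pmid = str(1000 + i)
        disease = leaves[rng.integers(len(leaves))]
        gender = _weighted_choice(rng, spec.gender_mix)
        rel = _weighted_choice(rng, spec.relationship_mix)
        noun_sg, noun_pl = _NOUNS[gender]
        year = int(rng.integers(1990, 2012))

        age_free = rng.random() < spec.age_free_fraction
        if age_free:
            low = high = None
            inferred = False
            age_sentence = _CUE_SENTENCE[rel].format(
                disease=disease.name, Disease=disease.name.capitalize(),
                phrase=f"clinical {noun_pl}",
            )
        else:
            age = _sample_age(rng, disease.mean_age, disease.sd_age)
            u = rng.random()
            if u < spec.inferred_fraction:
                form = "inferred"
                inferred_high = bool(rng.integers(2))
                if inferred_high:
                    low, high = float(age), 120.0
                else:
                    low, high = 0.0, float(age)
                lo, hi = age, age
            elif u < spec.inferred_fraction + spec.range_fraction:
                form = "range"
                width = int(rng.integers(2, 9))
                lo, hi = age, min(age + width, 120)
                low, high = float(lo), float(hi)
                inferred = False
                inferred_high = False
            else:
                form = "point"
                lo = hi = age
                low = high = float(age)
                inferred = False
                inferred_high = False
            inferred = form == "inferred"
            phrase = _age_phrase(rng, form, age, lo, hi,
                                 inferred_high if form == "inferred" else False,
                                 noun_sg, noun_pl)
            age_sentence = _CUE_SENTENCE[rel].format(
                disease=disease.name, Disease=disease.name.capitalize(),
                phrase=phrase,
            )

        intro = (f"We studied the link between age and {disease.name} "
                 f"in the clinical literature.")
        methods = "Hospital records were reviewed retrospectively."
        concl = (f"In summary, these reports refine the relation between "
                 f"age and {disease.name}.")

        if rng.random() < spec.structured_fraction:
            abstract = (f"OBJECTIVE: {intro} METHODS: {methods} "
                        f"RESULTS: {age_sentence} CONCLUSIONS: {concl}")
        else:
            abstract = f"{intro} {methods} {age_sentence} {concl}"

        blocks.append("\n".join([
            f"PMID- {pmid}",
            f"TI  - Age patterns of {disease.name}.",
            f"AB  - {abstract}",
            f"DP  - {year} Jan",
            "PT  - Journal Article",
        ]))

        gold[pmid] = GoldAnnotation(
            pmid=pmid,
            is_age_related=not age_free,
            gold_low=low,
            gold_high=high,
            gold_inferred=inferred if not age_free else False,
            gold_relationship=None if rel == "NONE" else rel,
            gold_phenotypes=frozenset({disease.term_id}),
            harmless_ids=harmless[disease.term_id],
        )
        planted[pmid] = {
            "disease": disease.term_id,
            "gender": gender,
            "relationship": None if rel == "NONE" else rel,
            "low": low, "high": high,
            "inferred": inferred if not age_free else False,
            "is_age_related": not age_free,
            "pub_year": year,
        }

    return FixtureCorpus(
        medline_text="\n\n".join(blocks) + "\n",
        obo_text=build_mini_obo(spec.disease_pool),
        concept_tsv=build_concept_tsv(),
        gold=gold,
        planted=planted,
    )


def generate_two_group_fixture(
    seed: int,
    n_per_disease: int = 80,
) -> tuple[EvidenceStore, dict[str, int]]:
    """An evidence store with two planted disease groups for clustering.

    Five diseases draw instance ages from profiles peaking in the early 20s
    and five from profiles peaking around age 60.  Returns the store and the
    planted partition (term_id -> group 0 or 1).
    """
    rng = np.random.default_rng(seed)
    pool = {d.term_id: d for d in default_disease_pool()}
    store = EvidenceStore()
    partition: dict[str, int] = {}
    counter = 0
    for group, term_ids in enumerate((YOUNG_GROUP, OLD_GROUP)):
        for tid in term_ids:
            d = pool[tid]
            partition[tid] = group
            for _ in range(n_per_disease):
                age = _sample_age(rng, d.mean_age, d.sd_age)
                rel = ("AGE_OF_ONSET", "AGE_OF_DIAGNOSIS",
                       "AGE_OF_OBSERVATION")[rng.integers(3)]
                pmid = f"SYN{counter}"
                counter += 1
                text = f"{d.name.capitalize()} was diagnosed in a {age}-year-old patient."
                rng_range = AgeRange(float(age), float(age))
                store.add(EvidenceInstance(
                    instance_id=f"{pmid}:0",
                    pmid=pmid,
                    age_range=rng_range,
                    age_class=assign_age_class(rng_range).name,
                    relationship=rel,
                    snippet=Snippet(pmid, (0,), text),
                    hits=(ConceptHit("ONTOLOGY", tid, None, d.name, 0, len(d.name)),),
                    gender="NONE",
                    pub_year=2005,
                    pub_types=("Journal Article",),
                ))
    return store, partition
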