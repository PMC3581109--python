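# agemine

Rule-based mining of **age–phenotype evidence** from biomedical abstracts.

Biomedical literature is full of statements linking specific ages or age
ranges to diseases and other clinical phenotypes — "carcinoma was diagnosed
in a 59-year-old man", "onset typically occurs between 45 and 64 years" —
but that knowledge is scattered and hard to search. `agemine` implements a
complete extraction pipeline and knowledge base for such statements, aimed
at researchers studying age-related disease patterns and at text-mining
practitioners who need an inspectable, fully rule-driven baseline.

## What the pipeline does

Mining proceeds in four steps over MEDLINE-format abstracts:

1. **Find age-related abstracts.** A table of regular expressions detects
   numeric age mentions and normalizes each to a year interval
   [low, high]. Open-ended expressions ("30 years or less") are completed
   with the 0/120-year bounds and flagged *inferred*; spelled-out ages are
   deliberately ignored. Every range is also assigned the most specific
   age-ontology class containing it (Infant 0–2 y, Adolescent 12–18 y,
   Young adult 18–24 y, Middle aged 45–64 y, Aged 64–120 y, ...).
2. **Type the age–phenotype relationship.** Cue words co-occurring with the
   age mention — in the same sentence, then adjacent sentences, then the
   whole abstract — assign one of five relationships: *age of onset*,
   *age of diagnosis*, *age of observation*, *age of occurrence*,
   *age of evaluation*. No cue in any window means the candidate is dropped.
3. **Build an evidence snippet.** One to three whole sentences (possibly
   non-consecutive) are selected by a transparent score favouring the
   concluding sentence, patient/subject sentences, and sentences carrying
   the assigned relationship's cues.
4. **Map to phenotypes.** Disease-ontology names/synonyms and a
   concept-subset lexicon (diseases, drugs, findings) are matched exactly on
   token boundaries. Disease concepts cross-map into the ontology via its
   cross-references; nested or ancestral hits ("carcinoma" inside "squamous
   cell carcinoma") are kept but flagged as harmless redundancy. Gender is
   recorded when exactly one gender is mentioned in the snippet.

Instances passing the population filter (a determined relationship *and* at
least one phenotype) enter a queryable store searchable by age, by
phenotype (with ontology descendant expansion — querying *cancer* finds
every specific cancer), or both, with conjunctive refinement filters.
Downstream, a disease × age matrix of instance counts — normalized per
disease by its instance total, F(d, a) = N(d, a) / N(d) — is clustered
hierarchically with distance 1 − r (Pearson) to reveal groups of diseases
the literature associates with the same ages.

Evaluation utilities score each pipeline step against gold annotations with
precision P, sensitivity S, and F = 2PS/(P+S), including the two scoring
modes for harmless mappings.

## Worked example

No corpus download is needed: the package generates a fully-annotated
synthetic corpus whose planted ages, cues, diseases and genders are known.

```
$ agemine simulate --seed 7 --n-abstracts 200 --outdir fixtures
wrote 200 abstracts to fixtures

$ agemine populate --corpus fixtures/corpus.medline --obo fixtures/ontology.obo \
    --concepts fixtures/concepts.tsv --out apk.jsonl
{
  "records_in": 200,
  "age_related": 200,
  "candidates": 200,
  "relationship_assigned": 182,
  "dropped_undetermined": 18,
  "snippets_built": 182,
  "dropped_no_phenotype": 0,
  "populated": 182,
  ...
}
```

182 of 200 abstracts yielded an evidence instance; the other 18 contained an
age but no relationship cue, so the population filter dropped them
(populated + dropped_undetermined + dropped_no_phenotype = candidates).

```
$ agemine query --store apk.jsonl --obo fixtures/ontology.obo \
    --age-class Adolescent --phenotype DOID:0200
AGE_OF_ONSET: 1 instances
AGE_OF_DIAGNOSIS: 3 instances
AGE_OF_OBSERVATION: 1 instances
AGE_OF_OCCURRENCE: 3 instances
total: 8
```

Eight instances link some cancer (DOID:0200 or any descendant) to an age
range overlapping 12–18 years, grouped by relationship type.

```
$ agemine cluster --store apk.jsonl --min-instances 5 --out tree.nwk
clustered 12 diseases (average linkage)
```

The exported Newick tree separates the planted young-peaking infections
from the old-peaking cancers/cardiovascular diseases into two clades.

The same operations are available as library functions
(`agemine.run_pipeline`, `agemine.query`, `agemine.cluster_diseases`, ...);
see `docs/methods.md` for the full model description and parameter defaults.

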