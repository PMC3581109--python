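# Methods

This note documents the model behind `agemine`, its tunable parameters, the
numerical conventions, and what the synthetic-data tests do and do not show.

## Pipeline model

The pipeline is deliberately rule-based: every behaviour is a table of
patterns shipped as TSV data (`src/agemine/data/`) and overridable per run.
This trades linguistic coverage for inspectability and determinism — the
same corpus and tables always produce a byte-identical evidence store.

### Age detection and normalization

Ages must be numeric; word-numbers ("sixty-five") and relative durations
("two years after surgery") are out of scope, the latter excluded by
requiring an age-anchoring token (`year/month/week/day old/aged/of age`) in
every pattern. Units convert at 1 month = 1/12 y, 1 week = 1/52 y,
1 day = 1/365 y; all bounds clamp to [0, 120]. The 120-year ceiling is the
upper bound of the Adult age class and is also used to complete open-ended
expressions: "under 30 years" → [0, 30], "over 65" → [65, 120], both
flagged *inferred* because one bound was never stated.

Overlapping pattern matches resolve **longest-match-first**, then by
pattern priority (explicit range > open-ended > point > mean age), then by
position. Longest-first matters: "mean age of 52" must win over its nested
substring "age of 52", otherwise a cohort mean masquerades as an explicit
age and defeats the range-over-mean preference below.

One candidate instance is produced per distinct normalized range. When an
abstract states both an explicit age/range and a mean/median age, the
explicit mention wins and the mean is discarded; `legacy_mean_priority`
inverts this (reproducing the historical failure mode of extracting a
cohort's mean age even when the full range is present elsewhere).

### Age classes

An age range is assigned the most specific class whose interval contains
it, "most specific" meaning smallest interval width; ties break by
declaration order. The classes (Infant newborn 0–1 mo, Infant 0–2 y,
Preschool child 2–6 y, Child 2–12 y, Adolescent 12–18 y, Young adult
18–24 y, Adult 18–120 y, Middle aged 45–64 y, Aged 64–120 y, 80-and-over
80–120 y, root 0–120 y) overlap, so e.g. [18, 24] resolves to Young adult,
not Adult. Ranges straddling class boundaries ([5, 15]) fall to the root.
Because Infant ∪ Child ∪ Adolescent ∪ Adult covers [0, 120], every point
age receives a non-root class; the test suite asserts this.

### Relationship typing

A candidate is typed by cue words that must co-occur with the age mention
inside a window — the mention's sentence, then the adjacent sentences, then
the whole abstract; the first non-empty window decides. This makes
assignment stricter than bag-of-words co-occurrence. Within a window the
priority order is onset > diagnosis > observation > occurrence >
evaluation (clinically specific events outrank generic study verbs); ties
resolve to the cue nearest the mention, then the earlier one. No firing cue
means UNDETERMINED, and the candidate never reaches the store. The default
cue table (22 cues) lives in `relation_cues.tsv`.

### Snippet construction

The snippet always contains the age sentence, plus up to two companions
with positive score: +3 for a CONCLUSION(S)/INTERPRETATION section sentence
or the final sentence of an unstructured abstract, +2 for a
patient/subject term, +2 for a cue of the assigned relationship, +1 for
adjacency to the age sentence; ties break by earlier position. Sentences
are whole by construction — the segmenter (terminal punctuation + capital
start, with an abbreviation list and a no-split rule inside decimals)
records character offsets, and snippets concatenate sentence texts
verbatim. The 3-sentence cap and the +3/+2/+2/+1 weights are design
choices; the factors they encode (concluding sentence, subject sentences,
structure, relationship type) are the stated selection criteria of the
original procedure, whose full rule is not public.

### Phenotype mapping

Matching is perfect-match only: strings normalize by lowercasing and
collapsing every non-alphanumeric run to one space (idempotent; hyphen ≡
space), and occurrences require token boundaries, so "human" never matches
"man" and "sccx" never matches "SCC". All occurrences are reported,
including nested ones; a hit is flagged **redundant** when its span lies
strictly inside another hit's span or its ontology term is a strict
ancestor of another hit's term. Redundant hits are harmless — they add
generality, not error — and are excluded from queries and clustering by
default (flags restore them). Disease-type concept hits cross-map to the
ontology term whose xref lists the concept ID (indexed both verbatim and by
bare ID). The concept lexicon is a neutral three-column TSV restricted to a
semantic-type allow-list defaulting to {disease, drug, finding}.

### Evidence store and queries

Only instances with a determined relationship and ≥1 phenotype hit are
stored (re-validated on load). Age queries use **interval intersection** —
the browser question "what is linked to this age range?" is naturally
overlap semantics — with a `contained` strict mode. Phenotype queries
expand to is_a descendants and are conjunctive across multiple query
terms, as are all refinement filters (year, publication type, curation,
relationship, gender). The wiki preset drops age-of-occurrence and
age-of-evaluation instances and inferred ranges. Persistence is JSON lines
with a versioned header plus an optional relational TSV export
(instance/hit/snippet tables) mirroring SQL-style access.

### Disease–age matrix and clustering

Inferred ranges are excluded from the matrix: [0, 30] inferred from
"30 years or less" carries no information about where evidence
concentrates. Each remaining instance increments every integer age in its
range, fractional bounds rounded outward. Normalization divides each
disease row by that disease's **instance count** (a literal reading of
"instances associated with that disease"; `row_sum` normalization is the
alternative flag) — note a normalized row sums to >1 when instances span
multiple ages. Clustering uses distance 1 − Pearson r on normalized rows
(condensed distances via scipy; values clipped to [0, 2] against rounding),
average linkage by default (complete/single available), `min_instances`
defaulting to 5 to suppress unstable singleton rows, and zero-variance rows
excluded because r is undefined for them. Trees export as rooted Newick
with ultrametric branch lengths (node height = merge distance / 2; labels
with `:` quoted).

### Evaluation harness

Precision = TP/(TP+FP), sensitivity = TP/(TP+FN), F = 2PS/(P+S) (defined
as 0 at P = S = 0; inputs outside [0, 1] rejected). Zero-denominator
conventions are explicit: precision is 0 (with a warning) when nothing was
retrieved but gold is non-empty; the incorrect-of-assigned fraction is None
when nothing was assigned. Mapping supports harmless-excluded (harmless
extras removed before FP counting) and harmless-as-FP modes; the former's
precision always dominates the latter's, with equal sensitivity. Gold
phenotypes flagged out-of-lexicon are true negatives and excluded. Gold
files are a documented 10-column TSV so any annotator can re-run the
four-task protocol.

## Synthetic data

The fixture generator plants, per abstract: one disease from a 17-term
mini-ontology (names, synonyms, is_a edges, xrefs), one age expression
rendered through the package's own pattern repertoire, at most one
relationship cue, and a controlled gender mix. Defaults — 200 abstracts;
relationship mix 0.18 per type + 0.10 cue-free; 10% inferred and 25% range
expressions; gender 30/30/40 male/female/none; 30% structured abstracts —
were fixed once as a plausible mix exercising every code path, and are not
tuned. The two-group clustering fixture draws 80 point-age instances per
disease for five infection-like diseases (profile means 19–22 y, sd 2.5)
and five cancer/cardiovascular-like diseases (means 58–63 y, sd 4),
mirroring the young-STI versus late-life-disease contrast such matrices
show; the planted partition and peaks are the recovery targets.

Because abstracts are templated, passing the 100%-recovery tests shows the
pipeline's rules are internally consistent and lossless on text drawn from
its own pattern/cue repertoire — not that they cover free-text PubMed
prose, where sensitivity is necessarily lower (textual ages, unseen cue
phrasings, nested clauses are all missed by design or by table coverage).

## Known limitations

- Conditional relationships are not modelled: an abstract about ulcer ages
  in HIV-positive patients links the age to both ulcers and HIV.
- No negation handling, abbreviation expansion, or disambiguation in
  mapping; no title mining by default (flag available).
- Evaluation of mapping is biased toward catching errors of commission;
  omissions outside both lexicons are invisible to it.
- Problem sizes in the test suite (120–200-abstract corpora, 800-instance
  cluster fixtures, 1,000-snippet mapping-oracle sweeps, 20-seed recovery
  loops) were chosen as the smallest sizes at which the checked properties
  are non-trivial and stable.
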