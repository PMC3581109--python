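import pytest

from agemine.fixtures import FixtureSpec, generate_corpus
from agemine.lexicon_mapper import load_concept_subset, load_ontology
from agemine.medline_io import parse_medline, segment_sentences


def make_record(abstract: str, pmid: str = "1", title: str = "T."):
    """Parse a single-abstract MEDLINE blob into a segmented record."""
    text = f"PMID- {pmid}\nTI  - {title}\nAB  - {abstract}\nDP  - 2005 Jan\nPT  - Journal Article\n"
    records, _ = parse_medline(text)
    return segment_sentences(records[0])


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    """A 120-abstract synthetic corpus written to disk once per session."""
    outdir = tmp_path_factory.mktemp("fixture")
    corpus = generate_corpus(FixtureSpec(seed=11, n_abstracts=120))
    corpus.write(outdir)
    return outdir


@pytest.fixture(scope="session")
def fixture_corpus():
    return generate_corpus(FixtureSpec(seed=11, n_abstracts=120))


@pytest.fixture(scope="session")
def ontology(fixture_dir):
    return load_ontology(fixture_dir / "ontology.obo")


@pytest.fixture(scope="session")
def concepts(fixture_dir):
    return load_concept_subset(fixture_dir / "concepts.tsv")
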