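"""Evidence assembly, the population filter, persistence, and queries."""

import itertools

import pytest

from agemine.age_extraction import AgeRange, assign_age_class
from agemine.evidence_store import (
    EvidenceInstance,
    EvidenceStore,
    QueryCriteria,
    StoreFormatError,
    assemble_instance,
    flatten,
    query,
    read_store,
    write_store,
)
from agemine.lexicon_mapper import ConceptHit
from agemine.snippet_builder import Snippet
from conftest import make_record


def make_instance(i, term="DOID:0100", low=20, high=20, rel="AGE_OF_DIAGNOSIS",
                  inferred=False, gender="NONE", year=2005, curated=False):
    r = AgeRange(low, high, inferred=inferred)
    return EvidenceInstance(
        instance_id=f"{i}:0",
        pmid=str(i),
        age_range=r,
        age_class=assign_age_class(r).name,
        relationship=rel,
        snippet=Snippet(str(i), (0,), f"Case {i}."),
        hits=(ConceptHit("ONTOLOGY", term, None, term, 0, 4),),
        gender=gender,
        pub_year=year,
        pub_types=("Journal Article",),
        curated=curated,
    )


@pytest.fixture()
def ten_instance_store():
    """10 instances: 3 AGE_OF_OCCURRENCE, 2 inferred (disjoint sets)."""
    insts = [
        make_instance(0, rel="AGE_OF_OCCURRENCE"),
        make_instance(1, rel="AGE_OF_OCCURRENCE"),
        make_instance(2, rel="AGE_OF_OCCURRENCE"),
        make_instance(3, low=0, high=30, inferred=True),
        make_instance(4, low=50, high=120, inferred=True, rel="AGE_OF_ONSET"),
        make_instance(5, rel="AGE_OF_ONSET"),
        make_instance(6, rel="AGE_OF_OBSERVATION"),
        make_instance(7),
        make_instance(8, rel="AGE_OF_EVALUATION"),
        make_instance(9),
    ]
    return EvidenceStore(insts)


class TestAssembly:
    def setup_method(self):
        from agemine.age_extraction import extract_age_mentions
        self.rec = make_record("A 59-year-old man was diagnosed with carcinoma.")
        (self.mention,) = extract_age_mentions(self.rec)
        self.snippet = Snippet("1", (0,), self.rec.abstract_text)
        self.hits = [ConceptHit("ONTOLOGY", "DOID:0201", None, "carcinoma", 40, 49)]

    def test_population_filter_undetermined(self):
        assert assemble_instance(self.rec, self.mention, "UNDETERMINED",
                                 self.snippet, self.hits) is None

    def test_population_filter_no_phenotype(self):
        assert assemble_instance(self.rec, self.mention, "AGE_OF_DIAGNOSIS",
                                 self.snippet, []) is None

    def test_valid_instance_age_class_consistent(self):
        inst = assemble_instance(self.rec, self.mention, "AGE_OF_DIAGNOSIS",
                                 self.snippet, self.hits, gender="MALE")
        assert inst is not None
        assert inst.instance_id == "1:0"
        assert inst.age_class == assign_age_class(inst.age_range).name
        assert inst.pub_year == 2005

    def test_constructor_rejects_bad_invariants(self):
        with pytest.raises(ValueError):
            make_instance(0, rel="UNDETERMINED")
        r = AgeRange(20, 20)
        with pytest.raises(ValueError, match="age_class"):
            EvidenceInstance(
                instance_id="x:0", pmid="x", age_range=r, age_class="AGED",
                relationship="AGE_OF_ONSET", snippet=Snippet("x", (0,), "t"),
                hits=(ConceptHit("ONTOLOGY", "D", None, "d", 0, 1),),
            )


class TestQuery:
    def test_wiki_preset_drops_two_types_and_inferred(self, ten_instance_store):
        res = query(ten_instance_store, QueryCriteria(
            mode="BY_AGE", age=AgeRange(0, 120), wiki_preset=True))
        assert len(flatten(res)) == 4  # 10 - 3 occurrence - 1 evaluation - 2 inferred
        kept = {i.relationship for i in flatten(res)}
        assert kept <= {"AGE_OF_ONSET", "AGE_OF_DIAGNOSIS", "AGE_OF_OBSERVATION"}
        assert not any(i.age_range.inferred for i in flatten(res))

    def test_by_age_interval_intersection_oracle(self, ten_instance_store):
        q = AgeRange(12, 18)
        res = flatten(query(ten_instance_store, QueryCriteria(mode="BY_AGE", age=q)))
        expected = [i for i in ten_instance_store if i.age_range.intersects(q)]
        assert {i.instance_id for i in res} == {i.instance_id for i in expected}
        assert len(res) == 1  # only the [0,30] inferred instance overlaps

    def test_contained_mode_stricter(self, ten_instance_store):
        q = AgeRange(0, 40)
        loose = flatten(query(ten_instance_store,
                              QueryCriteria(mode="BY_AGE", age=q)))
        strict = flatten(query(ten_instance_store,
                               QueryCriteria(mode="BY_AGE", age=q, contained=True)))
        assert {i.instance_id for i in strict} <= {i.instance_id for i in loose}
        assert all(q.contains(i.age_range) for i in strict)

    def test_phenotype_query_expands_descendants(self, ontology):
        store = EvidenceStore([
            make_instance(0, term="DOID:0202"),  # squamous cell carcinoma
            make_instance(1, term="DOID:0203"),  # leukemia
            make_instance(2, term="DOID:0100"),  # gonorrhea
        ])
        res = flatten(query(store, QueryCriteria(
            mode="BY_PHENOTYPE", phenotypes=("DOID:0200",)), ontology))  # cancer
        assert {i.pmid for i in res} == {"0", "1"}

    def test_root_query_superset_of_descendant_queries(self, ontology):
        store = EvidenceStore([
            make_instance(i, term=t) for i, t in enumerate(
                ["DOID:0202", "DOID:0203", "DOID:0204", "DOID:0100", "DOID:0301"])
        ])
        root = {i.instance_id for i in flatten(query(store, QueryCriteria(
            mode="BY_PHENOTYPE", phenotypes=("DOID:0001",)), ontology))}
        for term in ["DOID:0200", "DOID:0201", "DOID:0202", "DOID:0300"]:
            sub = {i.instance_id for i in flatten(query(store, QueryCriteria(
                mode="BY_PHENOTYPE", phenotypes=(term,)), ontology))}
            assert sub <= root

    def test_conjunctive_filter_bound(self, ten_instance_store):
        a = QueryCriteria(mode="BY_AGE", age=AgeRange(0, 120),
                          relationship="AGE_OF_DIAGNOSIS")
        b = QueryCriteria(mode="BY_AGE", age=AgeRange(0, 120), gender="NONE")
        ab = QueryCriteria(mode="BY_AGE", age=AgeRange(0, 120),
                           relationship="AGE_OF_DIAGNOSIS", gender="NONE")
        na = len(flatten(query(ten_instance_store, a)))
        nb = len(flatten(query(ten_instance_store, b)))
        nab = len(flatten(query(ten_instance_store, ab)))
        assert nab <= min(na, nb)

    def test_unknown_phenotype_errors_with_id(self, ten_instance_store, ontology):
        with pytest.raises(KeyError, match="DOID:9999"):
            query(ten_instance_store, QueryCriteria(
                mode="BY_PHENOTYPE", phenotypes=("DOID:9999",)), ontology)

    def test_mode_requires_fields(self):
        with pytest.raises(ValueError):
            QueryCriteria(mode="BY_AGE")
        with pytest.raises(ValueError):
            QueryCriteria(mode="BY_PHENOTYPE")
        with pytest.raises(ValueError):
            QueryCriteria(mode="SOMETHING")

    def test_results_invariant_to_store_order(self, ten_instance_store):
        insts = list(ten_instance_store)
        crit = QueryCriteria(mode="BY_AGE", age=AgeRange(0, 120), wiki_preset=True)
        baseline = [i.instance_id for i in flatten(query(ten_instance_store, crit))]
        for perm in itertools.islice(itertools.permutations(insts), 0, 30, 7):
            res = [i.instance_id for i in flatten(query(EvidenceStore(perm), crit))]
            assert res == baseline

    def test_year_and_pubtype_filters(self, ten_instance_store):
        res = flatten(query(ten_instance_store, QueryCriteria(
            mode="BY_AGE", age=AgeRange(0, 120),
            year_range=(2000, 2010), pub_type="Journal Article")))
        assert len(res) == 10
        res = flatten(query(ten_instance_store, QueryCriteria(
            mode="BY_AGE", age=AgeRange(0, 120), year_range=(2006, None))))
        assert res == []


class TestPersistence:
    def test_empty_store_round_trips(self, tmp_path):
        p = tmp_path / "s.jsonl"
        write_store(EvidenceStore(), p)
        assert len(read_store(p)) == 0

    def test_round_trip_byte_identical_on_rewrite(self, tmp_path, ten_instance_store):
        p1, p2 = tmp_path / "a.jsonl", tmp_path / "b.jsonl"
        write_store(ten_instance_store, p1)
        write_store(read_store(p1), p2)
        assert p1.read_bytes() == p2.read_bytes()
        assert [i.instance_id for i in read_store(p2)] == \
            sorted(i.instance_id for i in ten_instance_store)

    def test_truncated_file_rejected(self, tmp_path, ten_instance_store):
        p = tmp_path / "s.jsonl"
        write_store(ten_instance_store, p)
        lines = p.read_text().splitlines()
        p.write_text("\n".join(lines[:-2]) + "\n")
        with pytest.raises(StoreFormatError, match="truncated"):
            read_store(p)

    def test_version_mismatch_rejected(self, tmp_path):
        p = tmp_path / "s.jsonl"
        p.write_text('{"format": "apk-store", "version": 99, "count": 0}\n')
        with pytest.raises(StoreFormatError, match="version"):
            read_store(p)

    def test_population_filter_enforced_on_load(self, tmp_path, ten_instance_store):
        p = tmp_path / "s.jsonl"
        write_store(ten_instance_store, p)
        lines = p.read_text().splitlines()
        bad = lines[1].replace('"hits": [{', '"hits": [], "x": [{')
        p.write_text("\n".join([lines[0], bad] + lines[2:]) + "\n")
        with pytest.raises(StoreFormatError):
            read_store(p)
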