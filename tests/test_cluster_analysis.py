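"""Disease-age matrix, normalization, and hierarchical clustering."""

import math

import numpy as np
import pytest

from agemine.cluster_analysis import (
    build_matrix,
    cluster_age_profile,
    cluster_diseases,
    distance_matrix,
    normalize_matrix,
)
from agemine.evidence_store import EvidenceStore
from agemine.fixtures import (
    OLD_GROUP,
    YOUNG_GROUP,
    generate_two_group_fixture,
)
from test_evidence_store import make_instance


class TestMatrix:
    def test_single_point_instance_single_cell(self):
        store = EvidenceStore([make_instance(0, term="D", low=59, high=59)])
        m = build_matrix(store)
        assert m.counts.loc["D", 59] == 1
        assert m.counts.loc["D"].sum() == 1
        assert m.instance_totals["D"] == 1

    def test_range_instance_fills_every_covered_age(self):
        store = EvidenceStore([make_instance(0, term="D", low=12, high=18)])
        m = build_matrix(store)
        assert m.counts.loc["D"].sum() == 7
        assert all(m.counts.loc["D", a] == 1 for a in range(12, 19))
        assert m.instance_totals["D"] == 1

    def test_fractional_bounds_rounded_outward(self):
        store = EvidenceStore([make_instance(0, term="D", low=0.5, high=0.5)])
        m = build_matrix(store)
        assert m.counts.loc["D", 0] == 1 and m.counts.loc["D", 1] == 1

    def test_inferred_instances_excluded(self):
        store = EvidenceStore([
            make_instance(0, term="D", low=0, high=30, inferred=True),
            make_instance(1, term="D", low=20, high=20),
        ])
        m = build_matrix(store)
        assert m.instance_totals["D"] == 1
        assert m.counts.loc["D"].sum() == 1

    def test_only_inferred_instances_is_error(self):
        store = EvidenceStore(
            [make_instance(0, term="D", low=0, high=30, inferred=True)])
        with pytest.raises(ValueError):
            build_matrix(store)

    def test_redundant_hits_excluded_by_default(self):
        from agemine.lexicon_mapper import ConceptHit
        import dataclasses
        inst = make_instance(0, term="DOID:0202", low=60, high=60)
        redundant = ConceptHit("ONTOLOGY", "DOID:0201", None, "carcinoma",
                               0, 9, is_redundant=True)
        inst = dataclasses.replace(inst, hits=inst.hits + (redundant,))
        m = build_matrix(EvidenceStore([inst]))
        assert list(m.counts.index) == ["DOID:0202"]
        m2 = build_matrix(EvidenceStore([inst]), include_redundant=True)
        assert list(m2.counts.index) == ["DOID:0201", "DOID:0202"]


class TestNormalization:
    def test_point_instances_rows_sum_to_one(self):
        store = EvidenceStore([
            make_instance(i, term="D", low=20 + i, high=20 + i) for i in range(4)
        ])
        m = normalize_matrix(build_matrix(store))
        assert m.normalized.loc["D"].sum() == pytest.approx(1.0)

    def test_multi_age_instance_row_sums_exceed_one(self):
        store = EvidenceStore([make_instance(0, term="D", low=12, high=18)])
        m = normalize_matrix(build_matrix(store))
        assert m.normalized.loc["D"].sum() == pytest.approx(7.0)

    def test_duplicating_store_leaves_normalized_unchanged(self):
        insts = [make_instance(i, term="D", low=20 + i % 3, high=20 + i % 3)
                 for i in range(6)]
        doubled = insts + [
            make_instance(100 + i, term="D", low=20 + i % 3, high=20 + i % 3)
            for i in range(6)
        ]
        m1 = normalize_matrix(build_matrix(EvidenceStore(insts)))
        m2 = normalize_matrix(build_matrix(EvidenceStore(doubled)))
        np.testing.assert_allclose(m1.normalized.loc["D"], m2.normalized.loc["D"])

    def test_row_sum_mode(self):
        store = EvidenceStore([make_instance(0, term="D", low=12, high=18)])
        m = normalize_matrix(build_matrix(store), row_sum=True)
        assert m.normalized.loc["D"].sum() == pytest.approx(1.0)


def pearson(x, y):
    """Textbook Pearson correlation, independent of scipy."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    xc, yc = x - x.mean(), y - y.mean()
    return float((xc * yc).sum() / math.sqrt((xc ** 2).sum() * (yc ** 2).sum()))


class TestClustering:
    def test_identical_rows_merge_at_distance_zero(self):
        insts = []
        k = 0
        for term in ("A", "B"):
            for age in (20, 20, 25, 25, 30):
                insts.append(make_instance(k, term=term, low=age, high=age))
                k += 1
        m = normalize_matrix(build_matrix(EvidenceStore(insts)))
        res = cluster_diseases(m, min_instances=2)
        assert res.linkage[0, 2] == pytest.approx(0.0, abs=1e-12)

    def test_pairwise_distances_match_pearson_oracle(self):
        rng = np.random.default_rng(3)
        insts = []
        k = 0
        for t in range(6):
            for _ in range(10):
                age = int(rng.integers(5, 90))
                insts.append(make_instance(k, term=f"T{t}", low=age, high=age))
                k += 1
        m = normalize_matrix(build_matrix(EvidenceStore(insts)))
        res = cluster_diseases(m, min_instances=1)
        D = distance_matrix(res)
        X = m.normalized.loc[res.labels].to_numpy(float)
        for i in range(len(res.labels)):
            for j in range(len(res.labels)):
                expected = 0.0 if i == j else 1 - pearson(X[i], X[j])
                assert D[i, j] == pytest.approx(expected, abs=1e-9)
        assert np.allclose(D, D.T) and np.all(np.diag(D) == 0)
        assert D.min() >= 0 and D.max() <= 2

    def test_two_group_fixture_recovered(self):
        store, partition = generate_two_group_fixture(seed=5)
        m = normalize_matrix(build_matrix(store))
        res = cluster_diseases(m, min_instances=5)
        cut = res.cut(2)
        groups = {}
        for term, cl in cut.items():
            groups.setdefault(cl, set()).add(term)
        assert set(map(frozenset, groups.values())) == {
            frozenset(YOUNG_GROUP), frozenset(OLD_GROUP)}

    def test_permuting_disease_order_preserves_topology(self):
        store, _ = generate_two_group_fixture(seed=9)
        m1 = normalize_matrix(build_matrix(store))
        res1 = cluster_diseases(m1)
        # rebuild with instances in reversed order
        store2 = EvidenceStore(list(store)[::-1])
        res2 = cluster_diseases(normalize_matrix(build_matrix(store2)))
        np.testing.assert_allclose(
            sorted(res1.linkage[:, 2]), sorted(res2.linkage[:, 2]), atol=1e-12)
        cut1, cut2 = res1.cut(2), res2.cut(2)
        part1 = {frozenset(t for t, c in cut1.items() if c == k) for k in (1, 2)}
        part2 = {frozenset(t for t, c in cut2.items() if c == k) for k in (1, 2)}
        assert part1 == part2

    def test_too_few_rows_is_error(self):
        store = EvidenceStore([make_instance(i, term="D", low=20 + i, high=20 + i)
                               for i in range(6)])
        m = normalize_matrix(build_matrix(store))
        with pytest.raises(ValueError, match="at least 2"):
            cluster_diseases(m, min_instances=5)

    def test_zero_variance_rows_excluded(self):
        insts = [make_instance(i, term="FLAT", low=0, high=120) for i in range(5)]
        insts += [make_instance(10 + i, term=t, low=a, high=a)
                  for i, (t, a) in enumerate(
                      [("A", 20)] * 5 + [("B", 60)] * 5)]
        m = normalize_matrix(build_matrix(EvidenceStore(insts)))
        res = cluster_diseases(m, min_instances=5)
        assert "FLAT" not in res.labels and set(res.labels) == {"A", "B"}

    def test_newick_parses_with_branch_lengths(self):
        import dendropy
        store, _ = generate_two_group_fixture(seed=2)
        res = cluster_diseases(normalize_matrix(build_matrix(store)))
        tree = dendropy.Tree.get(data=res.to_newick(), schema="newick")
        leaves = sorted(l.taxon.label for l in tree.leaf_node_iter())
        assert leaves == sorted(res.labels)


class TestProfiles:
    def test_single_disease_profile_equals_count_row(self):
        store = EvidenceStore([make_instance(i, term="D", low=20, high=20)
                               for i in range(3)])
        m = build_matrix(store)
        profile, peak = cluster_age_profile({"D"}, m)
        np.testing.assert_array_equal(profile, m.counts.loc["D"].to_numpy(float))
        assert peak == 20

    def test_profile_is_arithmetic_mean(self):
        store = EvidenceStore(
            [make_instance(i, term="A", low=60, high=60) for i in range(2)]
            + [make_instance(10 + i, term="B", low=60, high=60) for i in range(4)]
        )
        profile, peak = cluster_age_profile({"A", "B"}, build_matrix(store))
        assert profile[60] == pytest.approx(3.0)
        assert peak == 60

    def test_planted_peaks_recovered(self):
        store, _ = generate_two_group_fixture(seed=13)
        m = build_matrix(store)
        _, peak_young = cluster_age_profile(set(YOUNG_GROUP), m)
        _, peak_old = cluster_age_profile(set(OLD_GROUP), m)
        assert 18 <= peak_young <= 24
        assert 55 <= peak_old <= 66

    def test_empty_cluster_rejected(self):
        store = EvidenceStore([make_instance(0, term="D", low=20, high=20)])
        with pytest.raises(ValueError):
            cluster_age_profile(set(), build_matrix(store))
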