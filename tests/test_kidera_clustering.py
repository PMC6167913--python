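import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from promab import cdr_annotation as ca
from promab import kidera_clustering as kc
from promab import synthetic_data as sd
from promab.cdr_annotation import AntibodyRecord
from promab.errors import InputError


def _vec(ab_id, arr20):
    arr20 = np.asarray(arr20, dtype=float)
    return kc.KideraFeatureVector(ab_id, arr20[:10], arr20[10:])


class TestKideraTable:
    def test_standardization_property(self):
        mat = np.array(list(kc.KIDERA_TABLE.values()))
        assert mat.shape == (20, 10)
        assert np.all(np.abs(mat.mean(axis=0)) < 0.1)
        assert np.all(np.abs(mat.var(axis=0) - 1.0) < 0.15)

    def test_single_residue_loop_equals_table_row(self):
        v = kc.kidera_encode("a", "V", "W")
        assert np.allclose(v.h3_part, kc.KIDERA_TABLE["V"])
        assert np.allclose(v.l3_part, kc.KIDERA_TABLE["W"])

    def test_mean_invariant_under_repetition(self):
        assert np.allclose(kc.encode_loop("AA"), kc.encode_loop("A"))

    def test_vim_loop_is_componentwise_mean(self):
        # expected value computed directly from the three table tuples
        expected = [(kc.KIDERA_TABLE["V"][k] + kc.KIDERA_TABLE["I"][k]
                     + kc.KIDERA_TABLE["M"][k]) / 3.0 for k in range(10)]
        assert np.allclose(kc.encode_loop("VIM"), expected)

    def test_sum_aggregation(self):
        assert np.allclose(kc.encode_loop("VIM", agg="sum"),
                           3.0 * np.asarray(kc.encode_loop("VIM")))

    def test_unknown_residue_raises(self):
        with pytest.raises(InputError):
            kc.encode_loop("VB")


class TestMinkowskiMetric:
    def test_identity_is_zero(self):
        a = np.arange(20.0)
        assert kc.minkowski_distance(a, a) == 0.0

    def test_unit_pair_closed_form(self):
        a = np.zeros(20)
        b = np.zeros(20)
        b[:2] = 1.0
        assert kc.minkowski_distance(a, b, p=4) == pytest.approx(2 ** 0.25)

    def test_p2_reduces_to_euclidean(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            a, b = rng.normal(size=(2, 20))
            # independent closed form: sqrt of summed squares
            expected = float(np.sqrt(((a - b) ** 2).sum()))
            assert kc.minkowski_distance(a, b, p=2) == pytest.approx(expected)

    def test_dimension_mismatch(self):
        with pytest.raises(InputError):
            kc.minkowski_distance(np.zeros(3), np.zeros(4))

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(st.lists(st.floats(-50, 50), min_size=5, max_size=5),
           st.lists(st.floats(-50, 50), min_size=5, max_size=5),
           st.lists(st.floats(-50, 50), min_size=5, max_size=5))
    def test_metric_axioms(self, a, b, c):
        a, b, c = map(np.asarray, (a, b, c))
        dab = kc.minkowski_distance(a, b, p=4)
        assert dab >= 0
        assert dab == pytest.approx(kc.minkowski_distance(b, a, p=4))
        assert dab <= (kc.minkowski_distance(a, c, p=4)
                       + kc.minkowski_distance(c, b, p=4) + 1e-9)


def _bruteforce_complete_linkage(X, p, k):
    """Exhaustive agglomeration by pair scanning (complete linkage)."""
    clusters = [frozenset([i]) for i in range(len(X))]

    def dist(c1, c2):
        return max(kc.minkowski_distance(X[i], X[j], p)
                   for i in c1 for j in c2)

    while len(clusters) > k:
        best = None
        for i, j in itertools.combinations(range(len(clusters)), 2):
            d = dist(clusters[i], clusters[j])
            if best is None or d < best[0]:
                best = (d, i, j)
        _, i, j = best
        merged = clusters[i] | clusters[j]
        clusters = [c for t, c in enumerate(clusters) if t not in (i, j)]
        clusters.append(merged)
    return {frozenset(c) for c in clusters}


class TestHierarchicalClustering:
    def test_two_tight_pairs_recovered(self):
        X = np.zeros((4, 20))
        X[0, 0], X[1, 0] = 0.0, 0.1
        X[2, 0], X[3, 0] = 10.0, 10.1
        vecs = [_vec(f"v{i}", X[i]) for i in range(4)]
        res = kc.hierarchical_cluster(vecs)
        lab = res.assignments_at_k(2)
        assert lab["v0"] == lab["v1"] != lab["v2"] == lab["v3"]

    def test_merge_heights_nondecreasing(self, panel):
        vecs = [kc.kidera_encode(r.id, ca.extract_cdr3(r, "H"),
                                 ca.extract_cdr3(r, "L")) for r in panel]
        res = kc.hierarchical_cluster(vecs)
        assert np.all(np.diff(res.merge_heights) >= -1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_bruteforce_agglomeration(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(7, 20))
        vecs = [_vec(f"v{i}", X[i]) for i in range(7)]
        res = kc.hierarchical_cluster(vecs, p=4.0)
        lab = res.assignments_at_k(3)
        mine = {frozenset(i for i, v in enumerate(vecs)
                          if lab[v.antibody_id] == c)
                for c in set(lab.values())}
        assert mine == _bruteforce_complete_linkage(X, 4.0, 3)

    def test_permutation_invariance(self, panel):
        vecs = [kc.kidera_encode(r.id, ca.extract_cdr3(r, "H"),
                                 ca.extract_cdr3(r, "L")) for r in panel]
        base = kc.hierarchical_cluster(vecs).assignments_at_k(3)
        rng = np.random.default_rng(0)
        for _ in range(3):
            order = rng.permutation(len(vecs))
            lab = kc.hierarchical_cluster(
                [vecs[i] for i in order]).assignments_at_k(3)
            # same partition up to label renaming
            part = lambda d: {frozenset(i for i in d if d[i] == c)
                              for c in set(d.values())}
            assert part(lab) == part(base)

    def test_duplicate_ids_rejected(self):
        vecs = [_vec("a", np.zeros(20)), _vec("a", np.ones(20))]
        with pytest.raises(InputError):
            kc.hierarchical_cluster(vecs)

    def test_newick_is_parseable_with_all_leaves(self, panel):
        from io import StringIO
        from Bio import Phylo
        vecs = [kc.kidera_encode(r.id, ca.extract_cdr3(r, "H"),
                                 ca.extract_cdr3(r, "L")) for r in panel]
        nwk = kc.hierarchical_cluster(vecs).to_newick()
        tree = Phylo.read(StringIO(nwk), "newick")
        assert {t.name for t in tree.get_terminals()} == \
            {r.id for r in panel}


class TestEnrichment:
    def _forced(self, labels, phenotypes):
        ids = list(labels)
        vecs = []
        rng = np.random.default_rng(0)
        # well-separated synthetic coordinates realizing the partition
        for i, ab in enumerate(ids):
            base = np.zeros(20)
            base[0] = labels[ab] * 100.0
            vecs.append(_vec(ab, base + rng.normal(0, .01, 20)))
        res = kc.hierarchical_cluster(vecs)
        records = [AntibodyRecord(id=ab, heavy_seq="A", light_seq="A",
                                  phenotype=phenotypes[ab]) for ab in ids]
        return kc.enrichment(res, records, k=len(set(labels.values())))

    def test_perfect_split_rows(self):
        labels = {f"p{i}": 1 for i in range(4)} | \
                 {f"n{i}": 2 for i in range(6)}
        phen = {k: ("promiscuous" if k[0] == "p" else "non_promiscuous")
                for k in labels}
        rep = self._forced(labels, phen)
        col = rep.pct_of_phenotype["promiscuous"]
        assert sorted(col.round(1)) == [0.0, 100.0]

    def test_four_of_six_nonpromiscuous_is_66_7(self):
        # a cluster holding 4 of the 6 non-promiscuous antibodies
        labels = {"n1": 1, "n2": 1, "n3": 1, "n4": 1, "n5": 2, "n6": 2,
                  "p1": 2, "p2": 3, "p3": 3, "p4": 3}
        phen = {k: ("promiscuous" if k[0] == "p" else "non_promiscuous")
                for k in labels}
        rep = self._forced(labels, phen)
        assert rep.pct_of_phenotype.loc[1, "non_promiscuous"] == \
            pytest.approx(66.7, abs=0.05)

    def test_three_of_four_promiscuous_is_75(self):
        labels = {"n1": 1, "n2": 1, "n3": 1, "n4": 1, "n5": 2, "n6": 2,
                  "p1": 2, "p2": 3, "p3": 3, "p4": 3}
        phen = {k: ("promiscuous" if k[0] == "p" else "non_promiscuous")
                for k in labels}
        rep = self._forced(labels, phen)
        assert rep.pct_of_phenotype.loc[3, "promiscuous"] == \
            pytest.approx(75.0, abs=0.05)

    def test_phenotype_percentages_sum_to_100(self, panel):
        vecs = [kc.kidera_encode(r.id, ca.extract_cdr3(r, "H"),
                                 ca.extract_cdr3(r, "L")) for r in panel]
        rep = kc.enrichment(kc.hierarchical_cluster(vecs), panel, 3)
        sums = rep.pct_of_phenotype.sum(axis=0)
        assert np.allclose(sums, 100.0)


def _purity(labels, phen):
    total = 0
    for c in set(labels.values()):
        members = [phen[i] for i in labels if labels[i] == c]
        total += max(members.count("promiscuous"),
                     members.count("non_promiscuous"))
    return total / len(labels)


def test_synthetic_panels_separate_phenotypes():
    """Panels with the strong stem/apex composition contrast cluster by
    phenotype: purity >= 0.8 in every one of 20 seeded replicates."""
    for seed in range(20):
        recs = sd.generate_antibody_set(sd.SequenceGenConfig(seed=seed))
        vecs = [kc.kidera_encode(r.id, ca.extract_cdr3(r, "H"),
                                 ca.extract_cdr3(r, "L")) for r in recs]
        labels = kc.hierarchical_cluster(vecs).assignments_at_k(3)
        phen = {r.id: r.phenotype for r in recs}
        assert _purity(labels, phen) >= 0.8, f"seed {seed}"
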