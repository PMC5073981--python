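"""AUC, cohesion, co-occurrence baseline, rank-sum comparison, gains."""

import itertools

import numpy as np
import pytest
from sklearn.metrics import roc_auc_score

from mirlsi.corpus import EntityCitationMap
from mirlsi.evaluation import (cohesion, cohesion_from_similarity,
                               compare_cohesions, cooccurrence_cohesion,
                               cooccurrence_similarity, information_gain,
                               read_gold_standard_tsv, recall_against_curated,
                               roc_auc)
from mirlsi.query import RankedList


def brute_force_auc(ids, scores, positives):
    """Fraction of (positive, negative) pairs ordered correctly; ties half."""
    pos = [s for i, s in zip(ids, scores) if i in positives]
    neg = [s for i, s in zip(ids, scores) if i not in positives]
    total = 0.0
    for p, n in itertools.product(pos, neg):
        total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestRocAuc:
    def test_all_positives_first_is_one(self):
        assert roc_auc(["p1", "p2", "n1", "n2"], {"p1", "p2"}) == 1.0

    def test_all_positives_last_is_zero(self):
        assert roc_auc(["n1", "n2", "p1", "p2"], {"p1", "p2"}) == 0.0

    def test_interleaved_example(self):
        # positives at ranks 1 and 3 of 4: 3 of 4 pairs correct
        assert roc_auc(["p1", "n1", "p2", "n2"], {"p1", "p2"}) == 0.75

    def test_matches_brute_force_pair_counting(self, rng):
        for _ in range(10):
            n = int(rng.integers(5, 50))
            ids = [f"e{i}" for i in range(n)]
            scores = rng.choice(np.linspace(0, 1, 11), size=n)  # ties likely
            positives = set(rng.choice(ids, size=int(rng.integers(1, n - 1)), replace=False))
            ranked = RankedList(ids, scores)
            assert roc_auc(ranked, positives) == pytest.approx(
                brute_force_auc(ids, scores, positives), abs=1e-12)

    def test_agrees_with_sklearn_on_tied_scores(self, rng):
        n = 40
        ids = [f"e{i}" for i in range(n)]
        scores = rng.choice([0.1, 0.3, 0.3, 0.8], size=n)
        positives = set(rng.choice(ids, size=12, replace=False))
        y = [1 if i in positives else 0 for i in ids]
        assert roc_auc(RankedList(ids, scores), positives) == pytest.approx(
            roc_auc_score(y, scores), abs=1e-12)

    def test_reversal_complements_auc(self, rng):
        ids = [f"e{i}" for i in range(30)]
        order = list(rng.permutation(ids))
        positives = set(order[3:9])
        assert roc_auc(order, positives) == pytest.approx(
            1.0 - roc_auc(order[::-1], positives))

    def test_degenerate_universes_rejected(self):
        with pytest.raises(ValueError):
            roc_auc(["a", "b"], set())
        with pytest.raises(ValueError):
            roc_auc(["a", "b"], {"a", "b"})


class TestCohesion:
    def test_identical_vectors_give_perfect_cohesion(self):
        ids = ["a", "b", "c", "d", "e"]
        sim = np.eye(5)
        sim[0, 1] = sim[1, 0] = 0.99  # a and b near-identical, rest unrelated
        res = cohesion_from_similarity({"a", "b"}, sim, ids)
        assert res.cohesion == 1.0

    def test_cohesion_is_median_of_member_aucs(self, planted_model):
        model, _, labels = planted_model
        members = {e for e, t in labels.items() if t == 2}
        res = cohesion(members, model)
        assert res.cohesion == pytest.approx(float(np.median(res.aucs)))
        assert len(res.aucs) == len(members)
        assert 0.0 <= res.cohesion <= 1.0

    def test_invariant_to_entity_relabeling(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(8, 3))
        sim = X @ X.T
        ids = [f"e{i}" for i in range(8)]
        res1 = cohesion_from_similarity({"e0", "e1", "e2"}, sim, ids)
        perm = rng.permutation(8)
        ids2 = [f"x{i}" for i in range(8)]
        sim2 = sim[np.ix_(perm, perm)]
        members2 = {ids2[int(np.where(perm == k)[0][0])] for k in (0, 1, 2)}
        res2 = cohesion_from_similarity(members2, sim2, ids2)
        assert res1.cohesion == pytest.approx(res2.cohesion)

    def test_singleton_set_rejected(self, planted_model):
        model, _, _ = planted_model
        with pytest.raises(ValueError):
            cohesion({model.entity_ids[0]}, model)


class TestCooccurrence:
    def _map(self, assignments):
        cmap = EntityCitationMap()
        for e, cids in assignments.items():
            for c in cids:
                cmap.add(e, c, "retrieved")
        return cmap

    def test_disjoint_and_identical_sets(self):
        cmap = self._map({"a": {"c1", "c2", "c3", "c4", "c5"},
                          "b": {"c1", "c2", "c3", "c4", "c5"},
                          "c": {"x1"}})
        sim, ids = cooccurrence_similarity(cmap)
        i = {e: k for k, e in enumerate(ids)}
        assert sim[i["a"], i["b"]] == 5
        assert sim[i["a"], i["c"]] == 0
        assert sim[i["a"], i["a"]] == 5  # diagonal = citation count

    def test_matches_brute_force_set_intersections(self, rng):
        entities = [f"e{i}" for i in range(12)]
        pool = [f"c{i}" for i in range(30)]
        assignments = {
            e: set(rng.choice(pool, size=int(rng.integers(1, 10)), replace=False))
            for e in entities
        }
        sim, ids = cooccurrence_similarity(self._map(assignments))
        for i, a in enumerate(ids):
            for j, b in enumerate(ids):
                assert sim[i, j] == len(assignments[a] & assignments[b])

    def test_baseline_cohesion_on_shared_literature(self):
        # a group that shares citations is cohesive under co-occurrence
        cmap = self._map({
            "a": {"c1", "c2"}, "b": {"c1", "c2"}, "c": {"c2", "c3"},
            "d": {"x1"}, "e": {"x2"}, "f": {"x3"},
        })
        res = cooccurrence_cohesion({"a", "b", "c"}, cmap)
        assert res.cohesion == 1.0


class TestCompareCohesions:
    def test_identical_lists_no_difference(self):
        p, direction = compare_cohesions([0.5, 0.6, 0.7], [0.7, 0.5, 0.6])
        assert p == 1.0 and direction == "none"

    def test_uniform_shift_detected(self):
        low = [0.40, 0.42, 0.44, 0.46, 0.48, 0.50, 0.52, 0.54]
        high = [v + 0.3 for v in low]
        p, direction = compare_cohesions(high, low)
        assert p < 0.05 and direction == "lsi"

    def test_p_values_in_unit_interval(self, rng):
        for _ in range(5):
            a = rng.uniform(0, 1, size=6)
            b = rng.uniform(0, 1, size=6)
            p, _ = compare_cohesions(a, b)
            assert 0.0 < p <= 1.0


class TestGains:
    @pytest.mark.parametrize("retrieved,curated,expected",
                             [(20, 10, 1.0), (5, 10, -0.5), (10, 10, 0.0)])
    def test_information_gain(self, retrieved, curated, expected):
        assert information_gain(retrieved, curated) == pytest.approx(expected)

    def test_information_gain_undefined_without_curated(self):
        with pytest.raises(ValueError):
            information_gain(5, 0)

    def test_recall(self):
        assert recall_against_curated({"a", "b", "x"}, {"a", "b", "c", "d"}) == 0.5
        assert recall_against_curated({"a"}, {"a"}) == 1.0
        assert recall_against_curated({"x"}, {"a"}) == 0.0
        with pytest.raises(ValueError):
            recall_against_curated({"a"}, set())


def test_gold_standard_tsv(tmp_path):
    path = tmp_path / "gold.tsv"
    path.write_text("category\tentity_id\nglioma\tmir-1\nglioma\tmir-2\nasthma\tmir-3\n")
    gold = read_gold_standard_tsv(path)
    assert gold.categories == {"glioma": {"mir-1", "mir-2"}, "asthma": {"mir-3"}}
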