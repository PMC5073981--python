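"""Similarity graph construction, components, clustering, annotation."""

import networkx as nx
import numpy as np
import pytest

from mirlsi.network import (ClusterSet, annotate_clusters, build_graph,
                            cluster_component, cluster_connectivity,
                            largest_connected_component, percentile_threshold)
from mirlsi.query import make_entity_query, pairwise_cosines, rank_terms


def bfs_components(nodes, edges):
    """Exhaustive reachability oracle: BFS from every node."""
    adj = {n: set() for n in nodes}
    for a, b in edges:
        adj[a].add(b)
        adj[b].add(a)
    comps = []
    for start in nodes:
        seen = {start}
        frontier = [start]
        while frontier:
            nxt = []
            for u in frontier:
                for v in adj[u] - seen:
                    seen.add(v)
                    nxt.append(v)
            frontier = nxt
        if seen not in comps:
            comps.append(seen)
    return comps


class TestPercentileThreshold:
    def test_degenerate_equal_cosines(self):
        M = np.full((4, 4), 0.3)
        np.fill_diagonal(M, 1.0)
        assert percentile_threshold(M, 99) == pytest.approx(0.3)

    def test_matches_independent_quantile(self):
        # 100 evenly spaced off-diagonal values placed in a symmetric matrix
        vals = np.round(np.linspace(0.0, 0.99, 100), 2)
        n = 15  # 105 upper-triangle slots; use first 100, pad with repeats
        pool = np.concatenate([vals, vals[:5]])
        M = np.eye(n)
        iu = np.triu_indices(n, 1)
        M[iu] = pool
        M[(iu[1], iu[0])] = pool
        expected = np.percentile(pool, 99)  # independent linear quantile
        assert percentile_threshold(M, 99) == pytest.approx(expected)

    def test_threshold_within_input_range(self, planted_model):
        model, _, _ = planted_model
        M = pairwise_cosines(model)
        iu = np.triu_indices(len(model.entity_ids), 1)
        thr = percentile_threshold(M, 99)
        assert M[iu].min() <= thr <= M[iu].max()

    def test_needs_two_entities(self):
        with pytest.raises(ValueError):
            percentile_threshold(np.ones((1, 1)), 99)


class TestBuildGraph:
    def test_orthogonal_entities_no_edges(self):
        g = build_graph(np.eye(3), ["a", "b", "c"], threshold=0.5)
        assert g.number_of_edges() == 0
        assert g.number_of_nodes() == 3  # isolated nodes retained

    def test_identical_entities_one_edge(self):
        M = np.array([[1.0, 1.0], [1.0, 1.0]])
        g = build_graph(M, ["a", "b"], threshold=0.9)
        assert list(g.edges()) == [("a", "b")]

    def test_strict_inequality_at_threshold(self):
        M = np.array([[1.0, 0.5], [0.5, 1.0]])
        assert build_graph(M, ["a", "b"], 0.5).number_of_edges() == 0

    def test_edge_count_matches_brute_force(self, planted_model, rng):
        model, _, _ = planted_model
        M = pairwise_cosines(model)
        thr = float(rng.uniform(0.0, 0.5))
        g = build_graph(M, model.entity_ids, thr)
        n = len(model.entity_ids)
        expected = sum(
            1 for i in range(n) for j in range(i + 1, n) if M[i, j] > thr
        )
        assert g.number_of_edges() == expected

    def test_raising_percentile_never_adds_edges(self, planted_model):
        model, _, _ = planted_model
        M = pairwise_cosines(model)
        g_low = build_graph(M, model.entity_ids, percentile_threshold(M, 90))
        g_high = build_graph(M, model.entity_ids, percentile_threshold(M, 99))
        assert g_high.number_of_edges() <= g_low.number_of_edges()
        assert all(g_low.has_edge(*e) for e in g_high.edges())


class TestLargestComponent:
    def test_path_graph_is_one_component(self):
        g = nx.path_graph(["a", "b", "c", "d"])
        assert largest_connected_component(g) == {"a", "b", "c", "d"}

    def test_larger_component_wins(self):
        g = nx.Graph()
        g.add_edges_from([("a", "b"), ("b", "c"), ("c", "d"), ("d", "e")])
        g.add_edges_from([("x", "y"), ("y", "z")])
        assert largest_connected_component(g) == {"a", "b", "c", "d", "e"}

    def test_tie_broken_by_smallest_lexicographic_member(self):
        g = nx.Graph()
        g.add_edge("m", "n")
        g.add_edge("a", "b")
        assert largest_connected_component(g) == {"a", "b"}

    def test_matches_bfs_oracle(self, planted_model):
        model, _, _ = planted_model
        M = pairwise_cosines(model)
        thr = percentile_threshold(M, 95)
        g = build_graph(M, model.entity_ids, thr)
        comps = bfs_components(list(g.nodes()), list(g.edges()))
        expected = sorted(comps, key=lambda c: (-len(c), min(c)))[0]
        assert largest_connected_component(g) == expected

    def test_empty_graph_rejected(self):
        with pytest.raises(ValueError):
            largest_connected_component(nx.Graph())


class TestClustering:
    def test_partition_covers_component(self, planted_model):
        model, _, _ = planted_model
        nodes = set(model.entity_ids)
        clusters = cluster_component(nodes, model, 5, seed=0)
        assert sum(len(m) for m in clusters.clusters.values()) == len(nodes)
        assert clusters.n_clusters == 5

    def test_same_seed_same_partition(self, planted_model):
        model, _, _ = planted_model
        nodes = set(model.entity_ids)
        a = cluster_component(nodes, model, 5, seed=3)
        b = cluster_component(nodes, model, 5, seed=3)
        assert a.labels() == b.labels()

    def test_k_equals_size_gives_singletons(self, planted_model):
        model, _, _ = planted_model
        nodes = set(model.entity_ids[:6])
        clusters = cluster_component(nodes, model, 6, seed=0)
        assert all(len(m) == 1 for m in clusters.clusters.values())

    def test_k_above_size_rejected(self, planted_model):
        model, _, _ = planted_model
        with pytest.raises(ValueError):
            cluster_component({model.entity_ids[0]}, model, 2)

    def test_within_cluster_cosine_exceeds_between(self, planted_model):
        model, _, labels = planted_model
        M = pairwise_cosines(model)
        clusters = cluster_component(set(model.entity_ids), model,
                                     len(set(labels.values())), seed=0)
        lab = clusters.labels()
        idx = {e: i for i, e in enumerate(model.entity_ids)}
        within, between = [], []
        ents = model.entity_ids
        for i in range(len(ents)):
            for j in range(i + 1, len(ents)):
                (within if lab[ents[i]] == lab[ents[j]] else between).append(
                    M[idx[ents[i]], idx[ents[j]]])
        assert np.mean(within) > np.mean(between)

    def test_overlapping_clusters_rejected(self):
        with pytest.raises(ValueError):
            ClusterSet({0: ["a", "b"], 1: ["b"]})
        with pytest.raises(ValueError):
            ClusterSet({0: []})


class TestAnnotation:
    def test_planted_cluster_annotated_with_topic_vocabulary(self, planted_model):
        model, _, labels = planted_model
        topic0 = {e for e, t in labels.items() if t == 0}
        clusters = ClusterSet({0: sorted(topic0)})
        (ann,) = annotate_clusters(clusters, model, top_n=300).values()
        top20 = ann.ids[:20]
        frac = sum(1 for t in top20 if t.startswith("topic00")) / 20
        assert frac >= 0.8

    def test_list_lengths_capped(self, planted_model):
        model, _, _ = planted_model
        clusters = ClusterSet({0: sorted(model.entity_ids[:4])})
        anns = annotate_clusters(clusters, model, top_n=17)
        assert all(len(a) <= 17 for a in anns.values())

    def test_singleton_annotation_equals_direct_term_ranking(self, planted_model):
        model, _, _ = planted_model
        entity = model.entity_ids[0]
        clusters = ClusterSet({0: [entity]})
        (ann,) = annotate_clusters(clusters, model, top_n=50).values()
        direct = rank_terms(make_entity_query([entity], model), model, top_n=50)
        assert ann.ids == direct.ids

    def test_connectivity_report(self):
        g = nx.Graph()
        g.add_edges_from([("a", "b"), ("c", "d")])
        clusters = ClusterSet({0: ["a", "b"], 1: ["b1"]})
        g.add_node("b1")
        conn = cluster_connectivity(clusters, g)
        assert conn[0] is True and conn[1] is True
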