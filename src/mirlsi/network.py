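"""Entity similarity graph: thresholding, components, clustering, annotation.

Pairwise entity cosines are thresholded at a high percentile (default the
99th) of all off-diagonal values to form a sparse undirected graph; the
largest connected component is clustered with k-means on the unit-normalized
scaled LSI vectors, and each cluster is annotated with the top-ranked terms
retrieved by querying the model with all of the cluster's entities.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .lsi import LsiModel, normalize_rows, scaled_entity_vectors
from .query import RankedList, make_entity_query, rank_terms

logger = logging.getLogger(__name__)

__all__ = [
    "ClusterSet",
    "percentile_threshold",
    "build_graph",
    "largest_connected_component",
    "cluster_component",
    "annotate_clusters",
    "cluster_connectivity",
    "write_edge_list",
    "write_clusters",
    "write_annotations",
]

DEFAULT_PERCENTILE = 99.0
DEFAULT_K_CLUSTERS = 25


@dataclass
class ClusterSet:
    """Partition of a node set: cluster ID -> sorted member list."""

    clusters: dict[int, list[str]]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for cid, members in self.clusters.items():
            if not members:
                raise ValueError(f"cluster {cid} is empty")
            dup = seen & set(members)
            if dup:
                raise ValueError(f"entities in multiple clusters: {sorted(dup)}")
            seen |= set(members)

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    def labels(self) -> dict[str, int]:
        return {e: cid for cid, members in self.clusters.items() for e in members}


def percentile_threshold(cosines: np.ndarray, pct: float = DEFAULT_PERCENTILE) -> float:
    """pct-th percentile (linear interpolation) of the off-diagonal pairwise
    cosines, each unordered pair counted once."""
    if cosines.shape[0] < 2:
        raise ValueError("need at least two entities")
    if not 0 < pct < 100:
        raise ValueError("percentile must lie strictly between 0 and 100")
    iu = np.triu_indices(cosines.shape[0], k=1)
    return float(np.percentile(cosines[iu], pct))


def build_graph(cosines: np.ndarray, ids: Sequence[str], threshold: float) -> nx.Graph:
    """Undirected graph with an edge where cosine is strictly above the
    threshold; isolated nodes are retained; no self-loops."""
    g = nx.Graph(threshold=float(threshold))
    g.add_nodes_from(ids)
    n = len(ids)
    iu, ju = np.triu_indices(n, k=1)
    above = cosines[iu, ju] > threshold
    for i, j in zip(iu[above], ju[above]):
        g.add_edge(ids[int(i)], ids[int(j)], cosine=float(cosines[i, j]))
    return g


def largest_connected_component(graph: nx.Graph) -> set[str]:
    """Largest mutually reachable node set; size ties broken in favour of
    the component containing the lexicographically smallest node."""
    if graph.number_of_nodes() == 0:
        raise ValueError("empty graph")
    comps = sorted(nx.connected_components(graph), key=lambda c: (-len(c), min(c)))
    return set(comps[0])


def cluster_component(
    nodes: set[str],
    model: LsiModel,
    k_clusters: int,
    seed: int = 0,
    n_init: int = 10,
) -> ClusterSet:
    """k-means partition of the component's entities.

    Entities are embedded as unit-normalized scaled LSI vectors; the seed
    and restart count make the partition reproducible.
    """
    ordered = sorted(nodes)
    if k_clusters > len(ordered):
        raise ValueError(f"k_clusters={k_clusters} exceeds component size {len(ordered)}")
    if k_clusters < 1:
        raise ValueError("k_clusters must be >= 1")
    unit, _ = normalize_rows(scaled_entity_vectors(model))
    idx = [model.entity_index(e) for e in ordered]
    X = unit[idx]
    km = KMeans(n_clusters=k_clusters, n_init=n_init, random_state=seed)
    labels = km.fit_predict(X)
    clusters: dict[int, list[str]] = {}
    for e, lab in zip(ordered, labels):
        clusters.setdefault(int(lab), []).append(e)
    return ClusterSet({cid: sorted(m) for cid, m in sorted(clusters.items())})


def annotate_clusters(
    clusters: ClusterSet, model: LsiModel, top_n: int = 300
) -> dict[int, RankedList]:
    """Top-ranked terms per cluster, from an all-members entity query."""
    out: dict[int, RankedList] = {}
    for cid, members in clusters.clusters.items():
        q = make_entity_query(members, model)
        out[cid] = rank_terms(q, model, top_n=top_n)
    return out


def cluster_connectivity(clusters: ClusterSet, graph: nx.Graph) -> dict[int, bool]:
    """Whether each cluster's induced subgraph is connected (reported, not
    enforced)."""
    return {
        cid: nx.is_connected(graph.subgraph(members))
        for cid, members in clusters.clusters.items()
    }


# --------------------------------------------------------------------------
# Exports
# --------------------------------------------------------------------------

def write_edge_list(graph: nx.Graph, path: str | Path) -> None:
    rows = [(a, b, d["cosine"]) for a, b, d in sorted(graph.edges(data=True))]
    pd.DataFrame(rows, columns=["id1", "id2", "cosine"]).to_csv(path, sep="\t", index=False)


def write_clusters(clusters: ClusterSet, path: str | Path) -> None:
    rows = [(e, cid) for cid, members in clusters.clusters.items() for e in members]
    pd.DataFrame(rows, columns=["entity_id", "cluster"]).to_csv(path, sep="\t", index=False)


def write_annotations(annotations: dict[int, RankedList], path: str | Path) -> None:
    rows = []
    for cid in sorted(annotations):
        for rank, term, score in annotations[cid].to_rows():
            rows.append((cid, rank, term, score))
    pd.DataFrame(rows, columns=["cluster", "rank", "term", "cosine"]).to_csv(
        path, sep="\t", index=False
    )
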