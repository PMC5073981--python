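"""Evaluation statistics for literature-based prioritization.

* ROC AUC of a ranked list against a gold-standard positive set, via the
  Mann-Whitney rank-sum identity (ties contribute half a pair).
* Cohesion of an entity set: each member in turn is used as a query, the
  rest are the positives, and the median of the leave-one-out AUCs is the
  cohesion.  A co-occurrence baseline (shared-citation counts as the
  similarity) gives the reference the LSI cosines are compared against with
  a rank-sum test.
* Information gain of automated retrieval over a curated citation set, and
  recall of curated citations among retrieved ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats

from .corpus import EntityCitationMap
from .lsi import LsiModel, normalize_rows, scaled_entity_vectors
from .query import RankedList

__all__ = [
    "GoldStandard",
    "CohesionResult",
    "roc_auc",
    "cohesion",
    "cohesion_from_similarity",
    "cooccurrence_similarity",
    "cooccurrence_cohesion",
    "compare_cohesions",
    "information_gain",
    "recall_against_curated",
    "read_gold_standard_tsv",
]


@dataclass
class GoldStandard:
    """Named categories mapping to positive entity (or term) sets."""

    categories: dict[str, set[str]]
    universe: set[str] | None = None

    def __post_init__(self) -> None:
        for name, members in self.categories.items():
            if not members:
                raise ValueError(f"gold-standard category {name!r} is empty")
            if self.universe is not None and not members <= self.universe:
                raise ValueError(f"category {name!r} has members outside the universe")


@dataclass
class CohesionResult:
    """Leave-one-out AUCs of a category and their median (the cohesion)."""

    category: str
    aucs: list[float]
    cohesion: float
    baseline_aucs: list[float] | None = None
    baseline_cohesion: float | None = None
    p_value: float | None = None
    direction: str | None = None


def roc_auc(ranking: RankedList | Sequence[str], positives: set[str]) -> float:
    """AUC of a ranking: the fraction of (positive, negative) pairs ordered
    correctly, with tied scores contributing half a pair.

    ``ranking`` covers the evaluation universe: either a RankedList (scores
    used, ties allowed) or a best-first sequence of IDs (no ties).
    """
    if isinstance(ranking, RankedList):
        ids = ranking.ids
        scores = np.asarray(ranking.scores, dtype=float)
    else:
        ids = list(ranking)
        scores = -np.arange(len(ids), dtype=float)  # best first
    pos_mask = np.array([i in positives for i in ids])
    n_pos = int(pos_mask.sum())
    n_neg = len(ids) - n_pos
    if n_pos == 0:
        raise ValueError("no positives in the ranked universe")
    if n_neg == 0:
        raise ValueError("no negatives in the ranked universe")
    ranks = scipy.stats.rankdata(scores)  # ascending, average ties
    auc = (ranks[pos_mask].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    return float(auc)


def cohesion_from_similarity(
    members: set[str],
    similarity: np.ndarray,
    ids: Sequence[str],
    universe: set[str] | None = None,
) -> CohesionResult:
    """Leave-one-out cohesion under an arbitrary symmetric similarity.

    For each member, the universe minus the member itself is ranked by
    similarity to it and scored with the remaining members as positives.
    The query member is excluded from its own ranked universe (it would be a
    guaranteed top positive and inflate the AUC).
    """
    idx = {e: i for i, e in enumerate(ids)}
    if universe is None:
        universe = set(ids)
    members = set(members)
    if len(members) < 2:
        raise ValueError("cohesion needs at least two member entities")
    if not members <= universe:
        raise ValueError("members must be contained in the universe")
    if not universe <= set(ids):
        raise ValueError("universe contains entities without similarity rows")
    aucs = []
    for m in sorted(members):
        others = sorted(universe - {m})
        scores = np.array([similarity[idx[m], idx[o]] for o in others], dtype=float)
        ranked = RankedList(others, scores)
        aucs.append(roc_auc(ranked, members - {m}))
    return CohesionResult("", aucs, float(np.median(aucs)))


def cohesion(
    members: set[str], model: LsiModel, universe: set[str] | None = None
) -> CohesionResult:
    """Cohesion under the LSI cosine similarity of scaled entity vectors."""
    unit, _ = normalize_rows(scaled_entity_vectors(model))
    sim = unit @ unit.T
    return cohesion_from_similarity(members, sim, model.entity_ids, universe)


def cooccurrence_similarity(cmap: EntityCitationMap) -> tuple[np.ndarray, list[str]]:
    """Entity-by-entity shared-citation counts (diagonal = citation counts)."""
    ids = cmap.entities()
    cids = sorted(cmap.all_citation_ids())
    cidx = {c: i for i, c in enumerate(cids)}
    B = np.zeros((len(ids), len(cids)), dtype=np.int64)
    for i, e in enumerate(ids):
        for c in cmap.citations_of(e):
            B[i, cidx[c]] = 1
    return B @ B.T, ids


def cooccurrence_cohesion(
    members: set[str], cmap: EntityCitationMap, universe: set[str] | None = None
) -> CohesionResult:
    """Cohesion under the shared-citation-count baseline similarity."""
    sim, ids = cooccurrence_similarity(cmap)
    return cohesion_from_similarity(members, sim.astype(float), ids, universe)


def compare_cohesions(
    lsi_aucs: Sequence[float], baseline_aucs: Sequence[float]
) -> tuple[float, str]:
    """Two-sample rank-sum test between per-member AUC lists.

    Returns (two-sided p-value, direction), direction being "lsi",
    "baseline" or "none".  Uses the exact distribution for small tie-free
    samples and the tie-corrected normal approximation otherwise.
    """
    lsi = np.asarray(lsi_aucs, dtype=float)
    base = np.asarray(baseline_aucs, dtype=float)
    if lsi.size == 0 or base.size == 0:
        raise ValueError("need observations on both sides")
    if np.array_equal(np.sort(lsi), np.sort(base)):
        return 1.0, "none"
    res = scipy.stats.mannwhitneyu(lsi, base, alternative="two-sided", method="auto")
    med_diff = np.median(lsi) - np.median(base)
    if med_diff > 0:
        direction = "lsi"
    elif med_diff < 0:
        direction = "baseline"
    else:
        direction = "none"
    return float(res.pvalue), direction


def information_gain(n_retrieved: int, n_curated: int) -> float:
    """Relative citation gain of retrieval over curation:
    (retrieved - curated) / curated.  Negative gain is possible."""
    if n_curated < 1:
        raise ValueError("information gain is undefined without curated citations")
    return (n_retrieved - n_curated) / n_curated


def recall_against_curated(retrieved: set[str], curated: set[str]) -> float:
    """Fraction of curated citations present among the retrieved ones."""
    if not curated:
        raise ValueError("empty curated set")
    return len(retrieved & curated) / len(curated)


def read_gold_standard_tsv(path: str | Path, universe: set[str] | None = None) -> GoldStandard:
    """TSV with columns (category, entity_id) -- or (category, term)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    cat_col, member_col = df.columns[:2]
    cats: dict[str, set[str]] = {}
    for cat, member in zip(df[cat_col], df[member_col]):
        cats.setdefault(cat, set()).add(member)
    return GoldStandard(cats, universe)
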