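"""Query projection and cosine-ranked retrieval in the truncated space.

A term query starts from a binary indicator q0 over the vocabulary and is
projected into the concept space as q = q0' U_k (the sum of the U_k rows of
the matched terms).  Entities are then ranked by the cosine between q and
each scaled entity vector (row of V_k S_k).  An entity query is the mirror
image: q is the sum of V_k rows of the queried entities, and terms are
ranked by cosine against rows of U_k S_k.

The entity-query direction has no single canonical projection; by symmetry
of the factorization (A' = V S U') this module sums unscaled V_k rows,
mirroring q0' U_k on the term side.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .lsi import LsiModel, normalize_rows, scaled_entity_vectors, scaled_term_vectors
from .vectorize import tokenize

__all__ = ["QueryVector", "RankedList", "QueryError",
           "make_term_query", "make_entity_query",
           "rank_entities", "rank_terms", "pairwise_cosines"]

DEFAULT_TOP_TERMS = 300
DEFAULT_TOP_ENTITIES = 50


class QueryError(ValueError):
    """No usable query could be built (e.g. no term matched the vocabulary)."""


@dataclass(frozen=True)
class QueryVector:
    """A k-dimensional query with provenance.

    ``matched`` are the vocabulary terms / entity IDs that contributed;
    ``missed`` the requested items absent from the model.
    """

    vector: np.ndarray
    provenance: tuple[str, ...]
    matched: tuple[str, ...]
    missed: tuple[str, ...] = ()


@dataclass
class RankedList:
    """Items ordered by descending cosine to a query; lexicographic ties."""

    ids: list[str]
    scores: np.ndarray
    provenance: tuple[str, ...] = ()

    def __len__(self) -> int:
        return len(self.ids)

    def __iter__(self):
        return iter(zip(self.ids, self.scores))

    def top(self, n: int) -> "RankedList":
        return RankedList(self.ids[:n], self.scores[:n], self.provenance)

    def to_rows(self) -> list[tuple[int, str, float]]:
        return [(i + 1, e, float(s)) for i, (e, s) in enumerate(self)]


def make_term_query(
    terms: Sequence[str] | str,
    model: LsiModel,
    stoplist: frozenset[str] | set[str] = frozenset(),
) -> QueryVector:
    """Project a (possibly multiword) term query: q = q0' U_k.

    Each input string is tokenized with the corpus tokenizer, so stop-words
    in phrases like "head and neck squamous cell carcinoma" are dropped.
    The indicator q0 is binary: duplicate terms count once.
    """
    if isinstance(terms, str):
        terms = [terms]
    tokens: list[str] = []
    for t in terms:
        tokens.extend(tokenize(t, stoplist))
    seen = sorted(set(tokens))
    matched = [t for t in seen if t in model.vocabulary]
    missed = [t for t in seen if t not in model.vocabulary]
    if not matched:
        raise QueryError(f"no query term found in vocabulary; missed: {missed}")
    idx = [model.term_index(t) for t in matched]
    q = model.u[idx].sum(axis=0)
    return QueryVector(q, tuple(terms), tuple(matched), tuple(missed))


def make_entity_query(entities: Sequence[str] | str, model: LsiModel) -> QueryVector:
    """Entity query by symmetry: q = sum of V_k rows of the queried entities."""
    if isinstance(entities, str):
        entities = [entities]
    if not entities:
        raise QueryError("empty entity query")
    unique = sorted(set(entities))
    idx = [model.entity_index(e) for e in unique]  # raises on unknown
    q = model.v[idx].sum(axis=0)
    return QueryVector(q, tuple(entities), tuple(unique))


def _cosine_rank(q: np.ndarray, vectors: np.ndarray, ids: Sequence[str],
                 provenance: tuple[str, ...]) -> RankedList:
    qn = np.linalg.norm(q)
    if qn == 0:
        raise QueryError("zero query vector")
    unit, zero = normalize_rows(vectors)
    scores = unit @ (q / qn)
    scores = np.clip(scores, -1.0, 1.0)
    scores[zero] = 0.0  # objects with no signal in the top-k factors
    order = sorted(range(len(ids)), key=lambda i: (-scores[i], ids[i]))
    return RankedList([ids[i] for i in order], scores[np.array(order)], provenance)


def rank_entities(q: QueryVector, model: LsiModel, top_n: int | None = None) -> RankedList:
    """Cosine of the query against every scaled entity vector, descending."""
    ranked = _cosine_rank(q.vector, scaled_entity_vectors(model),
                          model.entity_ids, q.provenance)
    return ranked.top(top_n) if top_n is not None else ranked


def rank_terms(q: QueryVector, model: LsiModel, top_n: int = DEFAULT_TOP_TERMS) -> RankedList:
    """Cosine of the query against every scaled term vector, top_n kept."""
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    ranked = _cosine_rank(q.vector, scaled_term_vectors(model),
                          model.vocabulary.terms, q.provenance)
    return ranked.top(top_n)


def pairwise_cosines(model: LsiModel) -> np.ndarray:
    """Entity-by-entity cosine matrix (symmetric, unit diagonal, in [-1,1])."""
    unit, _ = normalize_rows(scaled_entity_vectors(model))
    M = unit @ unit.T
    np.clip(M, -1.0, 1.0, out=M)
    np.fill_diagonal(M, 1.0)
    return (M + M.T) / 2.0
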