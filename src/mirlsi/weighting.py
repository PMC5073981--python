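"""Log-entropy weighting of the term-by-entity frequency matrix.

Each raw count f_ij is replaced by a_ij = l_ij * g_i, where

    l_ij = log2(1 + f_ij)                        (local weight)
    g_i  = 1 + sum_j p_ij log2 p_ij / log2 n     (global weight)
    p_ij = f_ij / sum_j f_ij

with n the number of entity documents and the 0*log(0) = 0 convention.
The global weight is 1 for a term confined to a single document and 0 for a
term spread uniformly over all documents, so common terms are discounted
while document-specific terms keep their weight.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import scipy.io
import scipy.sparse as sp

from .vectorize import TermDocumentMatrix, Vocabulary

__all__ = ["WeightedMatrix", "local_weight", "global_weight", "apply_log_entropy",
           "save_weighted", "load_weighted"]


@dataclass
class WeightedMatrix:
    """Log-entropy weighted term-by-entity matrix.

    ``matrix`` keeps the sparsity pattern of the raw counts (explicit zeros
    are retained where a zero global weight annihilates a nonzero count).
    """

    matrix: sp.csr_matrix
    global_weights: np.ndarray
    vocabulary: Vocabulary
    entity_ids: list[str]

    @property
    def shape(self) -> tuple[int, int]:
        return self.matrix.shape


def local_weight(f):
    """log2(1 + f) for nonnegative counts; accepts scalars or arrays."""
    arr = np.asarray(f, dtype=float)
    if np.any(arr < 0):
        raise ValueError("counts must be nonnegative")
    return np.log2(1.0 + arr) if arr.ndim else float(np.log2(1.0 + arr))


def global_weight(row, n: int | None = None) -> float:
    """Entropy-based global weight of one term's frequency row.

    Equals 1 when the term occurs in a single document and 0 when spread
    uniformly over all n documents.  For a single-document corpus (n=1) the
    formula is degenerate and the weight is defined as 1.
    """
    arr = np.asarray(row, dtype=float)
    if n is None:
        n = arr.size
    if np.any(arr < 0):
        raise ValueError("counts must be nonnegative")
    total = arr.sum()
    if total == 0:
        raise ValueError("all-zero frequency row has no global weight")
    if n == 1:
        return 1.0
    p = arr[arr > 0] / total
    entropy = float(np.sum(p * np.log2(p)))
    g = 1.0 + entropy / np.log2(n)
    return float(min(1.0, max(0.0, g)))


def apply_log_entropy(tdm: TermDocumentMatrix) -> WeightedMatrix:
    """Weight every entry of the raw matrix: a_ij = log2(1+f_ij) * g_i.

    Uses the sparse structure: only nonzero p_ij contribute to the row
    entropies (0*log0 = 0).
    """
    counts = tdm.counts.tocoo()
    n_terms, n_docs = tdm.counts.shape
    row_sums = np.asarray(tdm.counts.sum(axis=1)).ravel()
    if np.any(row_sums == 0):
        raise ValueError("vocabulary contains a term that appears nowhere")

    if n_docs == 1:
        g = np.ones(n_terms)
    else:
        p = counts.data / row_sums[counts.row]
        contrib = p * np.log2(p)
        entropy = np.zeros(n_terms)
        np.add.at(entropy, counts.row, contrib)
        g = 1.0 + entropy / np.log2(n_docs)
        np.clip(g, 0.0, 1.0, out=g)

    data = np.log2(1.0 + counts.data) * g[counts.row]
    weighted = sp.csr_matrix(
        (data, (counts.row, counts.col)), shape=(n_terms, n_docs)
    )
    return WeightedMatrix(weighted, g, tdm.vocabulary, list(tdm.entity_ids))


def save_weighted(w: WeightedMatrix, prefix: str | Path) -> None:
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(str(prefix) + ".mtx", w.matrix)
    np.savetxt(str(prefix) + ".g.txt", w.global_weights)
    Path(str(prefix) + ".rows.txt").write_text("\n".join(w.vocabulary.terms) + "\n")
    Path(str(prefix) + ".cols.txt").write_text("\n".join(w.entity_ids) + "\n")


def load_weighted(prefix: str | Path) -> WeightedMatrix:
    mat = sp.csr_matrix(scipy.io.mmread(str(prefix) + ".mtx"))
    g = np.loadtxt(str(prefix) + ".g.txt")
    terms = Path(str(prefix) + ".rows.txt").read_text().splitlines()
    entities = Path(str(prefix) + ".cols.txt").read_text().splitlines()
    return WeightedMatrix(mat, np.atleast_1d(g), Vocabulary(terms), entities)
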