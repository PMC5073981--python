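"""Truncated SVD of the weighted matrix with entropy-based rank selection.

The weighted term-by-entity matrix A is factorized as A = U S V'.  The
truncation rank k is chosen from the spectrum itself: with contributions
C_i = sigma_i^2 / sum sigma^2 and normalized spectrum entropy

    E = -(1/log r) * sum_i C_i log C_i        (0 <= E <= 1),

k = round(E * r), clamped to [1, r].  E is 0 when all variation sits in the
first dimension and 1 when all dimensions contribute equally, so k scales
with the effective dimensionality of the collection.

Term vectors are rows of U_k S_k and entity vectors rows of V_k S_k;
associations between any pair of objects are cosines between these vectors.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg

from .vectorize import Vocabulary
from .weighting import WeightedMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "LsiModel",
    "SpectrumSummary",
    "decompose",
    "contributions",
    "spectrum_entropy",
    "select_k",
    "truncate",
    "fit_lsi",
    "scaled_term_vectors",
    "scaled_entity_vectors",
    "normalize_rows",
    "save_model",
    "load_model",
]

# singular values below this fraction of sigma_1 are treated as numerical
# zeros when computing contributions
RANK_TOL = 1e-10

# below this min-dimension a dense LAPACK SVD is cheaper and exact; above it
# the sparse iterative solver is used
_DENSE_LIMIT = 1500


@dataclass
class LsiModel:
    """Truncated factors of the weighted term-by-entity matrix.

    u: terms x k left singular vectors; s: singular values (non-increasing);
    v: entities x k right singular vectors; r is the rank of the
    decomposition the truncation was taken from.
    """

    u: np.ndarray
    s: np.ndarray
    v: np.ndarray
    k: int
    r: int
    vocabulary: Vocabulary
    entity_ids: list[str]

    @property
    def n_terms(self) -> int:
        return self.u.shape[0]

    @property
    def n_entities(self) -> int:
        return self.v.shape[0]

    def term_index(self, term: str) -> int:
        return self.vocabulary.index[term]

    def entity_index(self, entity_id: str) -> int:
        try:
            return self._eidx[entity_id]
        except KeyError:
            raise KeyError(f"unknown entity {entity_id!r}") from None

    def __post_init__(self) -> None:
        self._eidx = {e: i for i, e in enumerate(self.entity_ids)}
        if np.any(np.diff(self.s) > 1e-9 * max(self.s[0], 1.0)):
            raise ValueError("singular values must be non-increasing")


@dataclass(frozen=True)
class SpectrumSummary:
    """Per-dimension variance contributions, their entropy, and the chosen k."""

    contributions: np.ndarray
    entropy: float
    k: int
    r: int


def _fix_signs(u: np.ndarray, v: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    # SVD is sign-ambiguous per column pair; make the largest-magnitude
    # component of each left singular vector positive for reproducible output
    idx = np.argmax(np.abs(u), axis=0)
    signs = np.sign(u[idx, np.arange(u.shape[1])])
    signs[signs == 0] = 1.0
    return u * signs, v * signs


def decompose(weighted: WeightedMatrix, r: int | None = None) -> LsiModel:
    """Singular value decomposition of the weighted matrix, kept to rank r.

    ``r`` defaults to min(n_terms, n_entities).  Small problems use a dense
    LAPACK SVD; larger ones the sparse Lanczos solver.
    """
    A = weighted.matrix
    max_rank = min(A.shape)
    if r is None:
        r = max_rank
    if not 1 <= r <= max_rank:
        raise ValueError(f"requested rank {r} outside [1, {max_rank}]")

    if max_rank <= _DENSE_LIMIT:
        u, s, vt = np.linalg.svd(np.asarray(A.todense()), full_matrices=False)
        u, s, vt = u[:, :r], s[:r], vt[:r]
    else:
        k_solve = min(r, max_rank - 1)
        u, s, vt = scipy.sparse.linalg.svds(A.astype(float), k=k_solve)
        order = np.argsort(s)[::-1]
        u, s, vt = u[:, order], s[order], vt[order]

    u, v = _fix_signs(u, vt.T)
    return LsiModel(u, s, v, k=len(s), r=len(s),
                    vocabulary=weighted.vocabulary,
                    entity_ids=list(weighted.entity_ids))


def contributions(singular_values) -> np.ndarray:
    """Fraction of total variance captured per dimension: C_i = s_i^2 / sum s^2."""
    s = np.asarray(singular_values, dtype=float)
    total = np.sum(s ** 2)
    if total == 0:
        raise ValueError("all-zero spectrum has no contributions")
    return s ** 2 / total


def spectrum_entropy(C, r: int | None = None) -> float:
    """Normalized entropy of a contribution vector, in [0, 1].

    The logarithm base cancels between numerator and the log(r) normalizer;
    natural logs are used.  0*log(0) is taken as 0.
    """
    C = np.asarray(C, dtype=float)
    if r is None:
        r = C.size
    if r < 2:
        raise ValueError("entropy normalization needs r >= 2")
    pos = C[C > 0]
    ent = -float(np.sum(pos * np.log(pos)))
    return float(min(1.0, max(0.0, ent / np.log(r))))


def select_k(model: LsiModel, rank_tol: float = RANK_TOL) -> SpectrumSummary:
    """Entropy-derived truncation rank: k = round(E * r), clamped to [1, r].

    Singular values below ``rank_tol * sigma_1`` are excluded as numerical
    zeros before computing contributions.
    """
    s = model.s
    s_eff = s[s > rank_tol * s[0]] if s[0] > 0 else s[:1]
    r_eff = len(s_eff)
    if r_eff < 2:
        return SpectrumSummary(np.array([1.0]), 0.0, 1, r_eff)
    C = contributions(s_eff)
    E = spectrum_entropy(C, r_eff)
    k = int(round(E * r_eff))  # round-half-even
    k = max(1, min(r_eff, k))
    logger.info("spectrum: r=%d E=%.4f k=%d", r_eff, E, k)
    return SpectrumSummary(C, E, k, r_eff)


def truncate(model: LsiModel, k: int) -> LsiModel:
    """Keep the k leading singular triplets."""
    if not 1 <= k <= len(model.s):
        raise ValueError(f"k={k} outside [1, {len(model.s)}]")
    return LsiModel(model.u[:, :k].copy(), model.s[:k].copy(), model.v[:, :k].copy(),
                    k=k, r=model.r, vocabulary=model.vocabulary,
                    entity_ids=list(model.entity_ids))


def fit_lsi(
    weighted: WeightedMatrix, k: int | None = None
) -> tuple[LsiModel, SpectrumSummary]:
    """Decompose, choose k by spectrum entropy (unless overridden), truncate."""
    full = decompose(weighted)
    summary = select_k(full)
    k_use = k if k is not None else summary.k
    return truncate(full, k_use), summary


def scaled_term_vectors(model: LsiModel, unit: bool = False) -> np.ndarray:
    """Rows of U_k S_k (term coordinates), optionally unit-normalized."""
    vecs = model.u * model.s
    return normalize_rows(vecs)[0] if unit else vecs


def scaled_entity_vectors(model: LsiModel, unit: bool = False) -> np.ndarray:
    """Rows of V_k S_k (entity coordinates), optionally unit-normalized."""
    vecs = model.v * model.s
    return normalize_rows(vecs)[0] if unit else vecs


def normalize_rows(m: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Unit-normalize rows; zero rows stay zero and are flagged.

    Returns (normalized matrix, boolean mask of zero rows).
    """
    norms = np.linalg.norm(m, axis=1)
    zero = norms == 0
    safe = np.where(zero, 1.0, norms)
    return m / safe[:, None], zero


# --------------------------------------------------------------------------
# Persistence
# --------------------------------------------------------------------------

def _corpus_hash(model: LsiModel) -> str:
    h = hashlib.sha256()
    h.update("\n".join(model.vocabulary.terms).encode())
    h.update("\n".join(model.entity_ids).encode())
    return h.hexdigest()[:16]


def save_model(model: LsiModel, summary: SpectrumSummary | None, directory: str | Path) -> None:
    """Persist factors (binary arrays), labels (text) and JSON metadata."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    np.save(d / "u.npy", model.u)
    np.save(d / "s.npy", model.s)
    np.save(d / "v.npy", model.v)
    (d / "terms.txt").write_text("\n".join(model.vocabulary.terms) + "\n")
    (d / "entities.txt").write_text("\n".join(model.entity_ids) + "\n")
    meta = {
        "k": model.k,
        "r": model.r,
        "weighting": "log-entropy",
        "corpus_hash": _corpus_hash(model),
    }
    if summary is not None:
        meta["entropy"] = summary.entropy
        meta["contributions"] = [float(c) for c in summary.contributions]
    (d / "metadata.json").write_text(json.dumps(meta, indent=1))


def load_model(directory: str | Path) -> LsiModel:
    d = Path(directory)
    meta = json.loads((d / "metadata.json").read_text())
    u = np.load(d / "u.npy")
    s = np.load(d / "s.npy")
    v = np.load(d / "v.npy")
    terms = (d / "terms.txt").read_text().splitlines()
    entities = (d / "entities.txt").read_text().splitlines()
    return LsiModel(u, s, v, k=meta["k"], r=meta["r"],
                    vocabulary=Vocabulary(terms), entity_ids=entities)
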