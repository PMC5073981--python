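"""Tokenization and the raw term-by-entity frequency matrix.

Text is lowercased; every punctuation character except hyphen and underscore
is treated as a token boundary (so "p53/MDM2" yields two tokens rather than
fusing into one); stop-list members are dropped.  The vocabulary is the
lexicographically sorted union of retained tokens, which makes matrix
construction deterministic.
"""

from __future__ import annotations

import logging
import re
from collections import Counter
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import scipy.io
import scipy.sparse as sp

from .corpus import EntityDocument

logger = logging.getLogger(__name__)

__all__ = [
    "Vocabulary",
    "TermDocumentMatrix",
    "tokenize",
    "build_term_document_matrix",
    "load_stoplist",
    "default_stoplist",
    "save_tdm",
    "load_tdm",
]

# token boundary: anything that is not a word character or hyphen
# (\w covers letters, digits and underscore)
_BOUNDARY = re.compile(r"[^\w\-]+")
_HAS_ALNUM = re.compile(r"[0-9a-z]")
_NUMERIC = re.compile(r"^[\d\-]+$")


def tokenize(
    text: str,
    stoplist: frozenset[str] | set[str] = frozenset(),
    keep_numeric: bool = True,
) -> list[str]:
    """Split free text into lowercase terms, preserving order and multiplicity.

    Hyphens and underscores are kept inside tokens; all other punctuation
    acts as whitespace.  Tokens with no alphanumeric character, stop-list
    members and (optionally) purely numeric tokens are dropped.
    """
    tokens = _BOUNDARY.split(text.lower())
    out = []
    for tok in tokens:
        if not tok or not _HAS_ALNUM.search(tok):
            continue
        if tok in stoplist:
            continue
        if not keep_numeric and _NUMERIC.match(tok):
            continue
        out.append(tok)
    return out


class Vocabulary:
    """Ordered list of unique terms with a term -> index lookup."""

    def __init__(self, terms: Sequence[str]) -> None:
        self.terms: list[str] = list(terms)
        self.index: dict[str, int] = {t: i for i, t in enumerate(self.terms)}
        if len(self.index) != len(self.terms):
            raise ValueError("vocabulary terms must be unique")

    def __len__(self) -> int:
        return len(self.terms)

    def __contains__(self, term: str) -> bool:
        return term in self.index

    def __getitem__(self, i: int) -> str:
        return self.terms[i]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Vocabulary):
            return NotImplemented
        return self.terms == other.terms


@dataclass
class TermDocumentMatrix:
    """Raw term frequencies f_ij over a vocabulary (rows) and entity
    documents (columns)."""

    counts: sp.csr_matrix
    vocabulary: Vocabulary
    entity_ids: list[str]

    @property
    def n_terms(self) -> int:
        return self.counts.shape[0]

    @property
    def n_documents(self) -> int:
        return self.counts.shape[1]


def build_term_document_matrix(
    documents: Sequence[EntityDocument],
    stoplist: frozenset[str] | set[str] = frozenset(),
    keep_numeric: bool = True,
) -> TermDocumentMatrix:
    """Count term occurrences per entity document.

    Documents that tokenize to nothing are dropped (with a warning) so that
    every matrix column has at least one nonzero; if *all* documents are
    empty after tokenization an error is raised.
    """
    if not documents:
        raise ValueError("need at least one document")
    token_lists: list[tuple[str, Counter]] = []
    for doc in documents:
        counts = Counter(tokenize(doc.text, stoplist, keep_numeric))
        if counts:
            token_lists.append((doc.entity_id, counts))
        else:
            logger.warning("document for entity %r tokenized to nothing; dropped", doc.entity_id)
    if not token_lists:
        raise ValueError("all documents tokenized to empty after stop-word removal")

    vocab = Vocabulary(sorted(set().union(*(c.keys() for _, c in token_lists))))
    rows, cols, data = [], [], []
    for j, (_, counts) in enumerate(token_lists):
        for term, f in counts.items():
            rows.append(vocab.index[term])
            cols.append(j)
            data.append(f)
    mat = sp.csr_matrix(
        (data, (rows, cols)), shape=(len(vocab), len(token_lists)), dtype=np.int64
    )
    return TermDocumentMatrix(mat, vocab, [e for e, _ in token_lists])


# --------------------------------------------------------------------------
# Stop lists
# --------------------------------------------------------------------------

def load_stoplist(path: str | Path) -> frozenset[str]:
    """Plain text, one word per line; '#' starts a comment; case-insensitive."""
    words = set()
    with open(path) as fh:
        for line in fh:
            word = line.split("#", 1)[0].strip().lower()
            if word:
                words.add(word)
    return frozenset(words)


def default_stoplist() -> frozenset[str]:
    """The generic English stop list bundled with the package."""
    text = resources.files("mirlsi").joinpath("data/stopwords.txt").read_text()
    words = set()
    for line in text.splitlines():
        word = line.split("#", 1)[0].strip().lower()
        if word:
            words.add(word)
    return frozenset(words)


# --------------------------------------------------------------------------
# Serialization: MatrixMarket plus sidecar label files
# --------------------------------------------------------------------------

def save_tdm(tdm: TermDocumentMatrix, prefix: str | Path) -> None:
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(str(prefix) + ".mtx", tdm.counts)
    Path(str(prefix) + ".rows.txt").write_text("\n".join(tdm.vocabulary.terms) + "\n")
    Path(str(prefix) + ".cols.txt").write_text("\n".join(tdm.entity_ids) + "\n")


def load_tdm(prefix: str | Path) -> TermDocumentMatrix:
    counts = sp.csr_matrix(scipy.io.mmread(str(prefix) + ".mtx")).astype(np.int64)
    terms = Path(str(prefix) + ".rows.txt").read_text().splitlines()
    entities = Path(str(prefix) + ".cols.txt").read_text().splitlines()
    return TermDocumentMatrix(counts, Vocabulary(terms), entities)
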