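"""Assembly of entity documents from literature citations.

An *entity document* is the concatenation of the titles and abstracts of
every citation linked to one entity (here, a miRNA).  Before concatenation,
nonspecific citations -- those that reference implausibly many entities,
typically high-throughput screens with no per-entity information -- are
removed using an interquartile-range (IQR) outlier rule on the distribution
of entities-per-citation.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Protocol, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Citation",
    "EntityCitationMap",
    "EntityDocument",
    "expand_synonyms",
    "build_query_string",
    "compute_citation_specificity_threshold",
    "filter_nonspecific_citations",
    "build_entity_documents",
    "read_citations_tsv",
    "read_citations_jsonl",
    "write_citations_tsv",
    "read_entity_map_tsv",
    "write_entity_map_tsv",
    "CitationRetriever",
    "FileBackedRetriever",
]


@dataclass(frozen=True)
class Citation:
    """One literature record (PMID-like ID, title, abstract, year)."""

    citation_id: str
    title: str
    abstract: str = ""
    year: int | None = None

    def __post_init__(self) -> None:
        if not self.citation_id:
            raise ValueError("citation_id must be non-empty")
        if not self.title:
            raise ValueError(f"citation {self.citation_id!r}: title must be non-empty")


class EntityCitationMap:
    """Mapping entity_id -> set of citation_ids, with per-link provenance.

    Provenance is ``"curated"`` (manually assigned, e.g. database linkouts)
    or ``"retrieved"`` (found by an automated literature search).
    """

    def __init__(self) -> None:
        self._links: dict[str, set[str]] = {}
        self._provenance: dict[tuple[str, str], str] = {}

    def add(self, entity_id: str, citation_id: str, provenance: str = "curated") -> None:
        if provenance not in ("curated", "retrieved"):
            raise ValueError(f"unknown provenance {provenance!r}")
        self._links.setdefault(entity_id, set()).add(citation_id)
        # curated wins if the same link arrives from both sources
        key = (entity_id, citation_id)
        if self._provenance.get(key) != "curated":
            self._provenance[key] = provenance

    def provenance(self, entity_id: str, citation_id: str) -> str:
        return self._provenance[(entity_id, citation_id)]

    def entities(self) -> list[str]:
        return sorted(self._links)

    def citations_of(self, entity_id: str) -> set[str]:
        return set(self._links[entity_id])

    def all_citation_ids(self) -> set[str]:
        out: set[str] = set()
        for cids in self._links.values():
            out |= cids
        return out

    def citation_entity_counts(self) -> dict[str, int]:
        """Number of entities each citation is linked to."""
        counts: dict[str, int] = {}
        for cids in self._links.values():
            for cid in cids:
                counts[cid] = counts.get(cid, 0) + 1
        return counts

    def n_links(self) -> int:
        return sum(len(c) for c in self._links.values())

    def __len__(self) -> int:
        return len(self._links)

    def __contains__(self, entity_id: str) -> bool:
        return entity_id in self._links

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, EntityCitationMap):
            return NotImplemented
        return self._links == other._links

    def copy(self) -> "EntityCitationMap":
        new = EntityCitationMap()
        new._links = {e: set(c) for e, c in self._links.items()}
        new._provenance = dict(self._provenance)
        return new

    def items(self):
        return self._links.items()


@dataclass(frozen=True)
class EntityDocument:
    """Concatenated titles+abstracts of every citation linked to one entity."""

    entity_id: str
    text: str
    n_citations: int

    def __post_init__(self) -> None:
        if self.n_citations < 1:
            raise ValueError("an entity document needs at least one citation")


# --------------------------------------------------------------------------
# Synonym expansion and query construction
# --------------------------------------------------------------------------

_SYMBOL_RE = re.compile(r"^(?:hsa[-_]?)?(mir|microrna|mirna)[-_\s]?(\S+)$", re.IGNORECASE)

DEFAULT_BASE_TOKENS = ("mir", "miR", "microRNA")


def expand_synonyms(
    symbol: str, base_tokens: Sequence[str] = DEFAULT_BASE_TOKENS
) -> set[str]:
    """Spelling variants of an entity symbol.

    A symbol such as ``mir-19a`` is split into a base token and a suffix
    (``19a``); variants are formed by crossing the base spellings
    (by default mir / miR / microRNA) with hyphenated and unhyphenated joins.
    The input symbol itself is always included, and for every hyphenated
    variant the hyphen-free form is included too.
    """
    m = _SYMBOL_RE.match(symbol.strip())
    if m is None or not m.group(2):
        raise ValueError(f"cannot parse entity symbol {symbol!r}: no base token + suffix")
    suffix = m.group(2)
    variants = {symbol}
    for base in base_tokens:
        variants.add(f"{base}{suffix}")
        variants.add(f"{base}-{suffix}")
    # closure under hyphen stripping
    variants |= {v.replace("-", "") for v in variants}
    return variants


def build_query_string(synonyms: Iterable[str]) -> str:
    """OR-joined literature query over the sorted synonyms."""
    syns = sorted(set(synonyms))
    if not syns:
        raise ValueError("cannot build a query from an empty synonym set")
    return " OR ".join(syns)


# --------------------------------------------------------------------------
# Nonspecific-citation filtering (IQR outlier rule)
# --------------------------------------------------------------------------

def compute_citation_specificity_threshold(
    counts: Sequence[int], quantile_method: str = "linear"
) -> int | None:
    """Smallest right outlier of the entities-per-citation distribution.

    A right outlier is a count strictly greater than Q3 + 1.5*(Q3 - Q1); the
    returned value is the smallest observed count beyond that fence, and any
    citation referencing at least that many entities is considered
    nonspecific.  Returns ``None`` (no filtering) when no count exceeds the
    fence.

    Quartiles use linear interpolation between order statistics by default
    (``quantile_method`` is passed to :func:`numpy.percentile`).
    """
    arr = np.asarray(list(counts))
    if arr.size == 0:
        raise ValueError("empty count list")
    if np.any(arr <= 0):
        raise ValueError("counts must be positive integers")
    q1, q3 = np.percentile(arr, [25, 75], method=quantile_method)
    fence = q3 + 1.5 * (q3 - q1)
    beyond = arr[arr > fence]
    if beyond.size == 0:
        return None
    return int(beyond.min())


def filter_nonspecific_citations(
    cmap: EntityCitationMap, threshold: int | None
) -> EntityCitationMap:
    """Remove every citation linked to ``threshold`` or more entities.

    Entities left with no citations are dropped (only "active" entities
    remain).  ``threshold=None`` is the no-filtering sentinel and returns an
    unmodified copy.
    """
    if threshold is None:
        return cmap.copy()
    if threshold < 1:
        raise ValueError("threshold must be >= 1")
    counts = cmap.citation_entity_counts()
    doomed = {cid for cid, c in counts.items() if c >= threshold}
    out = EntityCitationMap()
    for entity, cids in cmap.items():
        for cid in cids - doomed:
            out.add(entity, cid, cmap.provenance(entity, cid))
    logger.info(
        "nonspecific-citation filter (threshold=%d): removed %d of %d citations, "
        "kept %d of %d entities",
        threshold, len(doomed), len(counts), len(out), len(cmap),
    )
    return out


# --------------------------------------------------------------------------
# Document construction
# --------------------------------------------------------------------------

def build_entity_documents(
    citations: Iterable[Citation], cmap: EntityCitationMap
) -> list[EntityDocument]:
    """One document per active entity: titles+abstracts concatenated.

    Contributing citations are ordered by ascending citation_id; the title
    and (non-empty) abstract of each are joined by single spaces.
    """
    by_id: dict[str, Citation] = {c.citation_id: c for c in citations}
    docs: list[EntityDocument] = []
    for entity in cmap.entities():
        parts: list[str] = []
        cids = sorted(cmap.citations_of(entity))
        for cid in cids:
            if cid not in by_id:
                raise KeyError(f"entity {entity!r} references unknown citation {cid!r}")
            cit = by_id[cid]
            parts.append(cit.title)
            if cit.abstract:
                parts.append(cit.abstract)
        docs.append(EntityDocument(entity, " ".join(parts), len(cids)))
    return docs


# --------------------------------------------------------------------------
# File formats
# --------------------------------------------------------------------------

_WS = re.compile(r"[\t\r\n]+")


def _clean(text: str) -> str:
    return _WS.sub(" ", text)


def read_citations_tsv(path: str | Path) -> list[Citation]:
    """Read a tab-separated citation table (citation_id, year, title, abstract)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"citation_id", "year", "title", "abstract"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"citation table missing columns: {sorted(missing)}")
    return [
        Citation(
            citation_id=row.citation_id,
            title=row.title,
            abstract=row.abstract,
            year=int(row.year) if row.year else None,
        )
        for row in df.itertuples()
    ]


def write_citations_tsv(citations: Iterable[Citation], path: str | Path) -> None:
    """Write a citation table as TSV; embedded tabs/newlines become spaces."""
    cits = list(citations)
    df = pd.DataFrame(
        {
            "citation_id": [c.citation_id for c in cits],
            "year": [c.year if c.year is not None else "" for c in cits],
            "title": [_clean(c.title) for c in cits],
            "abstract": [_clean(c.abstract) for c in cits],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_citations_jsonl(path: str | Path) -> list[Citation]:
    """Read citations from JSON-lines: one object per line with keys
    citation_id, title, abstract, year."""
    out: list[Citation] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            rec = json.loads(line)
            out.append(
                Citation(
                    citation_id=str(rec["citation_id"]),
                    title=rec["title"],
                    abstract=rec.get("abstract", ""),
                    year=rec.get("year"),
                )
            )
    return out


def read_entity_map_tsv(path: str | Path) -> EntityCitationMap:
    """Read entity links (entity_id, citation_id[, provenance]) from TSV."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if "entity_id" not in df.columns or "citation_id" not in df.columns:
        raise ValueError("entity map needs entity_id and citation_id columns")
    has_prov = "provenance" in df.columns
    cmap = EntityCitationMap()
    for row in df.itertuples():
        prov = row.provenance if has_prov and row.provenance else "curated"
        cmap.add(row.entity_id, row.citation_id, prov)
    return cmap


def write_entity_map_tsv(cmap: EntityCitationMap, path: str | Path) -> None:
    rows = []
    for entity in cmap.entities():
        for cid in sorted(cmap.citations_of(entity)):
            rows.append((entity, cid, cmap.provenance(entity, cid)))
    pd.DataFrame(rows, columns=["entity_id", "citation_id", "provenance"]).to_csv(
        path, sep="\t", index=False
    )


# --------------------------------------------------------------------------
# Retrieval interface
# --------------------------------------------------------------------------

class CitationRetriever(Protocol):
    """A literature search backend: query string -> citation IDs.

    A live E-utilities client could implement this; the package ships only a
    file-backed implementation for offline use.
    """

    def fetch(self, query: str) -> list[str]:
        ...


class FileBackedRetriever:
    """Retriever answering from a pre-recorded query -> citation-ID table.

    The table is a JSON object mapping exact query strings to lists of
    citation IDs.
    """

    def __init__(self, mapping: Mapping[str, Sequence[str]] | None = None,
                 path: str | Path | None = None) -> None:
        if (mapping is None) == (path is None):
            raise ValueError("provide exactly one of mapping or path")
        if path is not None:
            with open(path) as fh:
                mapping = json.load(fh)
        self._mapping = {q: list(cids) for q, cids in dict(mapping).items()}

    def fetch(self, query: str) -> list[str]:
        return list(self._mapping.get(query, []))
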