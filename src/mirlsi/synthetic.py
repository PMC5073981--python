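"""Synthetic abstract corpora with planted topic structure.

The generator emulates an entity-centric literature collection: entities
(miRNA-like symbols) are partitioned into topics; each entity receives a set
of short citations (title + abstract) whose words mix a topic-specific
vocabulary with a shared background vocabulary.  Ground-truth topic labels
are returned so retrieval, cohesion and clustering can be scored against the
planted structure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .corpus import Citation, EntityCitationMap

__all__ = ["SyntheticCorpusConfig", "generate_synthetic_corpus"]


@dataclass(frozen=True)
class SyntheticCorpusConfig:
    """Parameters of a planted-topic corpus.

    Defaults describe a small but structured collection: 50 entities split
    evenly over 5 topics, 6 citations each, 40 topic-specific words per
    topic and 200 background words, with 60 % of abstract words drawn from
    the entity's topic vocabulary.
    """

    n_entities: int = 50
    n_topics: int = 5
    topic_vocab_size: int = 40
    background_vocab_size: int = 200
    citations_per_entity: int = 6
    title_length: int = 8
    abstract_length_mean: int = 60
    topic_word_fraction: float = 0.6
    n_nonspecific: int = 0
    nonspecific_breadth: int = 10
    year_range: tuple[int, int] = (2000, 2015)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "n_entities", "n_topics", "topic_vocab_size", "background_vocab_size",
            "citations_per_entity", "title_length", "abstract_length_mean",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 <= self.topic_word_fraction <= 1.0:
            raise ValueError("topic_word_fraction must lie in [0, 1]")
        if self.n_topics > self.n_entities:
            raise ValueError("need at least one entity per topic")
        if self.n_nonspecific < 0 or self.nonspecific_breadth < 2:
            raise ValueError("invalid nonspecific-citation settings")


def _topic_vocab(topic: int, size: int) -> list[str]:
    return [f"topic{topic:02d}term{w:03d}" for w in range(size)]


def _background_vocab(size: int) -> list[str]:
    return [f"common{w:03d}" for w in range(size)]


def generate_synthetic_corpus(
    config: SyntheticCorpusConfig,
) -> tuple[list[Citation], EntityCitationMap, dict[str, int]]:
    """Generate citations, entity links, and planted topic labels.

    Entities are assigned to topics round-robin; documents of entities in
    the same topic share that topic's vocabulary, so documents of different
    topics overlap only through background words.  Identical config (incl.
    seed) reproduces an identical corpus.
    """
    rng = np.random.default_rng(config.seed)
    topics = {t: np.array(_topic_vocab(t, config.topic_vocab_size)) for t in range(config.n_topics)}
    background = np.array(_background_vocab(config.background_vocab_size))

    entity_ids = [f"mir-{i + 1}" for i in range(config.n_entities)]
    labels = {e: i % config.n_topics for i, e in enumerate(entity_ids)}

    citations: list[Citation] = []
    cmap = EntityCitationMap()
    next_pmid = 90000000

    def draw_words(n: int, topic_words: np.ndarray, frac: float) -> list[str]:
        take_topic = rng.random(n) < frac
        out = np.where(
            take_topic,
            topic_words[rng.integers(0, len(topic_words), size=n)],
            background[rng.integers(0, len(background), size=n)],
        )
        return list(out)

    for entity in entity_ids:
        tvocab = topics[labels[entity]]
        for _ in range(config.citations_per_entity):
            pmid = str(next_pmid)
            next_pmid += 1
            n_abstract = max(10, int(rng.poisson(config.abstract_length_mean)))
            title = " ".join(draw_words(config.title_length, tvocab, config.topic_word_fraction))
            abstract = " ".join(draw_words(n_abstract, tvocab, config.topic_word_fraction))
            year = int(rng.integers(config.year_range[0], config.year_range[1] + 1))
            citations.append(Citation(pmid, title, abstract, year))
            cmap.add(entity, pmid, "retrieved")

    # optional nonspecific citations: background-only text linked to many
    # entities across topics (screen-like papers the IQR filter should catch)
    for _ in range(config.n_nonspecific):
        pmid = str(next_pmid)
        next_pmid += 1
        n_abstract = max(10, int(rng.poisson(config.abstract_length_mean)))
        title = " ".join(draw_words(config.title_length, background, 0.0))
        abstract = " ".join(draw_words(n_abstract, background, 0.0))
        year = int(rng.integers(config.year_range[0], config.year_range[1] + 1))
        citations.append(Citation(pmid, title, abstract, year))
        linked = rng.choice(config.n_entities, size=min(config.nonspecific_breadth, config.n_entities), replace=False)
        for idx in sorted(linked):
            cmap.add(entity_ids[int(idx)], pmid, "retrieved")

    return citations, cmap, labels
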