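"""Pipeline orchestration: build, query, evaluate, network, simulate.

Each run is reproducible from a configuration (YAML or keyword arguments)
plus a seed, and writes a machine-readable provenance record alongside its
outputs (configuration hash, corpus hash, per-stage counts, library
versions).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy
import sklearn
import yaml

from . import corpus as corpus_mod
from . import evaluation as eval_mod
from . import network as net_mod
from .lsi import LsiModel, SpectrumSummary, fit_lsi, load_model, save_model
from .query import (DEFAULT_TOP_ENTITIES, DEFAULT_TOP_TERMS, QueryError,
                    make_entity_query, make_term_query, pairwise_cosines,
                    rank_entities, rank_terms)
from .synthetic import SyntheticCorpusConfig, generate_synthetic_corpus
from .vectorize import build_term_document_matrix, default_stoplist, load_stoplist, tokenize
from .weighting import apply_log_entropy

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_build", "run_query", "run_evaluate",
           "run_network", "run_simulate"]


@dataclass
class PipelineConfig:
    """Settings of a pipeline run.

    ``specificity_threshold`` is "auto" (derive the smallest right outlier
    from the entities-per-citation distribution), an integer override, or
    None (no filtering).  ``k`` overrides the entropy-derived truncation
    rank when set.
    """

    citations: str = ""
    entity_map: str = ""
    stoplist: str | None = None
    gold_standard: str | None = None
    specificity_threshold: int | str | None = "auto"
    k: int | None = None
    max_year: int | None = None
    keep_numeric: bool = True
    top_terms: int = DEFAULT_TOP_TERMS
    top_entities: int = DEFAULT_TOP_ENTITIES
    percentile: float = net_mod.DEFAULT_PERCENTILE
    k_clusters: int = net_mod.DEFAULT_K_CLUSTERS
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.specificity_threshold, str) and self.specificity_threshold != "auto":
            raise ValueError("specificity_threshold must be 'auto', an integer, or null")
        for name in ("top_terms", "top_entities", "k_clusters"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0 < self.percentile < 100:
            raise ValueError("percentile must lie strictly between 0 and 100")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def _load_stoplist(config: PipelineConfig) -> frozenset[str]:
    return load_stoplist(config.stoplist) if config.stoplist else default_stoplist()


def _read_citations(path: str | Path) -> list[corpus_mod.Citation]:
    path = Path(path)
    if path.suffix in (".jsonl", ".json"):
        return corpus_mod.read_citations_jsonl(path)
    return corpus_mod.read_citations_tsv(path)


def _provenance(config: PipelineConfig, stages: dict, extra: dict | None = None) -> dict:
    prov = {
        "config": asdict(config),
        "config_hash": config.hash(),
        "stages": stages,
        "versions": {
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "scikit-learn": sklearn.__version__,
        },
    }
    if extra:
        prov.update(extra)
    return prov


def run_build(config: PipelineConfig, out_dir: str | Path) -> tuple[LsiModel, SpectrumSummary]:
    """Corpus -> filter -> tokenize -> weight -> SVD -> select k -> persist."""
    out_dir = Path(out_dir)
    stages: dict = {}

    citations = _read_citations(config.citations)
    cmap = corpus_mod.read_entity_map_tsv(config.entity_map)
    stages["citations_read"] = len(citations)
    stages["entities_read"] = len(cmap)

    if config.max_year is not None:
        keep = {c.citation_id for c in citations if c.year is not None and c.year <= config.max_year}
        citations = [c for c in citations if c.citation_id in keep]
        trimmed = corpus_mod.EntityCitationMap()
        for e, cids in cmap.items():
            for cid in cids & keep:
                trimmed.add(e, cid, cmap.provenance(e, cid))
        cmap = trimmed
        stages["citations_after_year_filter"] = len(citations)

    if config.specificity_threshold == "auto":
        counts = list(cmap.citation_entity_counts().values())
        threshold = corpus_mod.compute_citation_specificity_threshold(counts)
    else:
        threshold = config.specificity_threshold
    stages["specificity_threshold"] = threshold
    cmap = corpus_mod.filter_nonspecific_citations(cmap, threshold)
    stages["citations_kept"] = len(cmap.all_citation_ids())
    stages["entities_active"] = len(cmap)

    docs = corpus_mod.build_entity_documents(citations, cmap)
    stoplist = _load_stoplist(config)
    tdm = build_term_document_matrix(docs, stoplist, config.keep_numeric)
    stages["vocabulary_size"] = tdm.n_terms
    stages["documents"] = tdm.n_documents

    weighted = apply_log_entropy(tdm)
    model, summary = fit_lsi(weighted, k=config.k)
    stages["rank"] = summary.r
    stages["entropy"] = summary.entropy
    stages["k"] = model.k

    save_model(model, summary, out_dir)
    (out_dir / "provenance.json").write_text(
        json.dumps(_provenance(config, stages), indent=1, default=str)
    )
    logger.info("model built: %s", stages)
    return model, summary


def run_query(
    model_dir: str | Path,
    out_prefix: str | Path,
    terms: list[str] | None = None,
    entities: list[str] | None = None,
    top_entities: int = DEFAULT_TOP_ENTITIES,
    top_terms: int = DEFAULT_TOP_TERMS,
    stoplist: frozenset[str] | None = None,
) -> list[Path]:
    """Rank entities for a term query and/or terms for an entity query;
    write TSV files (rank, id, cosine)."""
    model = load_model(model_dir)
    if stoplist is None:
        stoplist = default_stoplist()
    written: list[Path] = []
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    if terms:
        q = make_term_query(terms, model, stoplist)
        ranked = rank_entities(q, model, top_n=top_entities)
        path = Path(str(out_prefix) + ".entities.tsv")
        pd.DataFrame(ranked.to_rows(), columns=["rank", "entity_id", "cosine"]).to_csv(
            path, sep="\t", index=False
        )
        written.append(path)
    if entities:
        q = make_entity_query(entities, model)
        ranked = rank_terms(q, model, top_n=top_terms)
        path = Path(str(out_prefix) + ".terms.tsv")
        pd.DataFrame(ranked.to_rows(), columns=["rank", "term", "cosine"]).to_csv(
            path, sep="\t", index=False
        )
        written.append(path)
    if not written:
        raise QueryError("provide query terms and/or entities")
    return written


def run_evaluate(
    config: PipelineConfig, model_dir: str | Path, out_path: str | Path
) -> pd.DataFrame:
    """Per-category evaluation report.

    For each gold-standard category: AUC of the term query (category name)
    against member entities; AUC of the entity query (members) against the
    category's constituent terms within the top-ranked term list; cohesion
    with the shared-citation co-occurrence baseline and a rank-sum p-value.
    Categories with fewer than two members in the model are reported without
    a cohesion (flagged).
    """
    model = load_model(model_dir)
    gold = eval_mod.read_gold_standard_tsv(config.gold_standard)
    cmap = corpus_mod.read_entity_map_tsv(config.entity_map)
    stoplist = _load_stoplist(config)
    model_entities = set(model.entity_ids)

    rows = []
    for category, members in sorted(gold.categories.items()):
        in_model = members & model_entities
        flags = []
        if len(in_model) < len(members):
            flags.append("members_missing_from_model")

        t2e_auc = np.nan
        try:
            q = make_term_query([category], model, stoplist)
            if in_model:
                t2e_auc = eval_mod.roc_auc(rank_entities(q, model), in_model)
        except QueryError:
            flags.append("no_query_term_in_vocabulary")

        e2t_auc = np.nan
        if in_model:
            qe = make_entity_query(sorted(in_model), model)
            top = rank_terms(qe, model, top_n=config.top_terms)
            name_terms = set(tokenize(category, stoplist))
            if name_terms & set(top.ids):
                e2t_auc = eval_mod.roc_auc(top, name_terms & set(top.ids))
            else:
                flags.append("no_category_term_in_top_ranked")

        coh = base = pval = np.nan
        direction = ""
        if len(in_model) >= 2:
            res = eval_mod.cohesion(in_model, model)
            baseline = eval_mod.cooccurrence_cohesion(
                in_model, cmap, universe=model_entities & set(cmap.entities())
            )
            coh, base = res.cohesion, baseline.cohesion
            pval, direction = eval_mod.compare_cohesions(res.aucs, baseline.aucs)
        else:
            flags.append("too_few_members_for_cohesion")
            logger.warning("category %r: <2 members in model, cohesion skipped", category)

        rows.append(
            {
                "category": category,
                "n_members": len(members),
                "n_in_model": len(in_model),
                "term_to_entity_auc": t2e_auc,
                "entity_to_term_auc": e2t_auc,
                "cohesion": coh,
                "cooccurrence_cohesion": base,
                "ranksum_p": pval,
                "direction": direction,
                "flags": ";".join(flags),
            }
        )
    report = pd.DataFrame(rows)
    Path(out_path).parent.mkdir(parents=True, exist_ok=True)
    report.to_csv(out_path, sep="\t", index=False)
    return report


def run_network(
    config: PipelineConfig, model_dir: str | Path, out_dir: str | Path
) -> dict:
    """Cosine graph at the configured percentile; cluster and annotate the
    largest connected component."""
    model = load_model(model_dir)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    cosines = pairwise_cosines(model)
    threshold = net_mod.percentile_threshold(cosines, config.percentile)
    graph = net_mod.build_graph(cosines, model.entity_ids, threshold)
    component = net_mod.largest_connected_component(graph)
    k_clusters = min(config.k_clusters, len(component))
    clusters = net_mod.cluster_component(component, model, k_clusters, seed=config.seed)
    annotations = net_mod.annotate_clusters(clusters, model, top_n=config.top_terms)
    connectivity = net_mod.cluster_connectivity(clusters, graph)

    net_mod.write_edge_list(graph, out_dir / "edges.tsv")
    net_mod.write_clusters(clusters, out_dir / "clusters.tsv")
    net_mod.write_annotations(annotations, out_dir / "annotations.tsv")
    import networkx as nx

    nx.write_graphml(graph, out_dir / "graph.graphml")

    summary = {
        "threshold": threshold,
        "percentile": config.percentile,
        "n_entities": len(model.entity_ids),
        "n_edges": graph.number_of_edges(),
        "component_size": len(component),
        "k_clusters": k_clusters,
        "clusters_connected": {str(c): bool(v) for c, v in connectivity.items()},
    }
    (out_dir / "network.json").write_text(json.dumps(summary, indent=1))
    return summary


def run_simulate(
    out_dir: str | Path, config: SyntheticCorpusConfig | None = None
) -> tuple[Path, Path, Path]:
    """Generate a planted-topic corpus and write it in the pipeline's input
    formats (citations.tsv, entity_map.tsv, labels.tsv)."""
    config = config or SyntheticCorpusConfig()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    citations, cmap, labels = generate_synthetic_corpus(config)
    cit_path = out_dir / "citations.tsv"
    map_path = out_dir / "entity_map.tsv"
    lab_path = out_dir / "labels.tsv"
    corpus_mod.write_citations_tsv(citations, cit_path)
    corpus_mod.write_entity_map_tsv(cmap, map_path)
    pd.DataFrame(sorted(labels.items()), columns=["entity_id", "topic"]).to_csv(
        lab_path, sep="\t", index=False
    )
    return cit_path, map_path, lab_path
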