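# Methods

## Model

The package implements a vector-space retrieval model over an
entity-centric literature collection. Each entity's document is the
concatenation of the titles and abstracts of its linked citations; the
term-by-entity count matrix is log-entropy weighted and factorized by SVD;
all downstream operations (ranking, cohesion, graph clustering) are cosine
comparisons between rows of the truncated, singular-value-scaled factor
matrices. The modelling assumptions are the usual bag-of-words ones: word
order, negation and sentence structure carry no signal, and an entity's
literature is treated as a single exchangeable pool of terms.

### Corpus assembly

* **Synonym expansion.** Entity symbols are split into a base token and a
  suffix and crossed over the base spellings {mir, miR, microRNA} × {with,
  without hyphen}. The set of base spellings is configurable because
  real usage is open-ended; the expansion is always closed under hyphen
  stripping so that retrieval queries cover both written forms.
* **Nonspecific-citation filter.** The number of entities linked to each
  citation is summarized by its quartiles; the removal threshold is the
  smallest observed count strictly above Q3 + 1.5·IQR, and every citation
  linked to **at least** that many entities is removed (the fence is
  strict, the removal rule inclusive). Quartiles use linear interpolation
  between order statistics (numpy's default), configurable via the
  `quantile_method` argument. If no count exceeds the fence the filter is a
  no-op (`None` sentinel). Entities left without citations are dropped;
  only "active" entities become matrix columns.
* **Concatenation.** Contributing citations are ordered by ascending
  citation ID and the non-empty of (title, abstract) are joined by single
  spaces. Neither the order nor the separator affects a bag-of-words
  model; both are fixed purely for byte-level reproducibility.

### Tokenization

Lowercase; every punctuation character except hyphen and underscore is
replaced by a token boundary (deletion would fuse unrelated words such as
"p53/MDM2"); stop-list members and tokens without any alphanumeric
character are dropped; multiplicity and order are preserved. No stemming is
applied. Numeric-only tokens are retained by default (`keep_numeric=False`
drops them). The bundled stop list is a small generic English list written
for this package; any plain-text list (one word per line, `#` comments) can
be supplied instead. A document that tokenizes to nothing is dropped with a
warning so that every matrix column has at least one nonzero; an all-empty
collection is an error.

### Weighting

a_ij = log2(1 + f_ij) · g_i with g_i = 1 + Σ_j p_ij log2 p_ij / log2 n.
Conventions made explicit: 0·log 0 = 0; for a single-document corpus
(n = 1) the denominator vanishes and g is defined as 1. g is computed from
the sparse structure only (zero entries contribute nothing); tests assert
agreement with a dense brute-force evaluation to 1e-12. Note that a term
occurring uniformly in every document has g = 0, so its whole weighted row
is zero even where counts are positive; the stored sparsity pattern still
matches the raw counts because explicit zeros are kept.

### Factorization and rank selection

The weighted matrix is decomposed with a dense LAPACK SVD when the smaller
dimension is at most 1500 (exact, and faster at these sizes), and with the
sparse Lanczos solver (`scipy.sparse.linalg.svds`) above that. Singular
values below 1e-10·σ₁ are treated as numerical zeros and excluded from the
contribution vector. The truncation rank is k = round(E·r) (banker's
rounding), clamped to [1, r]; with fewer than two effective dimensions the
entropy is undefined and k = 1. The normalized entropy is computed in
natural logs — the base cancels between numerator and the log r normalizer.
Sign ambiguity of the SVD is fixed by making the largest-magnitude
component of each left singular vector positive; cosines are unaffected but
serialized models become bit-reproducible. The transposed reading of the
factorization (A′ = V S U′) is the same decomposition with the roles of the
two factor matrices exchanged; no second decomposition is performed.

### Queries and ranking

A term query is the binary indicator q₀ over the vocabulary projected as
q₀′U_k (duplicate query words count once; multiword queries run through the
corpus tokenizer, so stop-words in phrases are dropped; unmatched words are
reported and an all-miss query is an error). Entities are ranked by cosine
against rows of V_k·S_k. The entity-query direction has no published
projection formula; by the symmetry of the factorization this package sums
the **unscaled** V_k rows of the queried entities, mirroring q₀′U_k on the
term side, and ranks terms against rows of U_k·S_k. (Summing scaled V·S_k
rows is the plausible alternative; it changes the weighting of
multi-entity queries but not single-entity ones, since cosine is
scale-invariant.) Ties in every ranking break lexicographically by ID.
Term rankings are truncated to a configurable top-n, default 300; entity
rankings default to top 50 in the pipeline outputs. Objects with no signal
in the retained factors (zero vectors) receive score 0 and are flagged by
the normalization helper rather than producing NaNs.

### Evaluation statistics

* **AUC** uses the Mann–Whitney rank-sum identity with average ranks, so
  tied scores contribute half a pair; a position-ordered ID list (no
  scores) is treated as tie-free. Both inputs are supported because
  gold-standard rankings may arrive either way.
* **Cohesion** of an entity set: each member in turn is the query, the
  universe minus that member is ranked by cosine to it, the remaining
  members are the positives, and the median of the per-member AUCs is the
  cohesion. The query member is excluded from its own ranked universe —
  including it would add a guaranteed top positive and inflate every AUC.
  The ranking universe is an explicit parameter (defaults to all model
  entities) because evaluation universes differ between gold standards.
* **Co-occurrence baseline**: entity-entity similarity as the number of
  shared citations; cohesion under this similarity uses the identical
  leave-one-out machinery, so the comparison isolates the similarity
  measure. The per-member AUC lists are compared with a two-sided
  Mann–Whitney/rank-sum test (exact for small tie-free samples,
  tie-corrected normal approximation otherwise).
* **Information gain** (retrieved − curated)/curated and **recall**
  |retrieved ∩ curated|/|curated| summarize corpus construction; gain is
  undefined (error) when no curated citations exist.

### Network clustering

The entity cosine matrix is thresholded at a percentile (default 99) of
the off-diagonal values, each unordered pair counted once, with linear
interpolation; edges require cosine **strictly** above the threshold.
The largest connected component (ties broken toward the component with the
lexicographically smallest member) is clustered by standard k-means on the
unit-normalized scaled entity vectors, with a fixed seed and 10 restarts.
A graph-aware k-means variant could be substituted here; standard k-means
on the LSI embedding is used because the embedding already encodes the
similarity the graph is built from. Whether each cluster's induced
subgraph is connected is reported, not enforced. Cluster annotation is an
all-members entity query followed by a top-n term ranking (default 300).

## Synthetic corpus

The generator emulates the structural features the pipeline depends on:
entities partitioned into topics (default 5 topics × 10 entities), short
title+abstract citations (titles of 8 words; abstract lengths Poisson with
mean 60, floored at 10), a per-topic vocabulary of 40 words and a shared
background vocabulary of 200 words, with each word drawn from the entity's
topic vocabulary with probability 0.6 and from the background otherwise.
Six citations per entity put the corpus in the low-citation regime typical
of entity-literature collections while keeping every stage well
conditioned. Optional "screen-like" citations (background-only text linked
to many entities across topics) exercise the nonspecific-citation filter.

What it does **not** emulate: Zipfian word frequencies, synonymy and
polysemy, entities belonging to several topics, citation growth over time,
and any correlation between entities beyond topic membership. Passing the
parameter-recovery tests therefore shows that the pipeline recovers clean
planted structure, not that it attains any particular accuracy on real
literature, where topic overlap and vocabulary ambiguity lower all scores.

## Numerical choices

* quartiles and percentiles: linear interpolation (numpy default),
  configurable where the choice is user-visible;
* k rounding: banker's rounding of E·r, clamped to [1, r];
* rank tolerance: singular values below 1e-10·σ₁ excluded from
  contributions;
* cosines clipped to [−1, 1] against floating-point drift; the pairwise
  matrix is symmetrized and its diagonal set to exactly 1;
* degenerate inputs: empty corpora, all-zero rows/spectra, singleton
  cohesion sets and empty query projections raise errors naming the cause;
  zero vectors in rankings score 0 rather than erroring, since they are a
  legitimate outcome of truncation.

## Limitations

Bag-of-words semantics (no negation handling — an abstract explicitly
denying an association still links its terms), no stemming or phrase
detection, English-centric tokenization, and an entity-query projection
chosen by symmetry rather than by a published formula. The entropy rank
rule is one of several reasonable strategies and is not claimed optimal.
Live literature retrieval is out of scope: the retrieval interface is
defined, and the package ships only a file-backed implementation.
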