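# Methods

## Problem setting

A variable codebook (data dictionary) lists each variable of a study
dataset with an identifier and a short free-text description. In
longitudinal cohort studies the same measurement recurs across waves,
often under identifiers differing only in letter case, and the
descriptions are the only semantic handle a curator has. `semharm`
treats harmonisation as three successive problems: lexical identifier
deduplication, semantic retrieval of domain-relevant variables, and
unsupervised grouping of semantically similar variables — each with an
explicit, quantitative validation protocol.

## Identifier harmonisation

Records are grouped by the Unicode casefold of their identifier
(`str.casefold`, not plain lowercasing, so non-ASCII identifiers merge
correctly). The canonical record of each group is the first occurrence
in input order; all merged records are retained in a merge map, so the
operation conserves records and is idempotent. Which duplicate supplies
the canonical description is a convention — the members of a casefold
group may in principle carry different descriptions; resolving such
conflicts semantically is the clustering pipeline's job, not this
step's. Descriptions play no role in identifier harmonisation.

## Embeddings

All downstream computation sees only an n × d matrix of unit rows
aligned to variable identifiers. Because rows are L2-normalised, cosine
similarity is the dot product and cosine distance is 1 − similarity
(range [0, 2]).

Two backend families satisfy the contract:

- **Builtin n-gram TF-IDF.** The vocabulary is the `dimension` most
  frequent character n-grams (default range 3–5) of the fitting corpus,
  with a deterministic tie-break (frequency descending, then
  lexicographic), weighted by sublinear term frequency × smoothed
  inverse document frequency and L2-normalised. Character n-grams are
  robust to the inflection and truncation typical of codebook prose,
  and fitting is bit-reproducible — no downloads, no GPU. The default
  `dimension` of 384 matches the output width of the small sentence
  encoders commonly used for this task, so persisted artefacts are
  interchangeable.
- **External sentence encoders.** Pretrained transformer encoders
  register by name through `register_backend`; the contract is texts in,
  fixed-width matrix out. The package neither trains nor re-implements
  them.

Empty descriptions embed to a flagged zero row. A zero vector has no
direction, so its similarity to anything is defined as 0 (distance 1,
the uninformative midpoint) and a warning is emitted.

Pairwise distance-distribution summaries (mean, SD over all unordered
pairs) switch to a seeded uniform subsample above `max_pairs` (default
10⁶): full enumeration over a realistically sized codebook is hundreds
of millions of pairs, which is wasteful when only two moments are
reported.

## Semantic search

The query phrase is embedded by the same fitted backend that produced
the variable matrix (verified through stored metadata — scoring against
a matrix from a different corpus or backend is refused). Every variable
is scored by dot product; the top N are returned with ties broken by
identifier ascending so repeated runs give identical lists. Top-N
selection, not similarity thresholding, is the primary mode: different
embedding backends occupy differently scaled regions of distance space,
so a fixed threshold does not transfer between them.

Retrieval is evaluated per validation domain with ROC-AUC, computed as
the Mann–Whitney statistic with midrank tie correction — equivalent to
the probability that a random positive outscores a random negative,
counting ties half. Positives are the domain's labelled variables;
negatives are *all* other labelled variables, including those labelled
NONE (matching no domain) — a real query competes against the whole
codebook, so unlabelled-but-present variables belong in the negative
pool. Domains without positives are skipped with a warning. The mean
and SD across domains use the population SD (ddof = 0), so a
single-domain evaluation reports SD 0.

## Semantic clustering

The pipeline is reduction → clustering → silhouette selection:

- **Reduction**: identity, PCA, or UMAP, over a target-dimension grid
  (default {10, 50, 100, 200, 300}); UMAP is seeded for deterministic
  output. Delegated to scikit-learn and umap-learn.
- **Clusterers**: K-means (Lloyd iterations, seeded initialisation,
  fixed k), hierarchical agglomerative clustering (distance-threshold
  cut; average linkage on cosine distance by default, both
  configurable — the metric question is genuinely open, since a
  threshold tuned on cosine distances is meaningless in a Euclidean
  UMAP space), and HDBSCAN (`min_cluster_size`, `min_samples`), which
  may label points NOISE. Delegated to scikit-learn.
- **Silhouette** is implemented here from its definition: s(i) =
  (b(i) − a(i))/max(a(i), b(i)), mean over points, with singleton
  clusters contributing 0 and NOISE points excluded. It is computed in
  the *reduced* space with the Euclidean metric: model selection must
  score the representation the clusterer actually saw. Configurations
  with fewer than two clusters after noise removal receive a sentinel
  of −1: they stay in the grid report but can never beat a valid
  configuration.
- **Selection** takes the maximal silhouette over the full
  (reduction × clusterer) grid, with ties broken by fewer dimensions,
  then fewer allocated clusters, then grid order. Allocated-cluster
  counts exclude NOISE. The default HDBSCAN minimum-cluster-size sweep
  is {5, 10, …, 65} (13 values), overridable in the grid config.

## External validation

Homogeneity, completeness and the V-measure are computed from the
entropies of the cluster × domain contingency table (natural log; the
base cancels in the ratios; β = 1, the plain harmonic mean). NOISE and
NONE items are excluded from the table and reported as exclusion
counts, so incomplete clustering is not penalised.

Because the number of clusters is arbitrary while the domains are
fixed, matching is pairwise: for each (cluster, domain) pair the
memberships are binarised over the evaluated universe and the V-measure
of the 2 × 2 table computed; each domain is assigned the cluster
maximising this value, and the mean of the per-domain maxima is the
mean-max V-measure (MMV), reported with its population SD and the
argmax cluster per domain. Averaging runs over domains (not clusters):
the statistic answers "how well is each domain of interest recovered?",
which is the curator's question.

## Synthetic study conditions

The generator provides labelled codebooks with the statistical shape
the pipelines assume, in two channels, because the builtin n-gram
embedder's geometry need not mimic a transformer's:

- **Text channel** (search pipeline): up to 12 domains with disjoint
  themed keyword pools; each variable description samples 3–5 keywords
  from its domain's pool, filler (NONE) variables sample from a neutral
  administrivia pool, and each domain's search phrase is its full pool.
  This makes domains lexically separable by construction — the point is
  a known-answer test of the retrieval machinery, not a simulation of
  encoder semantics.
- **Planted-geometry channel** (clustering pipeline): domain centroids
  are rejection-sampled on the unit sphere with pairwise angular
  separation ≥ `min_centroid_separation` (default 0.5 rad; 10,000
  attempts, failure explicit), members are centroid plus isotropic
  Gaussian noise of scale `within_domain_sigma` re-normalised, NONE
  variables are uniform on the sphere.

Default conditions: 12 domains × 40 variables, 13.6% unlabelled (the
share of a typical manually-labelled validation sample that matches no
domain), duplicate rate 0.2 (a fifth of base variables re-issued in a
different wave under a case-mutated identifier), 9 waves, embedding
dimension 64, σ = 0.05. Optional per-domain weights allow the skewed
domain sizes seen in real validation sets. Everything is determined by
a single seed.

What passing tests on these conditions show — and what they do not:
they verify the machinery (ranking, metrics, selection, bookkeeping) on
constructions with known answers. They do not show that any particular
pretrained encoder separates real clinical codebook domains; that
depends on the encoder and corpus and must be evaluated per deployment
with the same `evaluate_search`/`mean_max_v_measure` protocol.

## Numerical choices

- Unit-norm tolerance 1e−9; similarity clipped to [−1, 1] against
  floating-point drift.
- Ranking ties broken by identifier; grid ties by (dimensions,
  clusters, order); vocabulary ties by (frequency, lexicographic) — all
  total orders, so every stage is deterministic under a fixed seed.
- K-means uses 10 seeded initialisations; UMAP/PCA/HDBSCAN are run with
  fixed seeds or are deterministic by nature.
- SDs are population SDs throughout (ddof = 0).
- JSON reports round floats to 10 digits and sort keys, so identical
  runs produce byte-identical files.
- Problem sizes in the test suite and acceptance script (hundreds of
  variables, 5–12 domains) are chosen so known-answer structure is
  unambiguous while the full suite runs in about a minute.

## Known limitations

- The builtin embedder is lexical: it cannot match synonyms that share
  no character n-grams, so its retrieval quality on real codebooks is a
  floor, not an estimate, of what a sentence encoder achieves.
- The text channel supports at most the 12 shipped keyword pools; use
  the planted-geometry channel for larger domain counts.
- HAC with a cosine-distance threshold in a UMAP-reduced Euclidean
  space is a metric mismatch waiting to happen; the package exposes the
  linkage/metric knobs rather than guessing.
- MMV uses one-vs-rest binarisation per (cluster, domain) pair; other
  pairing schemes (e.g. restricting the multi-class V-measure to one
  domain's items) would yield different absolute values and are not
  implemented.
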