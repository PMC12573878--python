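# semharm

Semantics-aware harmonisation of study variable codebooks: search a data
dictionary for domain-relevant variables by meaning rather than keywords,
and group semantically similar variables into domains with unsupervised
clustering — with the validation machinery (per-domain ROC-AUC,
silhouette-driven model selection, V-measure domain matching) needed to
measure how well either pipeline works.

## Who this is for

Observational studies built on large cohort databases (ELSA-style
longitudinal surveys, routine healthcare records) start from codebooks of
tens of thousands of free-text variable descriptions, with the same
quantity re-collected every wave under inconsistently cased identifiers.
Curating such a codebook by hand takes weeks. `semharm` automates the
three steps a data curator performs:

1. **Identifier harmonisation** — merge variables whose identifiers match
   case-insensitively (Unicode casefold), keeping a complete merge map.
2. **Semantic search** — embed every variable description once, embed a
   free-text query phrase, rank all variables by cosine similarity and
   return the top *N*.
3. **Semantic clustering** — reduce the embedding space (PCA/UMAP),
   cluster (K-means, hierarchical agglomerative, HDBSCAN) over a
   configuration grid, and select the best configuration by silhouette.

## The statistics at the core

Embeddings are L2-normalised, so cosine similarity is a dot product and
*cosine distance = 1 − cosine similarity*.

- **ROC-AUC** for search evaluation is the Mann–Whitney rank statistic
  with midrank tie correction: P(s⁺ > s⁻) + ½·P(s⁺ = s⁻) over all
  positive/negative score pairs, so the measure is independent of any
  similarity threshold.
- **Silhouette**: s(i) = (b(i) − a(i)) / max(a(i), b(i)), where a(i) is
  the mean distance from point i to its own cluster and b(i) the smallest
  mean distance to another cluster; computed in the reduced space with
  the Euclidean metric, noise points excluded.
- **V-measure**: harmonic mean of homogeneity
  h = 1 − H(class|cluster)/H(class) and completeness
  c = 1 − H(cluster|class)/H(cluster), from contingency-table entropies.
- **Mean-max V-measure (MMV)**: an unsupervised clustering rarely has as
  many clusters as there are validation domains, so each domain is
  matched to the cluster maximising the one-vs-rest V-measure, and those
  per-domain maxima are averaged. Unclustered (NOISE) and unlabelled
  (NONE) variables are excluded, so incomplete clustering is not
  penalised.

Pretrained sentence encoders attach through a backend-plugin contract;
the package ships a deterministic corpus-fitted character n-gram TF-IDF
embedder so everything runs and is testable without model downloads. A
seeded synthetic codebook generator provides labelled test conditions:
themed keyword descriptions per domain, a configurable share of
variables matching no domain, case-duplicate identifiers across waves,
and planted embedding geometry for the clustering pipeline.

## Worked example

```python
import semharm as sh

spec = sh.SyntheticSpec(seed=1)          # 12 domains, 13.6% unlabelled
sc = sh.generate_codebook(spec)

hcb = sh.harmonise_identifiers(sc.codebook)
print(f"{len(sc.codebook)} records -> {len(hcb)} unique identifiers")

embedder = sh.fit_builtin_embedder(sc.codebook.descriptions,
                                   sh.EmbedderSpec(dimension=384, seed=1))
E = sh.embed_descriptions(embedder, sc.codebook.descriptions,
                          sc.codebook.identifiers)

hits = sh.rank_variables(E, embedder,
                         sh.SearchQuery("medication tablets dosage", top_n=3))
for ident, sim in hits.hits:
    print(f"{ident}\t{sim:.3f}")

ev = sh.evaluate_search(E, embedder, sc.phrases, sc.truth)
print(f"mean AUC {ev.mean_auc:.3f} (SD {ev.sd_auc:.3f}) "
      f"over {len(ev.per_domain_auc)} domains")
```

prints

```
667 records -> 556 unique identifiers
Me06v0003	0.778
Me06v0039	0.726
Me06V0029	0.724
mean AUC 0.999 (SD 0.001) over 12 domains
```

The codebook shrinks from 667 records to 556 unique variables because a
fifth of the base variables were re-issued in later waves under
case-mutated identifiers (note the third hit, `Me06V0029`, is one such
case variant). All three top hits come from the medication domain, and
retrieval over all 12 domains is near perfect because the synthetic
domains are lexically separable by construction.

The clustering pipeline on planted 5-domain geometry:

```python
cspec = sh.SyntheticSpec(n_domains=5, vars_per_domain=50,
                         unlabeled_fraction=0.0, duplicate_rate=0.0,
                         embedding_dim=50, within_domain_sigma=0.01, seed=1)
csc = sh.generate_codebook(cspec)
P = sh.generate_planted_embeddings(cspec, csc.truth)
grid = sh.select_best_configuration(
    P, [sh.ReductionConfig(method="identity")],
    [sh.ClustererConfig(algorithm="kmeans", k=k, seed=0) for k in (2, 5, 20)]
    + [sh.ClustererConfig(algorithm="hdbscan", min_cluster_size=20,
                          min_samples=20)])
sel = grid.selected
print(f"selected {sel.clusterer.describe()}: {sel.n_clusters} clusters, "
      f"silhouette {sel.silhouette:.3f}")
rep = sh.mean_max_v_measure(sel.assignment, csc.truth)
print(f"MMV {rep.mmv:.3f} (SD {rep.sd:.3f})")
```

prints

```
selected kmeans(k=5): 5 clusters, silhouette 0.924
MMV 1.000 (SD 0.000)
```

The silhouette maximum lands on exactly the planted number of clusters
and every domain is matched to its own cluster (MMV = 1).

A command-line interface mirrors the library
(`semharm synth | ingest | embed | search | evaluate-search | cluster |
evaluate-clustering | grid`); run `semharm --help` for details.

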