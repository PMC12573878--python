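"""Shared fixtures: synthetic study conditions used across the suite."""

import numpy as np
import pytest

import semharm as sh


@pytest.fixture(scope="session")
def default_synthetic():
    """Default synthetic text codebook: 12 domains, 13.6% unlabelled."""
    return sh.generate_codebook(sh.SyntheticSpec(seed=11))


@pytest.fixture(scope="session")
def default_embeddings(default_synthetic):
    """Builtin n-gram embeddings of the default synthetic codebook."""
    sc = default_synthetic
    emb = sh.fit_builtin_embedder(sc.codebook.descriptions,
                                  sh.EmbedderSpec(dimension=384, seed=11))
    E = sh.embed_descriptions(emb, sc.codebook.descriptions,
                              sc.codebook.identifiers)
    return emb, E


@pytest.fixture(scope="session")
def planted_five_domains():
    """Planted-geometry conditions: 5 tight, well-separated domains."""
    spec = sh.SyntheticSpec(n_domains=5, vars_per_domain=50,
                            unlabeled_fraction=0.0, duplicate_rate=0.0,
                            embedding_dim=50, within_domain_sigma=0.01,
                            seed=29)
    sc = sh.generate_codebook(spec)
    E = sh.generate_planted_embeddings(spec, sc.truth)
    return spec, sc, E


def table_to_labels(table):
    """Expand a cluster x class count table into aligned label arrays."""
    clusters, classes = [], []
    for i, row in enumerate(table):
        for j, n in enumerate(row):
            clusters.extend([i] * int(n))
            classes.extend([j] * int(n))
    return np.array(clusters), np.array(classes)
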