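"""Semantic search for domain-relevant variables, and its evaluation.

A query phrase is embedded with the same backend that produced the
variable-description embeddings; every variable is scored by cosine
similarity and the top N are returned.  Retrieval quality per validation
domain is measured threshold-free with ROC-AUC: positives are the
variables labelled with the domain, negatives are every other labelled
variable (including those matching no domain at all).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import rankdata

from .embedding import Embedder, EmbeddingMatrix
from .labels import NONE, DomainLabelSet

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SearchQuery:
    phrase: str
    top_n: int = 50

    def __post_init__(self) -> None:
        if self.top_n < 0:
            raise ValueError("top_n must be >= 0")
        if self.top_n > 0 and not self.phrase.strip():
            raise ValueError("query phrase must be non-empty when top_n > 0")


@dataclass(frozen=True)
class RankedResults:
    """Hits ordered by similarity descending, ties broken by identifier."""

    hits: tuple[tuple[str, float], ...]

    def __post_init__(self) -> None:
        for (i1, s1), (i2, s2) in zip(self.hits, self.hits[1:]):
            if s1 < s2 or (s1 == s2 and i1 >= i2):
                raise ValueError("hits are not in (similarity desc, id asc) order")

    @property
    def identifiers(self) -> tuple[str, ...]:
        return tuple(i for i, _ in self.hits)


@dataclass(frozen=True)
class SearchEvaluation:
    per_domain_auc: Mapping[str, float]
    mean_auc: float
    sd_auc: float
    phrases: Mapping[str, str]
    skipped_domains: tuple[str, ...] = ()


def _check_compatible(E: EmbeddingMatrix, embedder: Embedder) -> None:
    em = dict(embedder.metadata)
    mm = dict(E.metadata)
    for key in ("backend", "corpus_digest", "vocabulary_size", "dimension"):
        if key in em and key in mm and em[key] != mm[key]:
            raise ValueError(
                f"embedding matrix was not produced by this embedder "
                f"(metadata {key!r}: {mm[key]!r} != {em[key]!r})"
            )


def score_variables(E: EmbeddingMatrix, embedder: Embedder,
                    phrase: str) -> np.ndarray:
    """Cosine similarity of every variable embedding to the phrase embedding."""
    _check_compatible(E, embedder)
    q = np.asarray(embedder.transform([phrase]), dtype=np.float64)[0]
    nq = np.linalg.norm(q)
    if nq < 1e-9:
        warnings.warn(f"phrase {phrase!r} embeds to the zero vector; "
                      "all similarities are 0", RuntimeWarning, stacklevel=2)
        return np.zeros(E.n)
    q = q / nq
    sims = E.vectors @ q
    return np.clip(sims, -1.0, 1.0)


def rank_variables(E: EmbeddingMatrix, embedder: Embedder,
                   query: SearchQuery) -> RankedResults:
    """Return the top-N variables by similarity to the query phrase."""
    if query.top_n == 0:
        return RankedResults(())
    sims = score_variables(E, embedder, query.phrase)
    order = sorted(range(E.n), key=lambda i: (-sims[i], E.identifiers[i]))
    k = min(query.top_n, E.n)
    return RankedResults(tuple((E.identifiers[i], float(sims[i]))
                               for i in order[:k]))


def compute_auc(scored: Sequence[tuple[float, bool]]) -> float:
    """Area under the ROC curve via the Mann-Whitney rank statistic.

    Equals P(score_pos > score_neg) + 0.5 P(score_pos == score_neg),
    with midrank tie correction.
    """
    scores = np.array([s for s, _ in scored], dtype=np.float64)
    pos = np.array([bool(p) for _, p in scored])
    n_pos = int(pos.sum())
    n_neg = int((~pos).sum())
    if n_pos == 0:
        raise ValueError("AUC undefined: no positive examples")
    if n_neg == 0:
        raise ValueError("AUC undefined: no negative examples")
    ranks = rankdata(scores, method="average")
    u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def evaluate_search(E: EmbeddingMatrix, embedder: Embedder,
                    phrases: Mapping[str, str],
                    labels: DomainLabelSet) -> SearchEvaluation:
    """Per-domain retrieval AUC for one search phrase per domain.

    The evaluation universe is the labelled set: for each domain its
    members are positives and every other labelled variable — including
    NONE-labelled ones — is a negative.  Domains with no positives are
    skipped with a warning and excluded from the mean/SD.
    """
    labels.validate_against(E.identifiers)
    idx = {ident: i for i, ident in enumerate(E.identifiers)}
    eval_ids = list(labels.labels)
    per_domain: dict[str, float] = {}
    skipped: list[str] = []
    for domain, phrase in phrases.items():
        positives = {i for i, d in labels.labels.items() if d == domain}
        if not positives:
            logger.warning("domain %r has no positive examples; skipped", domain)
            skipped.append(domain)
            continue
        sims = score_variables(E, embedder, phrase)
        scored = [(float(sims[idx[i]]), i in positives) for i in eval_ids]
        per_domain[domain] = compute_auc(scored)
    if not per_domain:
        raise ValueError("no domain could be evaluated (all lacked positives)")
    vals = np.array(list(per_domain.values()))
    return SearchEvaluation(
        per_domain_auc=per_domain,
        mean_auc=float(vals.mean()),
        sd_auc=float(vals.std(ddof=0)),
        phrases=dict(phrases),
        skipped_domains=tuple(skipped),
    )
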