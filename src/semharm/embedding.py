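"""Unit-normalised description embeddings and cosine geometry.

Two backend families sit behind one contract: a deterministic,
corpus-fitted character n-gram TF-IDF embedder that ships with the
package, and pluggable external sentence encoders (registered by name)
for users with pretrained transformer models available.  Everything
downstream — search, clustering, the distance summaries — sees only a
matrix of unit rows, so the two families are interchangeable.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
from sklearn.feature_extraction.text import TfidfVectorizer

logger = logging.getLogger(__name__)

_NORM_TOL = 1e-9

BUILTIN_BACKEND = "builtin-ngram"

#: Registry of external embedding backends: name -> factory(spec) -> embedder.
_BACKEND_REGISTRY: dict[str, Callable[["EmbedderSpec"], "Embedder"]] = {}


def register_backend(name: str,
                     factory: Callable[["EmbedderSpec"], "Embedder"]) -> None:
    """Register an external sentence-encoder backend under ``name``."""
    _BACKEND_REGISTRY[name] = factory


@dataclass(frozen=True)
class EmbedderSpec:
    """Configuration of an embedding backend.

    ``dimension`` is the output vector size (384 matches the common
    MiniLM sentence encoder; for the builtin backend it caps the n-gram
    vocabulary).  ``ngram_range`` applies to the builtin backend only.
    """

    backend: str = BUILTIN_BACKEND
    dimension: int = 384
    seed: int = 0
    ngram_range: tuple[int, int] = (3, 5)

    def __post_init__(self) -> None:
        if self.dimension < 2:
            raise ValueError("embedding dimension must be >= 2")
        lo, hi = self.ngram_range
        if lo < 1 or hi < lo:
            raise ValueError(f"invalid ngram_range {self.ngram_range}")


class Embedder:
    """Minimal contract every backend satisfies."""

    spec: EmbedderSpec

    @property
    def metadata(self) -> dict:  # pragma: no cover - interface
        raise NotImplementedError

    def transform(self, texts: Sequence[str]) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class NgramTfidfEmbedder(Embedder):
    """Deterministic corpus-fitted character n-gram TF-IDF embedder.

    The vocabulary is the ``dimension`` most frequent character n-grams
    of the fitting corpus, ties broken by frequency descending then
    lexicographic order, so fitting is bit-reproducible.  Term weighting
    is sublinear TF x smoothed IDF and every output row is
    L2-normalised (empty texts give a zero row).
    """

    def __init__(self, spec: EmbedderSpec, vocabulary: Sequence[str],
                 vectorizer: TfidfVectorizer, corpus_digest: str) -> None:
        self.spec = spec
        self.vocabulary = tuple(vocabulary)
        self._vectorizer = vectorizer
        self._corpus_digest = corpus_digest

    @property
    def metadata(self) -> dict:
        return {
            "backend": self.spec.backend,
            "dimension": self.spec.dimension,
            "vocabulary_size": len(self.vocabulary),
            "seed": self.spec.seed,
            "ngram_range": list(self.spec.ngram_range),
            "corpus_digest": self._corpus_digest,
        }

    def transform(self, texts: Sequence[str]) -> np.ndarray:
        X = self._vectorizer.transform(list(texts))
        return np.asarray(X.todense(), dtype=np.float64)


def _corpus_ngram_counts(corpus: Sequence[str],
                         ngram_range: tuple[int, int]) -> Counter:
    counts: Counter = Counter()
    lo, hi = ngram_range
    for text in corpus:
        t = text.lower()
        for n in range(lo, hi + 1):
            for i in range(len(t) - n + 1):
                counts[t[i:i + n]] += 1
    return counts


def fit_builtin_embedder(corpus: Iterable[str],
                         spec: EmbedderSpec | None = None) -> NgramTfidfEmbedder:
    """Fit the builtin n-gram TF-IDF embedder on a description corpus."""
    spec = spec or EmbedderSpec()
    corpus = [t.strip() for t in corpus]
    if not corpus:
        raise ValueError("corpus must be non-empty")
    counts = _corpus_ngram_counts(corpus, spec.ngram_range)
    if not counts:
        raise ValueError("corpus contains only empty strings; cannot fit")
    # deterministic vocabulary: frequency descending, then lexicographic
    vocab = [g for g, _ in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))]
    vocab = sorted(vocab[: spec.dimension])
    vectorizer = TfidfVectorizer(
        analyzer="char",
        ngram_range=spec.ngram_range,
        vocabulary=vocab,
        sublinear_tf=True,
        norm="l2",
        lowercase=True,
    )
    vectorizer.fit(corpus)
    digest = hashlib.sha256("\x1f".join(corpus).encode("utf-8")).hexdigest()[:16]
    return NgramTfidfEmbedder(spec, vocab, vectorizer, digest)


def make_embedder(spec: EmbedderSpec, corpus: Iterable[str] | None = None) -> Embedder:
    """Instantiate the backend named in ``spec`` (fitting it if builtin)."""
    if spec.backend == BUILTIN_BACKEND:
        if corpus is None:
            raise ValueError("builtin backend requires a fitting corpus")
        return fit_builtin_embedder(corpus, spec)
    if spec.backend in _BACKEND_REGISTRY:
        return _BACKEND_REGISTRY[spec.backend](spec)
    raise ValueError(
        f"unknown embedding backend {spec.backend!r}; registered: "
        f"{sorted(_BACKEND_REGISTRY) + [BUILTIN_BACKEND]}"
    )


@dataclass(frozen=True)
class EmbeddingMatrix:
    """n x d matrix of unit-normalised description vectors.

    Rows align with ``identifiers``; ``zero_flags`` marks rows that
    could not be embedded (empty or out-of-vocabulary text) and are
    all-zero by convention.
    """

    identifiers: tuple[str, ...]
    vectors: np.ndarray
    zero_flags: np.ndarray
    metadata: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.vectors.ndim != 2:
            raise ValueError("vectors must be a 2-D matrix")
        n = self.vectors.shape[0]
        if len(self.identifiers) != n or len(self.zero_flags) != n:
            raise ValueError("identifiers/flags misaligned with vector rows")
        norms = np.linalg.norm(self.vectors, axis=1)
        ok = self.zero_flags | (np.abs(norms - 1.0) <= _NORM_TOL)
        if not np.all(ok):
            bad = int(np.argmin(ok))
            raise ValueError(
                f"row {bad} ({self.identifiers[bad]!r}) has norm {norms[bad]:.6g}, "
                "expected 1 or zero-flag"
            )

    @property
    def n(self) -> int:
        return self.vectors.shape[0]

    @property
    def dim(self) -> int:
        return self.vectors.shape[1]

    def row(self, identifier: str) -> np.ndarray:
        return self.vectors[self.identifiers.index(identifier)]


def embed_descriptions(embedder: Embedder, texts: Sequence[str],
                       identifiers: Sequence[str] | None = None) -> EmbeddingMatrix:
    """Embed one row per text; empty/unembeddable texts become flagged zero rows."""
    texts = list(texts)
    if identifiers is None:
        identifiers = [str(i) for i in range(len(texts))]
    if len(identifiers) != len(texts):
        raise ValueError("identifiers and texts differ in length")
    V = embedder.transform(texts)
    norms = np.linalg.norm(V, axis=1)
    flags = norms < _NORM_TOL
    if np.any(flags):
        logger.warning("%d text(s) produced zero embeddings (flagged)",
                       int(flags.sum()))
    V = V.copy()
    V[flags] = 0.0
    nz = ~flags
    V[nz] = V[nz] / norms[nz, None]
    return EmbeddingMatrix(tuple(identifiers), V, flags, dict(embedder.metadata))


def cosine_similarity(u: np.ndarray, v: np.ndarray) -> float:
    """Cosine of the angle between two vectors, in [-1, 1].

    Zero vectors get similarity 0 by convention (with a warning), so the
    corresponding distance is 1 — an uninformative midpoint.
    """
    u = np.asarray(u, dtype=np.float64)
    v = np.asarray(v, dtype=np.float64)
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu < _NORM_TOL or nv < _NORM_TOL:
        warnings.warn("cosine similarity of a zero vector defined as 0",
                      RuntimeWarning, stacklevel=2)
        return 0.0
    return float(np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0))


def cosine_distance(u: np.ndarray, v: np.ndarray) -> float:
    """``1 - cosine_similarity``, in [0, 2]."""
    return 1.0 - cosine_similarity(u, v)


@dataclass(frozen=True)
class DistanceSummary:
    """Mean/SD of pairwise cosine distances over an embedding matrix."""

    mean: float
    sd: float
    n_pairs: int
    subsample_seed: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.mean <= 2.0 + 1e-12:
            raise ValueError(f"mean distance {self.mean} outside [0, 2]")
        if self.sd < 0:
            raise ValueError("sd must be non-negative")


def pairwise_distance_summary(E: EmbeddingMatrix, max_pairs: int = 10 ** 6,
                              seed: int = 0) -> DistanceSummary:
    """Summarise the distribution of cosine distances over all unordered
    pairs, or over a seeded uniform subsample when the pair count exceeds
    ``max_pairs``.

    Rows are unit (or zero-flagged), so the pair distance is simply
    ``1 - dot``; flagged rows contribute distance 1 against everything,
    matching the zero-vector convention.
    """
    n = E.n
    if n < 2:
        raise ValueError("need at least 2 rows for a pairwise summary")
    total = n * (n - 1) // 2
    if total <= max_pairs:
        sims = E.vectors @ E.vectors.T
        iu = np.triu_indices(n, k=1)
        d = 1.0 - sims[iu]
        # zero-zero pairs: dot is 0 already -> distance 1, consistent
        return DistanceSummary(float(np.clip(d.mean(), 0, 2)),
                               float(d.std(ddof=0)), total, None)
    rng = np.random.default_rng(seed)
    got = 0
    chunks: list[np.ndarray] = []
    while got < max_pairs:
        m = min(max_pairs - got, 2 ** 18)
        i = rng.integers(0, n, size=2 * m)
        j = rng.integers(0, n, size=2 * m)
        keep = i != j
        i, j = i[keep][:m], j[keep][:m]
        chunks.append(1.0 - np.einsum("ij,ij->i", E.vectors[i], E.vectors[j]))
        got += len(i)
    d = np.concatenate(chunks)[:max_pairs]
    return DistanceSummary(float(np.clip(d.mean(), 0, 2)),
                           float(d.std(ddof=0)), int(len(d)), seed)


def save_embeddings(E: EmbeddingMatrix, prefix: str | Path) -> None:
    """Persist a matrix as ``<prefix>.npy`` + identifier TSV + JSON metadata."""
    prefix = Path(prefix)
    np.save(prefix.with_suffix(".npy"), E.vectors)
    with open(prefix.with_suffix(".ids.tsv"), "w", encoding="utf-8") as fh:
        fh.write("variable\tzero_flag\n")
        for ident, flag in zip(E.identifiers, E.zero_flags):
            fh.write(f"{ident}\t{int(flag)}\n")
    with open(prefix.with_suffix(".meta.json"), "w", encoding="utf-8") as fh:
        json.dump(dict(E.metadata), fh, indent=2, sort_keys=True, default=str)


def load_embeddings(prefix: str | Path) -> EmbeddingMatrix:
    prefix = Path(prefix)
    V = np.load(prefix.with_suffix(".npy"))
    idents: list[str] = []
    flags: list[bool] = []
    with open(prefix.with_suffix(".ids.tsv"), encoding="utf-8") as fh:
        next(fh)
        for line in fh:
            ident, flag = line.rstrip("\n").split("\t")
            idents.append(ident)
            flags.append(bool(int(flag)))
    meta_path = prefix.with_suffix(".meta.json")
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    return EmbeddingMatrix(tuple(idents), V, np.array(flags, dtype=bool), meta)
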