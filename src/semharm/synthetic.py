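"""Synthetic labelled codebooks for end-to-end pipeline testing.

Real cohort data dictionaries cannot be redistributed, so this module
generates codebooks with the same statistical shape: tens of domains of
short English variable descriptions built from themed keyword pools, a
share of filler variables matching no validation domain, and identifier
duplication across waves differing only in letter case.

Two generation channels exist because the two pipelines stress different
things.  The *text* channel emits descriptions for the search pipeline
(the builtin n-gram embedder separates its keyword pools well).  The
*planted-geometry* channel emits unit vectors around well-separated
domain centroids for the clustering pipeline, whose behaviour depends
only on embedding-space geometry, not on any particular encoder.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .codebook import Codebook, VariableRecord
from .embedding import EmbeddingMatrix
from .labels import NONE, DomainLabelSet

#: Themed keyword pools for the 12 default validation domains.  Topics
#: mirror common social-care determinants (finance, housing, activities,
#: services, technology, lifestyle, medication, informal care, holistic
#: care, self-management, daily living, environment); pools are kept
#: lexically disjoint so the text channel has a known separable signal.
DOMAIN_KEYWORD_POOLS: dict[str, tuple[str, ...]] = {
    "finance": ("income", "pension", "savings", "benefit", "insurance",
                "inheritance", "salary", "debt", "investment", "allowance"),
    "housing": ("house", "mortgage", "property", "tenancy", "landlord",
                "dwelling", "accommodation", "rooms", "heating", "rent"),
    "activities": ("hobby", "volunteering", "club", "holiday", "leisure",
                   "cinema", "gardening", "membership", "outing", "crafts"),
    "services": ("nurse", "doctor", "clinic", "appointment", "referral",
                 "hospital", "therapist", "chiropody", "optician", "dentist"),
    "technology": ("computer", "internet", "mobile", "gadget", "television",
                   "email", "website", "alarm", "microwave", "vehicle"),
    "lifestyle": ("diet", "exercise", "alcohol", "smoking", "cigarettes",
                  "vegetables", "walking", "sport", "fruit", "drinking"),
    "medication": ("medication", "drugs", "tablets", "prescription", "dosage",
                   "pills", "pharmacy", "injection", "statin", "painkiller"),
    "informal_care": ("spouse", "relative", "neighbour", "grandchild",
                      "sibling", "carer", "partner", "friend", "family",
                      "daughter"),
    "holistic_care": ("blood", "pressure", "cholesterol", "measurement",
                      "pulse", "weight", "height", "sample", "grip", "lung"),
    "self_management": ("feelings", "emotions", "mood", "worry", "confidence",
                        "loneliness", "happiness", "depression", "anxiety",
                        "coping"),
    "daily_living": ("dressing", "bathing", "cooking", "shopping", "cleaning",
                     "laundry", "stairs", "toileting", "eating", "chores"),
    "environment": ("outdoors", "pollution", "noise", "park", "pavement",
                    "traffic", "litter", "greenspace", "vandalism",
                    "streetlight"),
}

#: Filler pool for variables matching no validation domain — survey
#: administrivia sharing no keyword with any domain pool.
NEUTRAL_POOL: tuple[str, ...] = (
    "serial", "number", "archive", "batch", "session", "timestamp", "proxy",
    "flag", "version", "office", "region", "code", "interviewer", "consent",
    "checksum", "module", "spare", "derived",
)


@dataclass(frozen=True)
class SyntheticSpec:
    """Generation conditions for a synthetic codebook.

    Defaults mirror the shape of a typical manually-labelled validation
    sample: 12 domains, 13.6% of variables matching no domain, a fifth
    of base variables re-issued in a later wave under a case-mutated
    identifier, and 9 collection waves.
    """

    n_domains: int = 12
    vars_per_domain: int = 40
    unlabeled_fraction: float = 0.136
    duplicate_rate: float = 0.2
    n_waves: int = 9
    embedding_dim: int = 64
    within_domain_sigma: float = 0.05
    min_centroid_separation: float = 0.5  # radians
    seed: int = 0
    domain_weights: tuple[float, ...] | None = None  # optional size skew

    def __post_init__(self) -> None:
        if self.n_domains < 1:
            raise ValueError("n_domains must be >= 1")
        if self.vars_per_domain < 1:
            raise ValueError("vars_per_domain must be >= 1")
        if not 0.0 <= self.unlabeled_fraction < 1.0:
            raise ValueError("unlabeled_fraction must lie in [0, 1)")
        if not 0.0 <= self.duplicate_rate < 1.0:
            raise ValueError("duplicate_rate must lie in [0, 1)")
        if self.n_waves < 1:
            raise ValueError("n_waves must be >= 1")
        if self.embedding_dim < 2:
            raise ValueError("embedding_dim must be >= 2")
        if self.within_domain_sigma < 0:
            raise ValueError("within_domain_sigma must be >= 0")
        if self.min_centroid_separation <= 0:
            raise ValueError("min_centroid_separation must be > 0")
        if (self.domain_weights is not None
                and len(self.domain_weights) != self.n_domains):
            raise ValueError("domain_weights length must equal n_domains")


@dataclass(frozen=True)
class SyntheticCodebook:
    """A generated codebook plus its ground truth and search phrases."""

    codebook: Codebook
    truth: DomainLabelSet
    phrases: dict[str, str]
    embeddings: EmbeddingMatrix | None = None
    planned_wave_counts: dict[int, int] = field(default_factory=dict)
    n_base: int = 0
    n_duplicates: int = 0


def _case_mutate(identifier: str, rng: np.random.Generator) -> str:
    """Randomly flip letter case; guaranteed to differ from the input
    while casefolding to the same string."""
    chars = list(identifier)
    alpha = [i for i, ch in enumerate(chars) if ch.isalpha()]
    if not alpha:
        return identifier
    while True:
        out = [ch.swapcase() if (i in alpha and rng.random() < 0.5) else ch
               for i, ch in enumerate(chars)]
        cand = "".join(out)
        if cand != identifier:
            return cand


def _domain_sizes(spec: SyntheticSpec, rng: np.random.Generator) -> list[int]:
    if spec.domain_weights is None:
        return [spec.vars_per_domain] * spec.n_domains
    w = np.asarray(spec.domain_weights, dtype=float)
    w = w / w.sum()
    total = spec.n_domains * spec.vars_per_domain
    sizes = np.maximum(1, np.round(w * total).astype(int))
    return list(sizes)


def generate_codebook(spec: SyntheticSpec) -> SyntheticCodebook:
    """Generate a labelled synthetic codebook (text channel).

    Labelled variables draw 3-5 keywords from their domain's pool;
    filler variables draw from the neutral pool and are labelled NONE.
    A ``duplicate_rate`` share of base variables is re-emitted in a
    different wave with a case-mutated identifier (same description),
    emulating longitudinal identifier duplication.  Fully deterministic
    given the seed.
    """
    if spec.n_domains > len(DOMAIN_KEYWORD_POOLS):
        raise ValueError(
            f"text channel supports at most {len(DOMAIN_KEYWORD_POOLS)} "
            f"domains (asked for {spec.n_domains}); use the planted-geometry "
            "channel for larger domain counts"
        )
    rng = np.random.default_rng(spec.seed)
    domains = list(DOMAIN_KEYWORD_POOLS)[: spec.n_domains]
    sizes = _domain_sizes(spec, rng)

    records: list[VariableRecord] = []
    truth: dict[str, str] = {}

    def _description(pool: tuple[str, ...]) -> str:
        k = int(rng.integers(3, 6))
        words = rng.choice(len(pool), size=min(k, len(pool)), replace=False)
        return " ".join(pool[w] for w in words)

    for d_idx, (domain, size) in enumerate(zip(domains, sizes)):
        pool = DOMAIN_KEYWORD_POOLS[domain]
        code = "".join(w[0].upper() + w[1] for w in [domain.split("_")[0]])
        for k in range(size):
            ident = f"{code}{d_idx:02d}v{k:04d}"
            wave = int(rng.integers(1, spec.n_waves + 1))
            records.append(VariableRecord(
                identifier=ident,
                description=_description(pool),
                wave=wave,
                source=f"wave{wave}.tsv",
            ))
            truth[ident] = domain

    n_lab = len(records)
    f = spec.unlabeled_fraction
    n_unl = int(round(n_lab * f / (1.0 - f))) if f > 0 else 0
    for k in range(n_unl):
        ident = f"Gen{k:05d}"
        wave = int(rng.integers(1, spec.n_waves + 1))
        records.append(VariableRecord(
            identifier=ident,
            description=_description(NEUTRAL_POOL),
            wave=wave,
            source=f"wave{wave}.tsv",
        ))
        truth[ident] = NONE

    n_base = len(records)
    n_dup = int(round(spec.duplicate_rate * n_base))
    dup_idx = rng.choice(n_base, size=n_dup, replace=False) if n_dup else []
    for i in sorted(int(j) for j in np.atleast_1d(dup_idx)):
        base = records[i]
        mutated = _case_mutate(base.identifier, rng)
        wave = base.wave
        if spec.n_waves > 1:
            others = [w for w in range(1, spec.n_waves + 1) if w != base.wave]
            wave = int(others[int(rng.integers(0, len(others)))])
        records.append(VariableRecord(
            identifier=mutated,
            description=base.description,
            wave=wave,
            source=f"wave{wave}.tsv",
        ))
        truth[mutated] = truth[base.identifier]

    order = rng.permutation(len(records))
    records = [records[i] for i in order]
    truth = {r.identifier: truth[r.identifier] for r in records}

    wave_counts: dict[int, int] = {}
    for r in records:
        wave_counts[r.wave] = wave_counts.get(r.wave, 0) + 1

    # the phrase names the domain's full keyword vocabulary, so every
    # member description shares tokens with it
    phrases = {d: " ".join(DOMAIN_KEYWORD_POOLS[d]) for d in domains}
    return SyntheticCodebook(
        codebook=Codebook(records=tuple(records),
                          provenance=f"synthetic(seed={spec.seed})"),
        truth=DomainLabelSet(truth),
        phrases=phrases,
        planned_wave_counts=dict(sorted(wave_counts.items())),
        n_base=n_base,
        n_duplicates=n_dup,
    )


def _sample_centroids(n: int, dim: int, min_sep: float,
                      rng: np.random.Generator,
                      max_attempts: int = 10_000) -> np.ndarray:
    """Rejection-sample unit centroids with pairwise angle >= min_sep."""
    centroids: list[np.ndarray] = []
    attempts = 0
    while len(centroids) < n:
        if attempts >= max_attempts:
            raise RuntimeError(
                f"could not place {n} centroids with separation "
                f">= {min_sep} rad in {dim} dimensions after "
                f"{max_attempts} attempts"
            )
        attempts += 1
        c = rng.normal(size=dim)
        c /= np.linalg.norm(c)
        if all(np.arccos(np.clip(c @ p, -1, 1)) >= min_sep for p in centroids):
            centroids.append(c)
    return np.vstack(centroids)


def generate_planted_embeddings(spec: SyntheticSpec,
                                truth: DomainLabelSet) -> EmbeddingMatrix:
    """Generate unit vectors with planted domain geometry.

    Each domain gets a centroid on the unit sphere (pairwise angular
    separation >= ``min_centroid_separation``); members are the centroid
    plus isotropic Gaussian noise of scale ``within_domain_sigma``,
    re-normalised.  NONE variables are uniform on the sphere.
    """
    rng = np.random.default_rng(spec.seed + 1)
    domains = truth.domains
    centroids = _sample_centroids(len(domains), spec.embedding_dim,
                                  spec.min_centroid_separation, rng)
    cent = {d: centroids[i] for i, d in enumerate(domains)}
    idents = tuple(truth.labels)
    V = np.empty((len(idents), spec.embedding_dim))
    for r, ident in enumerate(idents):
        dom = truth.labels[ident]
        if dom == NONE:
            v = rng.normal(size=spec.embedding_dim)
        else:
            v = cent[dom] + spec.within_domain_sigma * rng.normal(
                size=spec.embedding_dim)
        V[r] = v / np.linalg.norm(v)
    return EmbeddingMatrix(
        identifiers=idents,
        vectors=V,
        zero_flags=np.zeros(len(idents), dtype=bool),
        metadata={"backend": "planted", "dimension": spec.embedding_dim,
                  "seed": spec.seed, "sigma": spec.within_domain_sigma},
    )


def write_fixture(sc: SyntheticCodebook, out_dir: str | Path) -> dict[str, Path]:
    """Write codebook.tsv, labels.tsv and phrases.tsv under ``out_dir``."""
    from .codebook import write_harmonised  # noqa: F401  (kept local: optional)
    from .labels import write_labels
    import pandas as pd

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "codebook": out / "codebook.tsv",
        "labels": out / "labels.tsv",
        "phrases": out / "phrases.tsv",
    }
    rows = [{"variable": r.identifier, "description": r.description,
             "wave": r.wave, "source": r.source or ""}
            for r in sc.codebook.records]
    pd.DataFrame(rows).to_csv(paths["codebook"], sep="\t", index=False)
    write_labels(sc.truth, paths["labels"])
    pd.DataFrame({"domain": list(sc.phrases),
                  "phrase": list(sc.phrases.values())}
                 ).to_csv(paths["phrases"], sep="\t", index=False)
    return paths
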