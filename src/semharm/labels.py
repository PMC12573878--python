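"""Validation-domain label sets.

A domain label set is the ground truth used to evaluate both pipelines:
each variable identifier maps to a human-assigned topical domain, or to
:data:`NONE` when it matches no validation domain.  ``NONE`` variables
are kept — they act as negatives in search evaluation and are excluded
from V-measure computations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

#: Sentinel domain for variables matching no validation domain.
NONE = "NONE"


@dataclass(frozen=True)
class DomainLabelSet:
    """Mapping from variable identifier to validation domain (or ``NONE``)."""

    labels: Mapping[str, str]

    def __post_init__(self) -> None:
        for ident in self.labels:
            if not ident or not ident.strip():
                raise ValueError("label set contains an empty identifier")

    @property
    def domains(self) -> tuple[str, ...]:
        """Distinct non-NONE domains, in first-appearance order."""
        seen: dict[str, None] = {}
        for d in self.labels.values():
            if d != NONE:
                seen.setdefault(d, None)
        return tuple(seen)

    def identifiers_in(self, domain: str) -> tuple[str, ...]:
        return tuple(i for i, d in self.labels.items() if d == domain)

    def validate_against(self, identifiers: Iterable[str]) -> None:
        """Check every labelled identifier appears in the given codebook."""
        universe = set(identifiers)
        missing = [i for i in self.labels if i not in universe]
        if missing:
            raise ValueError(
                f"{len(missing)} labelled identifier(s) absent from codebook, "
                f"e.g. {missing[:3]}"
            )


def read_labels(path: str | Path, *, identifier_col: str = "variable",
                domain_col: str = "domain") -> DomainLabelSet:
    """Read a TSV of (identifier, domain) pairs; domain may be ``NONE``."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"label file not found: {path}")
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in (identifier_col, domain_col):
        if col not in df.columns:
            raise ValueError(f"label file {path} lacks column {col!r}")
    return DomainLabelSet(
        {r[identifier_col].strip(): r[domain_col].strip()
         for _, r in df.iterrows()}
    )


def write_labels(labels: DomainLabelSet, path: str | Path) -> None:
    pd.DataFrame(
        {"variable": list(labels.labels), "domain": list(labels.labels.values())}
    ).to_csv(path, sep="\t", index=False)


def shuffle_domain_labels(labels: DomainLabelSet, fraction: float,
                          seed: int) -> DomainLabelSet:
    """Permute the domains of a random ``fraction`` of labelled variables.

    Only non-NONE entries participate; the selected entries' domains are
    permuted among themselves, so per-domain totals are preserved.  Used
    to study how label noise degrades harmonisation statistics.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    idents = [i for i, d in labels.labels.items() if d != NONE]
    n_pick = int(round(fraction * len(idents)))
    if n_pick < 2:
        return DomainLabelSet(dict(labels.labels))
    picked = rng.choice(len(idents), size=n_pick, replace=False)
    picked_ids = [idents[j] for j in picked]
    perm = rng.permutation(n_pick)
    new = dict(labels.labels)
    doms = [labels.labels[i] for i in picked_ids]
    for i, j in zip(picked_ids, perm):
        new[i] = doms[j]
    return DomainLabelSet(new)
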