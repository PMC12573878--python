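"""External validation of clusterings against human-labelled domains.

Homogeneity, completeness and the V-measure are computed from the
entropies of the cluster x domain contingency table (natural log; the
base cancels in the ratios).  Because an unsupervised clustering rarely
produces the same number of groups as the validation domains, matching
is done pairwise: for each (cluster, domain) pair a binary one-vs-rest
V-measure is computed, each domain is matched to its best cluster, and
the mean of those per-domain maxima — the mean-max V-measure (MMV) — is
the headline harmonisation statistic.  Unclustered (NOISE) and
unlabelled (NONE) items are excluded throughout, so incomplete
clustering is not penalised.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .clustering import NOISE, ClusterAssignment
from .labels import NONE, DomainLabelSet


@dataclass(frozen=True)
class ContingencyTable:
    """Cluster x domain count matrix over the evaluated universe."""

    counts: np.ndarray
    cluster_ids: tuple[int, ...]
    class_ids: tuple[str, ...]
    n_excluded_noise: int = 0
    n_excluded_unlabelled: int = 0

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.ndim != 2 or np.any(c < 0):
            raise ValueError("counts must be a non-negative 2-D matrix")
        if c.sum() == 0:
            raise ValueError("contingency table is all-zero")
        if c.shape != (len(self.cluster_ids), len(self.class_ids)):
            raise ValueError("counts shape does not match id lists")

    @property
    def total(self) -> int:
        return int(np.asarray(self.counts).sum())


@dataclass(frozen=True)
class VMeasureResult:
    homogeneity: float
    completeness: float
    v: float

    def __post_init__(self) -> None:
        for name in ("homogeneity", "completeness", "v"):
            val = getattr(self, name)
            if not -1e-12 <= val <= 1 + 1e-12:
                raise ValueError(f"{name}={val} outside [0, 1]")


@dataclass(frozen=True)
class DomainMatchReport:
    """Per-domain best-cluster matches and the MMV summary."""

    per_domain: Mapping[str, tuple[int, float]]
    mmv: float
    sd: float
    n_clusters: int
    n_excluded: int


def _evaluated_universe(a: ClusterAssignment,
                        labels: DomainLabelSet) -> tuple[list[str], int, int]:
    """Identifiers both clustered (non-NOISE) and labelled (non-NONE)."""
    universe: list[str] = []
    n_noise = 0
    n_unlab = 0
    for ident, cid in a.assignment.items():
        dom = labels.labels.get(ident)
        if cid == NOISE:
            n_noise += 1
            continue
        if dom is None or dom == NONE:
            n_unlab += 1
            continue
        universe.append(ident)
    return universe, n_noise, n_unlab


def build_contingency(a: ClusterAssignment,
                      labels: DomainLabelSet) -> ContingencyTable:
    """Tally cluster x domain counts over the evaluated universe only."""
    universe, n_noise, n_unlab = _evaluated_universe(a, labels)
    if not universe:
        raise ValueError("no identifier is both clustered (non-NOISE) and "
                         "labelled (non-NONE)")
    cluster_ids = sorted({a.assignment[i] for i in universe})
    class_ids: list[str] = []
    for i in universe:
        d = labels.labels[i]
        if d not in class_ids:
            class_ids.append(d)
    ci = {c: k for k, c in enumerate(cluster_ids)}
    di = {d: k for k, d in enumerate(class_ids)}
    counts = np.zeros((len(cluster_ids), len(class_ids)), dtype=int)
    for i in universe:
        counts[ci[a.assignment[i]], di[labels.labels[i]]] += 1
    return ContingencyTable(counts, tuple(cluster_ids), tuple(class_ids),
                            n_noise, n_unlab)


def _entropy(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def v_measure_from_counts(counts: np.ndarray) -> VMeasureResult:
    """Homogeneity / completeness / V from a raw cluster x class matrix."""
    c = np.asarray(counts, dtype=np.float64)
    total = c.sum()
    if total <= 0:
        raise ValueError("empty contingency table")
    p = c / total
    p_cluster = p.sum(axis=1)
    p_class = p.sum(axis=0)
    h_class = _entropy(p_class)
    h_cluster = _entropy(p_cluster)
    # H(class | cluster) = -sum_ij p_ij log(p_ij / p_i.)
    nz = p > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        h_class_given = float(-(p[nz] * np.log(
            p[nz] / np.outer(p_cluster, np.ones_like(p_class))[nz])).sum())
        h_cluster_given = float(-(p[nz] * np.log(
            p[nz] / np.outer(np.ones_like(p_cluster), p_class)[nz])).sum())
    h = 1.0 if h_class == 0 else 1.0 - h_class_given / h_class
    cpl = 1.0 if h_cluster == 0 else 1.0 - h_cluster_given / h_cluster
    h = min(max(h, 0.0), 1.0)
    cpl = min(max(cpl, 0.0), 1.0)
    v = 0.0 if h + cpl == 0 else 2 * h * cpl / (h + cpl)
    return VMeasureResult(h, cpl, v)


def v_measure(t: ContingencyTable) -> VMeasureResult:
    """V-measure of a contingency table: harmonic mean of homogeneity
    (each cluster holds one class) and completeness (each class lands in
    one cluster)."""
    return v_measure_from_counts(np.asarray(t.counts))


def pair_v_measure(a: ClusterAssignment, labels: DomainLabelSet,
                   cluster_id: int, domain: str) -> float:
    """One-vs-rest V-measure of a single (cluster, domain) pair.

    Both memberships are binarised over the evaluated universe and the
    V-measure of the resulting 2x2 table is returned.
    """
    universe, _, _ = _evaluated_universe(a, labels)
    if not universe:
        raise ValueError("empty evaluated universe")
    in_c = np.array([a.assignment[i] == cluster_id for i in universe])
    in_d = np.array([labels.labels[i] == domain for i in universe])
    if not in_c.any():
        raise ValueError(f"cluster {cluster_id} is empty over the evaluated universe")
    if not in_d.any():
        raise ValueError(f"domain {domain!r} is empty over the evaluated universe")
    counts = np.array([
        [int((in_c & in_d).sum()), int((in_c & ~in_d).sum())],
        [int((~in_c & in_d).sum()), int((~in_c & ~in_d).sum())],
    ])
    return v_measure_from_counts(counts).v


def _pair_v_from_margins(n11: int, row: int, col: int, total: int) -> float:
    counts = np.array([
        [n11, row - n11],
        [col - n11, total - row - col + n11],
    ])
    return v_measure_from_counts(counts).v


def mean_max_v_measure(a: ClusterAssignment,
                       labels: DomainLabelSet) -> DomainMatchReport:
    """Match each domain to its best cluster by one-vs-rest V-measure
    and average the per-domain maxima (MMV, with population SD)."""
    table = build_contingency(a, labels)
    counts = np.asarray(table.counts)
    rows = counts.sum(axis=1)
    cols = counts.sum(axis=0)
    total = table.total
    per_domain: dict[str, tuple[int, float]] = {}
    for j, domain in enumerate(table.class_ids):
        best_v = -1.0
        best_c = table.cluster_ids[0]
        for i, cid in enumerate(table.cluster_ids):
            v = _pair_v_from_margins(int(counts[i, j]), int(rows[i]),
                                     int(cols[j]), total)
            if v > best_v:
                best_v, best_c = v, cid
        per_domain[domain] = (best_c, best_v)
    vals = np.array([v for _, v in per_domain.values()])
    return DomainMatchReport(
        per_domain=per_domain,
        mmv=float(vals.mean()),
        sd=float(vals.std(ddof=0)),
        n_clusters=len(table.cluster_ids),
        n_excluded=table.n_excluded_noise + table.n_excluded_unlabelled,
    )
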