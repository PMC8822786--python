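"""Pair-counting and information-theoretic partition concordance metrics.

Given two partitions U (reference labels) and V (a clustering) of the same N
cells, every unordered cell pair falls into one of four classes:

* N11 — same cluster in both U and V
* N00 — different clusters in both
* N01 — same in U only
* N10 — same in V only

with N11 + N00 + N01 + N10 = N(N-1)/2.  The indices are

    ARI     = 2(N00*N11 - N01*N10) /
              ((N00+N01)(N01+N11) + (N00+N10)(N10+N11))
    FM      = sqrt( N11/(N11+N01) * N11/(N11+N10) )
    Jaccard = N11 / (N11 + N10 + N01)
    NMI     = 2*I(U;V) / (H(U) + H(V))        (default normalisation)

where I and H are mutual information and partition entropy computed in bits
from the U x V contingency table.  An alternative normalisation
I/(H(U)+H(V)) — which gives 0.5, not 1, for identical partitions — is kept
available as ``normalization="as_printed"`` for comparability with sources
that define NMI that way.

All functions accept either a :class:`~scstab.ensemble.Partition` or any
label sequence, and all are invariant to cluster relabelling and cell order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.metrics.cluster import contingency_matrix

__all__ = [
    "PairCounts",
    "EntropyStats",
    "ConcordanceScores",
    "DeviationStats",
    "pair_counts",
    "ari",
    "nmi",
    "fm",
    "jaccard",
    "entropy_stats",
    "concordance_scores",
    "deviation_stats",
]


def _as_labels(partition) -> np.ndarray:
    """Coerce a Partition object or any label sequence to a label array."""
    if hasattr(partition, "assignment"):
        partition = partition.assignment
    arr = np.asarray(partition)
    if arr.ndim != 1:
        raise ValueError("a partition must be a one-dimensional label sequence")
    return arr


@dataclass(frozen=True)
class PairCounts:
    """Counts of the four pair classes over all N(N-1)/2 unordered cell pairs."""

    N11: int
    N00: int
    N01: int
    N10: int
    N: int

    def __post_init__(self) -> None:
        total = self.N * (self.N - 1) // 2
        if self.N11 + self.N00 + self.N01 + self.N10 != total:
            raise ValueError(
                f"pair counts sum to {self.N11 + self.N00 + self.N01 + self.N10}, "
                f"expected N(N-1)/2 = {total}"
            )
        if min(self.N11, self.N00, self.N01, self.N10) < 0:
            raise ValueError("pair counts must be non-negative")


@dataclass(frozen=True)
class EntropyStats:
    """Mutual information and partition entropies, in bits."""

    I_UV: float
    H_U: float
    H_V: float


@dataclass(frozen=True)
class ConcordanceScores:
    ari: float
    nmi: float
    fm: float
    jaccard: float


@dataclass(frozen=True)
class DeviationStats:
    """Deviation of estimated cluster numbers from the true count.

    ``deviation`` is mean(estimate - true) over the replicates (positive =
    over-estimation); ``relative_deviation`` divides by the true count;
    ``sd_estimate`` is the sample standard deviation of the estimates.
    """

    deviation: float
    relative_deviation: float
    sd_estimate: float
    deviations: tuple[int, ...]
    relative_deviations: tuple[float, ...]


def _pairs_same(labels: np.ndarray) -> int:
    """Number of unordered pairs placed in the same cluster."""
    _, counts = np.unique(labels, return_counts=True)
    return int((counts * (counts - 1) // 2).sum())


def pair_counts(U, V) -> PairCounts:
    """Classify all unordered cell pairs by agreement between partitions U and V.

    Computed from the contingency table in O(RC) rather than by enumerating
    the N(N-1)/2 pairs; the two agree exactly (a property test checks this
    against brute-force enumeration).
    """
    u, v = _as_labels(U), _as_labels(V)
    if u.shape[0] != v.shape[0]:
        raise ValueError(f"partitions cover {u.shape[0]} and {v.shape[0]} cells")
    n = u.shape[0]
    cont = contingency_matrix(u, v, sparse=True)
    nij = cont.data.astype(np.int64)
    n11 = int((nij * (nij - 1) // 2).sum())
    same_u = _pairs_same(u)
    same_v = _pairs_same(v)
    total = n * (n - 1) // 2
    n01 = same_u - n11
    n10 = same_v - n11
    n00 = total - n11 - n01 - n10
    return PairCounts(N11=n11, N00=n00, N01=n01, N10=n10, N=n)


def _coerce_pc(U, V=None) -> PairCounts:
    if isinstance(U, PairCounts):
        return U
    if V is None:
        raise ValueError("provide either a PairCounts or two partitions")
    return pair_counts(U, V)


def ari(U, V=None) -> float:
    """Adjusted Rand index from pair counts.

    ARI = 2(N00*N11 - N01*N10) / ((N00+N01)(N01+N11) + (N00+N10)(N10+N11)).
    A zero denominator arises only for degenerate partitions (all cells in
    one cluster, or every cell its own cluster, in both U and V): identical
    degenerate partitions score 1, otherwise 0 with a warning.
    """
    pc = _coerce_pc(U, V)
    num = 2.0 * (pc.N00 * pc.N11 - pc.N01 * pc.N10)
    den = (pc.N00 + pc.N01) * (pc.N01 + pc.N11) + (pc.N00 + pc.N10) * (pc.N10 + pc.N11)
    if den == 0:
        if pc.N01 == 0 and pc.N10 == 0:
            return 1.0
        warnings.warn("degenerate pair counts with non-identical partitions; ARI set to 0")
        return 0.0
    return num / den


def fm(U, V=None) -> float:
    """Fowlkes-Mallows index: sqrt of precision times recall on same-pairs."""
    pc = _coerce_pc(U, V)
    if pc.N11 == 0:
        return 1.0 if pc.N01 == 0 and pc.N10 == 0 else 0.0
    return float(np.sqrt((pc.N11 / (pc.N11 + pc.N01)) * (pc.N11 / (pc.N11 + pc.N10))))


def jaccard(U, V=None) -> float:
    """Jaccard index over same-cluster pairs."""
    pc = _coerce_pc(U, V)
    den = pc.N11 + pc.N10 + pc.N01
    if den == 0:
        return 1.0 if pc.N11 == 0 else 0.0
    return pc.N11 / den


def entropy_stats(U, V) -> EntropyStats:
    """Mutual information I(U;V) and entropies H(U), H(V) in bits."""
    u, v = _as_labels(U), _as_labels(V)
    if u.shape[0] != v.shape[0]:
        raise ValueError(f"partitions cover {u.shape[0]} and {v.shape[0]} cells")
    n = u.shape[0]
    cont = np.asarray(contingency_matrix(u, v), dtype=float)
    pij = cont / n
    pi = pij.sum(axis=1)
    pj = pij.sum(axis=0)
    outer = np.outer(pi, pj)
    nz = pij > 0
    I = float((pij[nz] * np.log2(pij[nz] / outer[nz])).sum())
    H_U = float(-(pi[pi > 0] * np.log2(pi[pi > 0])).sum())
    H_V = float(-(pj[pj > 0] * np.log2(pj[pj > 0])).sum())
    # clip tiny negatives from floating-point cancellation
    return EntropyStats(I_UV=max(I, 0.0), H_U=H_U, H_V=H_V)


def nmi(U, V, normalization: str = "standard") -> float:
    """Normalised mutual information between two partitions.

    ``standard`` (default) returns 2*I/(H_U + H_V), which is 1 for identical
    partitions; ``as_printed`` returns I/(H_U + H_V).  When both entropies
    are zero (single-cluster partitions) the score is 1 if the partitions
    are identical up to relabelling and 0 otherwise, with a warning.
    """
    if normalization not in ("standard", "as_printed"):
        raise ValueError(f"unknown normalization {normalization!r}")
    es = entropy_stats(U, V)
    den = es.H_U + es.H_V
    if den == 0.0:
        u, v = _as_labels(U), _as_labels(V)
        identical = len(np.unique(u)) == 1 and len(np.unique(v)) == 1
        if not identical:
            warnings.warn("zero total entropy with non-identical partitions; NMI set to 0")
            return 0.0
        return 1.0
    factor = 2.0 if normalization == "standard" else 1.0
    return min(factor * es.I_UV / den, 1.0)


def concordance_scores(U, V, nmi_normalization: str = "standard") -> ConcordanceScores:
    """All four concordance indices between a clustering and reference labels."""
    pc = pair_counts(U, V)
    return ConcordanceScores(
        ari=ari(pc),
        nmi=nmi(U, V, normalization=nmi_normalization),
        fm=fm(pc),
        jaccard=jaccard(pc),
    )


def deviation_stats(estimates: Sequence[int], true_k: int) -> DeviationStats:
    """Deviation statistics for a set of replicate cluster-number estimates."""
    if true_k < 1:
        raise ValueError("true_k must be a positive integer")
    est = np.asarray(list(estimates), dtype=int)
    if est.size == 0:
        raise ValueError("at least one estimate is required")
    devs = est - true_k
    rel = devs / float(true_k)
    sd = float(np.std(est, ddof=1)) if est.size > 1 else 0.0
    return DeviationStats(
        deviation=float(devs.mean()),
        relative_deviation=float(rel.mean()),
        sd_estimate=sd,
        deviations=tuple(int(d) for d in devs),
        relative_deviations=tuple(float(r) for r in rel),
    )
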