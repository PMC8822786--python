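"""Stability-based selection of the number of cell types.

For each candidate k in a grid (2..25 by default) the ensemble members are
clustered into k groups and the stability of that k is the median (or mean)
normalised mutual information over all B(B-1)/2 unordered member pairs.  The
estimate k_hat is the k with the highest stability; ties break to the
smallest k (parsimony).  The rationale: when k matches the real number of
cell populations, clusterings of independently projected and encoded views
of the data agree with each other; at wrong k the members fragment or merge
populations inconsistently and agreement drops.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.utils.validation import check_array, check_is_fitted

from . import metrics
from .ensemble import (
    ClustererFn,
    EnsembleConfig,
    EnsembleResult,
    Partition,
    build_encodings,
    cluster_encodings,
    coassociation_matrix,
    consensus_partition,
)
from .preprocess import NormalizedMatrix

__all__ = ["StabilityProfile", "EstimateResult", "StabilityKEstimator",
           "stability_score", "estimate_k"]


@dataclass(frozen=True)
class StabilityProfile:
    """Stability score (in [0, 1]) for every k on the candidate grid."""

    k_grid: tuple[int, ...]
    score: dict
    aggregate: str = "median"

    def __post_init__(self) -> None:
        missing = [k for k in self.k_grid if k not in self.score]
        if missing:
            raise ValueError(f"no score for grid points {missing}")
        bad = {k: s for k, s in self.score.items() if not 0.0 <= s <= 1.0}
        if bad:
            raise ValueError(f"scores outside [0, 1]: {bad}")

    def argmax(self) -> int:
        """Highest-scoring k; ties break to the smallest k."""
        best = max(self.score[k] for k in self.k_grid)
        return min(k for k in self.k_grid if self.score[k] == best)


@dataclass
class EstimateResult:
    k_hat: int
    profile: StabilityProfile
    consensus: Partition


def stability_score(members: Sequence[Partition], aggregate: str = "median") -> float:
    """Aggregate pairwise NMI over all unordered pairs of ensemble members."""
    if len(members) < 2:
        raise ValueError("stability needs at least 2 ensemble members")
    if aggregate not in ("median", "mean"):
        raise ValueError(f"unknown aggregate {aggregate!r}")
    n_cells = {m.n_cells if hasattr(m, "n_cells") else len(m) for m in members}
    if len(n_cells) != 1:
        raise ValueError("all member partitions must cover the same cells")
    scores = [
        metrics.nmi(members[i], members[j])
        for i in range(len(members))
        for j in range(i + 1, len(members))
    ]
    return float(np.median(scores) if aggregate == "median" else np.mean(scores))


class StabilityKEstimator(ClusterMixin, BaseEstimator):
    """Estimate the number of cell types by clustering-stability maximisation.

    ``fit(X)`` takes a cells x genes log-normalised matrix, builds an
    ensemble of encoded random gene-subspace projections, scores every k in
    ``[k_min, k_max]`` by the aggregate pairwise NMI of the members' k-way
    clusterings, and selects the most stable k.

    Parameters
    ----------
    k_min, k_max : int, default 2 and 25
        Candidate grid bounds (inclusive); ``k_grid`` overrides them.
    ensemble_size : int, default=20
        Number of projection -> encode -> cluster members (B).
    projection_fraction : float, default=0.1
        Fraction of genes per random projection (floored at 2 * encode_dim).
    encode_dim : int, default=16
        Encoded dimensionality per member.
    encoder : {"autoencoder", "pca_fallback"}, default="autoencoder"
        Per-member encoder; PCA is a fast deterministic alternative.
    encoder_epochs : int, default=30
        Autoencoder training epochs per member.
    aggregate : {"median", "mean"}, default="median"
        Aggregation of the pairwise NMI scores at each k.
    share_projections : bool, default=True
        Reuse the same B encodings across all k (comparable and fast); if
        False, each k re-derives projections and encoders from k-specific
        seeds.
    base_clusterer : {"kmeans", "plugin"}; clusterer_fn for "plugin".
    random_state : int, default=0
        Seed for all randomness.

    Attributes
    ----------
    k_hat_, n_clusters_ : int
        The estimated number of cell types.
    stability_profile_ : StabilityProfile
        Score for every k on the grid.
    labels_ : ndarray
        Consensus partition at k_hat_ (co-association + average linkage).
    members_ : list of Partition
        Ensemble member partitions at k_hat_.
    """

    def __init__(self, k_min: int = 2, k_max: int = 25, k_grid: Optional[Sequence[int]] = None,
                 ensemble_size: int = 20, projection_fraction: float = 0.1,
                 encode_dim: int = 16, encoder: str = "autoencoder",
                 encoder_epochs: int = 30, aggregate: str = "median",
                 share_projections: bool = True, base_clusterer: str = "kmeans",
                 clusterer_fn: Optional[ClustererFn] = None, kmeans_n_init: int = 5,
                 random_state: int = 0):
        self.k_min = k_min
        self.k_max = k_max
        self.k_grid = k_grid
        self.ensemble_size = ensemble_size
        self.projection_fraction = projection_fraction
        self.encode_dim = encode_dim
        self.encoder = encoder
        self.encoder_epochs = encoder_epochs
        self.aggregate = aggregate
        self.share_projections = share_projections
        self.base_clusterer = base_clusterer
        self.clusterer_fn = clusterer_fn
        self.kmeans_n_init = kmeans_n_init
        self.random_state = random_state

    def _grid(self) -> tuple[int, ...]:
        if self.k_grid is not None:
            grid = tuple(sorted(int(k) for k in self.k_grid))
        else:
            grid = tuple(range(int(self.k_min), int(self.k_max) + 1))
        if not grid:
            raise ValueError("empty k grid")
        if grid[0] < 2:
            raise ValueError("candidate k values must be >= 2")
        return grid

    def _config(self, k: int, seed: int) -> EnsembleConfig:
        return EnsembleConfig(
            B=self.ensemble_size, projection_fraction=self.projection_fraction,
            encode_dim=self.encode_dim, encoder=self.encoder,
            encoder_epochs=self.encoder_epochs, base_clusterer=self.base_clusterer,
            clusterer_fn=self.clusterer_fn, kmeans_n_init=self.kmeans_n_init,
            k=k, seed=seed,
        )

    def fit(self, X, y=None):
        X = check_array(X, dtype=float)
        grid = self._grid()
        if grid[-1] > X.shape[0]:
            raise ValueError(f"k_max={grid[-1]} exceeds the {X.shape[0]} cells")
        nm = NormalizedMatrix(
            values=X.T,
            gene_ids=[f"g{i}" for i in range(X.shape[1])],
            cell_ids=[f"c{i}" for i in range(X.shape[0])],
        )
        seed = self.random_state if self.random_state is not None else 0

        scores: dict[int, float] = {}
        members_at_k: dict[int, list[Partition]] = {}
        shared = build_encodings(nm, self._config(max(grid[0], 2), seed)) \
            if self.share_projections else None
        for k in grid:
            cfg = self._config(max(k, 2), seed if self.share_projections else seed + k)
            try:
                encodings = shared if shared is not None else build_encodings(nm, cfg)
                members = cluster_encodings(encodings, k, cfg)
            except Exception as exc:
                raise RuntimeError(f"ensemble failed at k={k}: {exc}") from exc
            members_at_k[k] = members
            scores[k] = stability_score(members, aggregate=self.aggregate)

        profile = StabilityProfile(k_grid=grid, score=scores, aggregate=self.aggregate)
        k_hat = profile.argmax()
        best_members = members_at_k[k_hat]
        er = EnsembleResult(
            members=best_members,
            coassociation=coassociation_matrix(best_members),
            config=self._config(max(k_hat, 2), seed),
        )
        consensus = consensus_partition(er, k_hat)

        self.stability_profile_ = profile
        self.k_hat_ = k_hat
        self.n_clusters_ = k_hat
        self.members_ = best_members
        self.ensemble_result_ = er
        self.labels_ = consensus.as_array()
        self.consensus_ = consensus
        self.n_features_in_ = X.shape[1]
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


def estimate_k(nm: NormalizedMatrix, cfg: EnsembleConfig,
               k_grid: Optional[Sequence[int]] = None,
               aggregate: str = "median", share_projections: bool = True) -> EstimateResult:
    """Functional interface over :class:`StabilityKEstimator`.

    Takes a genes x cells :class:`NormalizedMatrix` and an
    :class:`EnsembleConfig`; returns the estimate, the full stability
    profile, and the consensus partition at the estimate.
    """
    grid = tuple(k_grid) if k_grid is not None else tuple(range(2, 26))
    est = StabilityKEstimator(
        k_grid=grid, ensemble_size=cfg.B, projection_fraction=cfg.projection_fraction,
        encode_dim=cfg.encode_dim, encoder=cfg.encoder, encoder_epochs=cfg.encoder_epochs,
        aggregate=aggregate, share_projections=share_projections,
        base_clusterer=cfg.base_clusterer, clusterer_fn=cfg.clusterer_fn,
        kmeans_n_init=cfg.kmeans_n_init, random_state=cfg.seed,
    ).fit(nm.X)
    return EstimateResult(k_hat=est.k_hat_, profile=est.stability_profile_,
                          consensus=est.consensus_)
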