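"""Ensembles of clusterings on encoded random gene-subspace projections.

Each ensemble member draws a random subset of genes from the log-normalised
matrix, encodes those genes to a low dimension — with a small autoencoder
(single bottleneck, reconstruction objective) or a PCA projection — and
clusters the encoding into k groups with k-means (or a plugged-in clusterer).
The members' co-association matrix (fraction of members placing each cell
pair together) supports a consensus partition via average-linkage
hierarchical clustering of 1 - co-association.

Randomness is contained per member: member b derives its own seed from the
ensemble seed, so runs are reproducible end to end and members differ from
each other in both gene subset and encoder initialisation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import scipy.cluster.hierarchy as sch
import scipy.spatial.distance as ssd
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.utils.validation import check_array, check_is_fitted

from .preprocess import NormalizedMatrix

__all__ = [
    "Partition",
    "EnsembleConfig",
    "EnsembleResult",
    "SubspaceEnsembleClustering",
    "random_projection",
    "encode",
    "run_ensemble",
    "consensus_partition",
]

# type of a pluggable base clusterer: (cells x dims matrix, k, seed) -> labels
ClustererFn = Callable[[np.ndarray, int, int], np.ndarray]


@dataclass(frozen=True)
class Partition:
    """A hard assignment of every cell to exactly one cluster.

    Cluster identifiers are arbitrary; every metric consuming partitions is
    invariant to relabelling.
    """

    assignment: tuple

    def __init__(self, assignment: Sequence):
        arr = np.asarray(assignment)
        if arr.ndim != 1:
            raise ValueError("assignment must be one label per cell")
        object.__setattr__(self, "assignment", tuple(arr.tolist()))

    @property
    def n_cells(self) -> int:
        return len(self.assignment)

    @property
    def n_clusters(self) -> int:
        return len(set(self.assignment))

    def as_array(self) -> np.ndarray:
        return np.asarray(self.assignment)


@dataclass(frozen=True)
class EnsembleConfig:
    """Configuration of one projection -> encode -> cluster ensemble.

    ``B`` is the ensemble size (default 20).  ``projection_fraction`` is the
    fraction of genes per random projection, subject to a floor of
    ``2 * encode_dim`` genes.  ``encoder`` selects the per-member encoder:
    ``"autoencoder"`` (bottleneck network trained on reconstruction) or
    ``"pca_fallback"`` (truncated linear projection, identical interface,
    much faster).  ``base_clusterer`` is ``"kmeans"`` or ``"plugin"`` (supply
    ``clusterer_fn``).
    """

    B: int = 20
    projection_fraction: float = 0.1
    encode_dim: int = 16
    encoder: str = "autoencoder"
    encoder_epochs: int = 30
    base_clusterer: str = "kmeans"
    k: int = 2
    seed: int = 0
    kmeans_n_init: int = 5
    clusterer_fn: Optional[ClustererFn] = None

    def __post_init__(self) -> None:
        if self.B < 2:
            raise ValueError("ensemble size B must be >= 2 (pairwise scores need two members)")
        if not 0.0 < self.projection_fraction <= 1.0:
            raise ValueError("projection_fraction must lie in (0, 1]")
        if self.encode_dim < 1:
            raise ValueError("encode_dim must be positive")
        if self.encoder not in ("autoencoder", "pca_fallback"):
            raise ValueError(f"unknown encoder {self.encoder!r}")
        if self.encoder_epochs < 1:
            raise ValueError("encoder_epochs must be positive")
        if self.base_clusterer not in ("kmeans", "plugin"):
            raise ValueError(f"unknown base_clusterer {self.base_clusterer!r}")
        if self.base_clusterer == "plugin" and self.clusterer_fn is None:
            raise ValueError("base_clusterer='plugin' requires clusterer_fn")
        if self.k < 2:
            raise ValueError("k must be >= 2")


@dataclass
class EnsembleResult:
    """All member partitions plus their co-association matrix."""

    members: list
    coassociation: np.ndarray
    config: EnsembleConfig

    def __post_init__(self) -> None:
        n = self.coassociation.shape[0]
        if self.coassociation.shape != (n, n):
            raise ValueError("co-association matrix must be square")
        for m in self.members:
            if m.n_cells != n:
                raise ValueError("member partition size does not match co-association matrix")


def member_seeds(seed: int, B: int) -> list[int]:
    """Derive one reproducible sub-seed per ensemble member."""
    return [int(s) for s in np.random.SeedSequence(seed).generate_state(B) % (2**31)]


def random_projection(nm: NormalizedMatrix, fraction: float, member_seed: int,
                      min_genes: int = 2) -> NormalizedMatrix:
    """Restrict to ceil(fraction * G) genes drawn uniformly without replacement."""
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must lie in (0, 1]")
    G = nm.n_genes
    n_sel = max(int(np.ceil(fraction * G)), min_genes)
    if n_sel > G:
        raise ValueError(f"projection needs {n_sel} genes but only {G} are available")
    rng = np.random.default_rng(member_seed)
    idx = np.sort(rng.choice(G, size=n_sel, replace=False))
    return NormalizedMatrix(
        values=nm.values[idx, :],
        gene_ids=[nm.gene_ids[i] for i in idx],
        cell_ids=nm.cell_ids,
        labels=nm.labels,
        pseudocount=nm.pseudocount,
        log_base=nm.log_base,
    )


def _autoencoder_encode(X: np.ndarray, dim: int, epochs: int, seed: int) -> np.ndarray:
    """Bottleneck activations of a single-hidden-layer autoencoder.

    tanh bottleneck, linear output, MSE reconstruction loss, Adam, seeded
    minibatches.  Input is standardised feature-wise; small and CPU-friendly.
    """
    rng = np.random.default_rng(seed)
    n, g = X.shape
    mu, sd = X.mean(axis=0), X.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (X - mu) / sd

    scale = np.sqrt(2.0 / (g + dim))
    W1 = rng.normal(0.0, scale, size=(g, dim))
    b1 = np.zeros(dim)
    W2 = rng.normal(0.0, scale, size=(dim, g))
    b2 = np.zeros(g)

    params = [W1, b1, W2, b2]
    m_t = [np.zeros_like(p) for p in params]
    v_t = [np.zeros_like(p) for p in params]
    lr, beta1, beta2, eps = 1e-2, 0.9, 0.999, 1e-8
    batch = min(64, n)
    step = 0
    for _ in range(epochs):
        order = rng.permutation(n)
        for start in range(0, n, batch):
            xb = Z[order[start:start + batch]]
            h_pre = xb @ W1 + b1
            h = np.tanh(h_pre)
            out = h @ W2 + b2
            err = out - xb  # d(MSE)/d(out) up to 2/n factor folded into lr
            gW2 = h.T @ err / xb.shape[0]
            gb2 = err.mean(axis=0)
            dh = (err @ W2.T) * (1.0 - h**2)
            gW1 = xb.T @ dh / xb.shape[0]
            gb1 = dh.mean(axis=0)
            step += 1
            for p, gr, m, v in zip(params, [gW1, gb1, gW2, gb2], m_t, v_t):
                m *= beta1
                m += (1 - beta1) * gr
                v *= beta2
                v += (1 - beta2) * gr**2
                mhat = m / (1 - beta1**step)
                vhat = v / (1 - beta2**step)
                p -= lr * mhat / (np.sqrt(vhat) + eps)
    return np.tanh(Z @ W1 + b1)


def _pca_encode(X: np.ndarray, dim: int, seed: int) -> np.ndarray:
    dim = min(dim, min(X.shape) - 1) if min(X.shape) > 1 else 1
    pca = PCA(n_components=dim, svd_solver="full", random_state=seed)
    return pca.fit_transform(X)


def encode(nm: NormalizedMatrix, encode_dim: int, epochs: int, member_seed: int,
           encoder: str = "autoencoder") -> np.ndarray:
    """Encode a projected matrix to (n_cells, encode_dim); deterministic per seed."""
    if encode_dim >= nm.n_genes:
        raise ValueError(
            f"encode_dim={encode_dim} must be smaller than the {nm.n_genes} projected genes"
        )
    X = check_array(nm.X, dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite values in input")
    if encoder == "autoencoder":
        return _autoencoder_encode(X, encode_dim, epochs, member_seed)
    if encoder == "pca_fallback":
        return _pca_encode(X, encode_dim, member_seed)
    raise ValueError(f"unknown encoder {encoder!r}")


def _cluster(X: np.ndarray, k: int, seed: int, cfg: EnsembleConfig) -> np.ndarray:
    if cfg.base_clusterer == "plugin":
        labels = np.asarray(cfg.clusterer_fn(X, k, seed))
        if labels.shape[0] != X.shape[0]:
            raise ValueError("plugin clusterer returned wrong number of labels")
        return labels
    km = KMeans(n_clusters=k, n_init=cfg.kmeans_n_init, random_state=seed)
    return km.fit_predict(X)


def build_encodings(nm: NormalizedMatrix, cfg: EnsembleConfig) -> list[tuple[np.ndarray, int]]:
    """Materialise the B encoded member datasets (shared across k grids)."""
    out = []
    for b, s in enumerate(member_seeds(cfg.seed, cfg.B)):
        proj = random_projection(nm, cfg.projection_fraction, s,
                                 min_genes=min(2 * cfg.encode_dim, nm.n_genes))
        if cfg.encode_dim >= proj.n_genes:
            raise ValueError(
                f"member {b}: projection yields {proj.n_genes} genes, "
                f"not enough for encode_dim={cfg.encode_dim}"
            )
        out.append((encode(proj, cfg.encode_dim, cfg.encoder_epochs, s, cfg.encoder), s))
    return out


def coassociation_matrix(members: Sequence[Partition]) -> np.ndarray:
    """Fraction of members placing each cell pair in the same cluster."""
    n = members[0].n_cells
    co = np.zeros((n, n))
    for m in members:
        _, lab = np.unique(m.as_array(), return_inverse=True)
        co += (lab[:, None] == lab[None, :]).astype(float)
    co /= len(members)
    np.fill_diagonal(co, 1.0)
    return co


def cluster_encodings(encodings: Sequence[tuple[np.ndarray, int]], k: int,
                      cfg: EnsembleConfig) -> list[Partition]:
    members = []
    for b, (enc, s) in enumerate(encodings):
        try:
            members.append(Partition(_cluster(enc, k, s, cfg)))
        except Exception as exc:
            raise RuntimeError(f"base clusterer failed on ensemble member {b}: {exc}") from exc
    return members


def run_ensemble(nm: NormalizedMatrix, cfg: EnsembleConfig) -> EnsembleResult:
    """Project, encode and cluster each of the B members at cfg.k."""
    if cfg.k > nm.n_cells:
        raise ValueError(f"k={cfg.k} exceeds the {nm.n_cells} cells")
    encodings = build_encodings(nm, cfg)
    members = cluster_encodings(encodings, cfg.k, cfg)
    return EnsembleResult(members=members, coassociation=coassociation_matrix(members),
                          config=cfg)


def consensus_partition(er: EnsembleResult, k: int) -> Partition:
    """Average-linkage hierarchical cut of 1 - co-association into k clusters."""
    n = er.coassociation.shape[0]
    if k > n:
        raise ValueError(f"k={k} exceeds the {n} cells")
    if n == 1:
        return Partition([0])
    dist = 1.0 - er.coassociation
    np.fill_diagonal(dist, 0.0)
    link = sch.linkage(ssd.squareform(dist, checks=False), method="average")
    labels = sch.fcluster(link, t=k, criterion="maxclust")
    return Partition(labels)


class SubspaceEnsembleClustering(ClusterMixin, BaseEstimator):
    """Consensus clustering of encoded random gene-subspace projections.

    A sklearn-style clusterer: ``fit(X)`` (cells x genes, log-normalised)
    builds ``ensemble_size`` members — random gene subset, low-dimensional
    encoding, k-means at ``n_clusters`` — and cuts the co-association matrix
    into a consensus partition.

    Parameters mirror :class:`EnsembleConfig`.  Fitted attributes:
    ``labels_`` (consensus), ``members_`` (list of Partition),
    ``coassociation_``, ``ensemble_result_``.
    """

    def __init__(self, n_clusters: int = 2, ensemble_size: int = 20,
                 projection_fraction: float = 0.1, encode_dim: int = 16,
                 encoder: str = "autoencoder", encoder_epochs: int = 30,
                 base_clusterer: str = "kmeans", clusterer_fn: Optional[ClustererFn] = None,
                 kmeans_n_init: int = 5, random_state: int = 0):
        self.n_clusters = n_clusters
        self.ensemble_size = ensemble_size
        self.projection_fraction = projection_fraction
        self.encode_dim = encode_dim
        self.encoder = encoder
        self.encoder_epochs = encoder_epochs
        self.base_clusterer = base_clusterer
        self.clusterer_fn = clusterer_fn
        self.kmeans_n_init = kmeans_n_init
        self.random_state = random_state

    def _config(self, k: int) -> EnsembleConfig:
        return EnsembleConfig(
            B=self.ensemble_size,
            projection_fraction=self.projection_fraction,
            encode_dim=self.encode_dim,
            encoder=self.encoder,
            encoder_epochs=self.encoder_epochs,
            base_clusterer=self.base_clusterer,
            clusterer_fn=self.clusterer_fn,
            kmeans_n_init=self.kmeans_n_init,
            k=k,
            seed=self.random_state if self.random_state is not None else 0,
        )

    def fit(self, X, y=None):
        X = check_array(X, dtype=float)
        nm = NormalizedMatrix(
            values=X.T,
            gene_ids=[f"g{i}" for i in range(X.shape[1])],
            cell_ids=[f"c{i}" for i in range(X.shape[0])],
        )
        er = run_ensemble(nm, self._config(self.n_clusters))
        consensus = consensus_partition(er, self.n_clusters)
        self.ensemble_result_ = er
        self.members_ = er.members
        self.coassociation_ = er.coassociation
        self.labels_ = consensus.as_array()
        self.n_features_in_ = X.shape[1]
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_
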