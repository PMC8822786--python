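"""Synthetic labelled scRNA-seq count pools.

Generates a labelled "selection pool" of cells with a configurable number of
cell types, standing in for a large annotated atlas that benchmark datasets
are subsampled from.  Each cell type carries a disjoint block of marker genes
whose mean expression is elevated ``2**separation``-fold over the shared
background; counts are negative-binomial (variance = mu + dispersion * mu**2)
with log-normal per-cell library-size factors.

The model deliberately omits dropout beyond negative-binomial zeros, batch
effects, doublets and hierarchical subtypes; the ground-truth number of cell
types is unambiguous by construction, which is what the downstream
parameter-recovery tests require.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

__all__ = [
    "SimPoolSpec",
    "CountMatrix",
    "simulate_pool",
    "write_mtx",
    "read_mtx",
    "write_csv",
    "read_csv",
]


class SpecValidationError(ValueError):
    """A simulation spec violates one of its invariants."""


@dataclass(frozen=True)
class SimPoolSpec:
    """Recipe for a synthetic labelled count pool.

    Parameters
    ----------
    n_types : int
        Number of distinct cell types (ground-truth k).
    cells_per_type : sequence of int
        Number of cells for each type; length must equal ``n_types``.
    n_genes : int
        Total genes; marker blocks are carved out of this set.
    n_marker_genes_per_type : int
        Disjoint marker genes per type; ``n_marker_genes_per_type * n_types``
        must not exceed ``n_genes``.
    separation : float
        log2 fold-change of a type's marker genes in that type's cells over
        the background rate.  0 means no signal.
    dispersion : float
        Negative-binomial overdispersion; variance = mu + dispersion * mu**2.
        0 falls back to Poisson.
    base_expression_rate : float
        Mean count of background genes (before library-size scaling).
    libsize_cv : float
        Coefficient of variation of the log-normal per-cell library-size
        factors (mean 1).  0 disables library-size variation.
    seed : int
        Seed for all randomness; identical specs give bit-identical pools.
    """

    n_types: int
    cells_per_type: Sequence[int]
    n_genes: int = 1000
    n_marker_genes_per_type: int = 25
    separation: float = 3.0
    dispersion: float = 0.3
    base_expression_rate: float = 2.0
    libsize_cv: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "cells_per_type", tuple(int(c) for c in self.cells_per_type))
        if self.n_types < 1:
            raise SpecValidationError("n_types must be a positive integer")
        if len(self.cells_per_type) != self.n_types:
            raise SpecValidationError(
                f"length(cells_per_type)={len(self.cells_per_type)} != n_types={self.n_types}"
            )
        if any(c < 1 for c in self.cells_per_type):
            raise SpecValidationError("cells_per_type entries must be positive")
        if self.n_genes < 1:
            raise SpecValidationError("n_genes must be positive")
        if self.n_marker_genes_per_type < 0:
            raise SpecValidationError("n_marker_genes_per_type must be non-negative")
        if self.n_marker_genes_per_type * self.n_types > self.n_genes:
            raise SpecValidationError(
                "n_marker_genes_per_type * n_types exceeds n_genes "
                f"({self.n_marker_genes_per_type} * {self.n_types} > {self.n_genes})"
            )
        if self.separation < 0:
            raise SpecValidationError("separation must be non-negative")
        if self.dispersion < 0:
            raise SpecValidationError("dispersion must be non-negative")
        if self.base_expression_rate <= 0:
            raise SpecValidationError("base_expression_rate must be positive")
        if self.libsize_cv < 0:
            raise SpecValidationError("libsize_cv must be non-negative")


@dataclass
class CountMatrix:
    """A genes x cells raw count matrix with identifiers and optional labels."""

    counts: np.ndarray  # genes x cells, non-negative integers
    gene_ids: list[str]
    cell_ids: list[str]
    labels: Optional[list[str]] = None

    def __post_init__(self) -> None:
        if sp.issparse(self.counts):
            self.counts = np.asarray(self.counts.todense())
        self.counts = np.asarray(self.counts)
        self.gene_ids = list(self.gene_ids)
        self.cell_ids = list(self.cell_ids)
        if self.labels is not None:
            self.labels = list(self.labels)
        self.validate()

    def validate(self) -> None:
        g, c = self.counts.shape
        if len(self.gene_ids) != g:
            raise ValueError(f"{len(self.gene_ids)} gene ids for {g} matrix rows")
        if len(self.cell_ids) != c:
            raise ValueError(f"{len(self.cell_ids)} cell ids for {c} matrix columns")
        if self.labels is not None and len(self.labels) != c:
            raise ValueError(f"{len(self.labels)} labels for {c} cells")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.allclose(self.counts, np.round(self.counts)):
                raise ValueError("counts must be integral")
            self.counts = self.counts.astype(np.int64)

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    def subset_cells(self, idx: Sequence[int]) -> "CountMatrix":
        idx = np.asarray(idx, dtype=int)
        return CountMatrix(
            counts=self.counts[:, idx],
            gene_ids=self.gene_ids,
            cell_ids=[self.cell_ids[i] for i in idx],
            labels=None if self.labels is None else [self.labels[i] for i in idx],
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CountMatrix):
            return NotImplemented
        return (
            np.array_equal(self.counts, other.counts)
            and self.gene_ids == other.gene_ids
            and self.cell_ids == other.cell_ids
            and self.labels == other.labels
        )


def simulate_pool(spec: SimPoolSpec) -> CountMatrix:
    """Draw a labelled count pool from the negative-binomial marker-gene model.

    Each type ``t`` owns a disjoint block of ``n_marker_genes_per_type`` genes
    whose mean in type-``t`` cells is ``base_expression_rate * 2**separation``;
    all other genes (and marker genes outside their own type) sit at the
    background rate.  Per-cell library-size factors are log-normal with mean 1
    and the requested coefficient of variation, multiplying every gene's mean
    in that cell.
    """
    rng = np.random.default_rng(spec.seed)
    n_cells = int(sum(spec.cells_per_type))
    G, T, M = spec.n_genes, spec.n_types, spec.n_marker_genes_per_type

    type_names = [f"type_{t}" for t in range(T)]
    labels = np.repeat(type_names, spec.cells_per_type)
    type_of_cell = np.repeat(np.arange(T), spec.cells_per_type)

    # mean matrix: background everywhere, marker blocks elevated in own type
    mu = np.full((G, n_cells), spec.base_expression_rate, dtype=float)
    fold = 2.0 ** spec.separation
    for t in range(T):
        marker_rows = slice(t * M, (t + 1) * M)
        mu[marker_rows, type_of_cell == t] *= fold

    if spec.libsize_cv > 0:
        sigma2 = np.log1p(spec.libsize_cv ** 2)
        factors = rng.lognormal(mean=-sigma2 / 2.0, sigma=np.sqrt(sigma2), size=n_cells)
    else:
        factors = np.ones(n_cells)
    mu *= factors[np.newaxis, :]

    if spec.dispersion > 0:
        n_param = 1.0 / spec.dispersion
        counts = rng.negative_binomial(n_param, n_param / (n_param + mu))
    else:
        counts = rng.poisson(mu)

    gene_ids = [
        (f"marker_t{g // M}_g{g % M}" if M > 0 and g < M * T else f"gene_{g}")
        for g in range(G)
    ]
    cell_ids = [f"cell_{i}" for i in range(n_cells)]
    return CountMatrix(counts.astype(np.int64), gene_ids, cell_ids, list(labels))


class MtxParseError(ValueError):
    """Malformed on-disk dataset (bad MTX header or mismatched sidecars)."""


def write_mtx(cm: CountMatrix, path: str | Path) -> Path:
    """Write a CountMatrix to ``path`` as matrix.mtx + genes/barcodes/labels TSVs.

    ``matrix.mtx`` holds the sparse counts in Matrix Market coordinate integer
    format; one-column sidecars hold gene ids, cell ids and (if present)
    per-cell labels, one entry per line with no header.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(path / "matrix.mtx", sp.coo_matrix(cm.counts), field="integer")
    (path / "genes.tsv").write_text("".join(f"{g}\n" for g in cm.gene_ids))
    (path / "barcodes.tsv").write_text("".join(f"{c}\n" for c in cm.cell_ids))
    if cm.labels is not None:
        (path / "labels.tsv").write_text("".join(f"{l}\n" for l in cm.labels))
    return path


def _read_lines(p: Path) -> list[str]:
    return [line.rstrip("\n") for line in p.read_text().splitlines()]


def read_mtx(path: str | Path) -> CountMatrix:
    """Read a CountMatrix written by :func:`write_mtx`; exact round-trip."""
    path = Path(path)
    mtx_file = path / "matrix.mtx"
    if not mtx_file.exists():
        raise MtxParseError(f"{mtx_file} not found")
    try:
        mat = scipy.io.mmread(mtx_file)
    except ValueError as exc:  # scipy reports the offending line
        raise MtxParseError(f"malformed MTX file {mtx_file}: {exc}") from exc
    counts = np.asarray(sp.coo_matrix(mat).todense())
    gene_ids = _read_lines(path / "genes.tsv")
    cell_ids = _read_lines(path / "barcodes.tsv")
    if len(gene_ids) != counts.shape[0]:
        raise MtxParseError(
            f"MTX declares {counts.shape[0]} genes (header line 2 of {mtx_file}) "
            f"but genes.tsv has {len(gene_ids)} rows"
        )
    if len(cell_ids) != counts.shape[1]:
        raise MtxParseError(
            f"MTX declares {counts.shape[1]} cells (header line 2 of {mtx_file}) "
            f"but barcodes.tsv has {len(cell_ids)} rows"
        )
    labels = None
    if (path / "labels.tsv").exists():
        labels = _read_lines(path / "labels.tsv")
        if len(labels) != counts.shape[1]:
            raise MtxParseError(
                f"labels.tsv has {len(labels)} rows for {counts.shape[1]} cells"
            )
    return CountMatrix(counts, gene_ids, cell_ids, labels)


def write_csv(cm: CountMatrix, path: str | Path) -> Path:
    """Dense CSV alternative: genes as rows, header row of cell ids.

    Labels, if present, go in a ``<stem>.labels.tsv`` sidecar.
    """
    path = Path(path)
    df = pd.DataFrame(cm.counts, index=cm.gene_ids, columns=cm.cell_ids)
    df.to_csv(path)
    if cm.labels is not None:
        path.with_suffix(".labels.tsv").write_text("".join(f"{l}\n" for l in cm.labels))
    return path


def read_csv(path: str | Path) -> CountMatrix:
    path = Path(path)
    df = pd.read_csv(path, index_col=0)
    labels_file = path.with_suffix(".labels.tsv")
    labels = _read_lines(labels_file) if labels_file.exists() else None
    return CountMatrix(
        df.to_numpy(), [str(g) for g in df.index], [str(c) for c in df.columns], labels
    )
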