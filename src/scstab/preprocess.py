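"""Library-size log-normalisation of raw counts.

The single supported convention: per-cell size factor = library size divided
by the mean library size over cells with nonzero counts; normalised value =
log(count / size_factor + pseudocount) in base 2 (default) or e.  Cells with
zero library size are left as all-zero columns with a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .synthdata import CountMatrix

__all__ = ["NormalizedMatrix", "LogNormalizer", "log_normalise"]


@dataclass
class NormalizedMatrix:
    """Log-normalised expression (genes x cells) with carried-through metadata."""

    values: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]
    labels: Optional[list[str]] = None
    pseudocount: float = 1.0
    log_base: float = 2.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.cell_ids)} cells"
            )
        if self.labels is not None and len(self.labels) != len(self.cell_ids):
            raise ValueError("labels length does not match number of cells")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    @property
    def X(self) -> np.ndarray:
        """Cells x genes view (the sklearn orientation)."""
        return self.values.T


class LogNormalizer(TransformerMixin, BaseEstimator):
    """Size-factor log transform of raw counts, sklearn-style.

    Operates on the sklearn orientation (cells as samples, genes as
    features).  ``fit`` computes per-cell size factors from the library sizes
    of ``X``; ``transform`` must be called on the same cells.

    Parameters
    ----------
    pseudocount : float, default=1.0
        Added inside the log; >= 1 keeps all outputs non-negative.
    log_base : {2, "e"}, default=2
        Base of the logarithm.
    """

    def __init__(self, pseudocount: float = 1.0, log_base=2):
        self.pseudocount = pseudocount
        self.log_base = log_base

    def _validate(self, X) -> np.ndarray:
        X = check_array(X, dtype=float, ensure_min_samples=1)
        if X.size == 0:
            raise ValueError("empty matrix")
        if np.any(X < 0):
            raise ValueError("counts must be non-negative")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be positive")
        if self.log_base not in (2, "e", np.e):
            raise ValueError("log_base must be 2 or 'e'")
        return X

    def fit(self, X, y=None):
        X = self._validate(X)
        libsize = X.sum(axis=1)
        nonzero = libsize > 0
        if not np.any(nonzero):
            raise ValueError("all cells have zero library size")
        if not np.all(nonzero):
            warnings.warn(
                f"{int((~nonzero).sum())} cell(s) with zero library size; "
                "their normalised columns are all zero",
                UserWarning,
            )
        factors = np.ones_like(libsize)
        factors[nonzero] = libsize[nonzero] / libsize[nonzero].mean()
        self.size_factors_ = factors
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "size_factors_")
        X = self._validate(X)
        if X.shape[0] != self.size_factors_.shape[0]:
            raise ValueError("transform must see the same cells as fit")
        scaled = X / self.size_factors_[:, np.newaxis]
        base = np.e if self.log_base in ("e", np.e) else float(self.log_base)
        out = np.log(scaled + self.pseudocount) / np.log(base)
        out[X.sum(axis=1) == 0, :] = 0.0
        return out


def log_normalise(cm: CountMatrix, pseudocount: float = 1.0, log_base=2) -> NormalizedMatrix:
    """Log-normalise a raw :class:`CountMatrix` (genes x cells)."""
    values = (
        LogNormalizer(pseudocount=pseudocount, log_base=log_base)
        .fit_transform(cm.counts.T)
        .T
    )
    return NormalizedMatrix(
        values=values,
        gene_ids=cm.gene_ids,
        cell_ids=cm.cell_ids,
        labels=cm.labels,
        pseudocount=pseudocount,
        log_base=np.e if log_base in ("e", np.e) else float(log_base),
    )
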