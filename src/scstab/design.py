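"""The four-setting benchmark sampling design over a labelled cell pool.

Datasets are subsampled without replacement from a labelled selection pool
(cell types with <= 300 cells are excluded first).  The four settings:

* ``type_sweep`` — 5..20 cell types, 200 cells each: 16 x 10 replicates = 160
  datasets.
* ``cell_sweep`` — {5, 10, 15, 20} types x {50, 100, 150, 200, 250} cells per
  type: 4 x 5 x 10 = 200 datasets.
* ``imbalance`` — {10, 20} types split into equal major/minor halves; major
  types hold 200 cells, minor {100, 50, 20} (imbalance ratios 2:1, 4:1,
  10:1): 2 x 3 x 10 = 60 datasets.
* ``large_n`` — {5, 10} types x {500, 1000} cells per type, drawn from each
  of two pool sources: 2 x 2 x 2 x 10 = 80 datasets.

Each configuration carries a deterministic seed derived from its fields, so
the whole design is reproducible from a single base seed.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from .synthdata import CountMatrix

__all__ = ["DesignConfig", "SampledDataset", "filter_pool", "enumerate_design",
           "sample_dataset", "SETTINGS", "design_to_frame"]

SETTINGS = ("type_sweep", "cell_sweep", "imbalance", "large_n")

_TYPE_SWEEP_RANGE = range(5, 21)
_CELL_SWEEP_TYPES = (5, 10, 15, 20)
_CELL_SWEEP_CELLS = (50, 100, 150, 200, 250)
_IMBALANCE_TYPES = (10, 20)
_IMBALANCE_MINOR = (100, 50, 20)
_LARGE_N_TYPES = (5, 10)
_LARGE_N_CELLS = (500, 1000)
_SOURCES = ("pool_a", "pool_b")
_N_REPLICATES = 10


def derive_seed(base_seed: int, *fields_) -> int:
    """Deterministic per-configuration seed from the base seed and config fields."""
    key = "|".join(str(f) for f in fields_).encode()
    return (int(base_seed) + zlib.crc32(key)) % (2**31)


@dataclass(frozen=True)
class DesignConfig:
    """One sampled-dataset recipe within a benchmark setting."""

    setting: str
    n_types: int
    cells_per_major_type: int
    cells_per_minor_type: Optional[int] = None
    source: str = "pool_a"
    replicate: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.setting not in SETTINGS:
            raise ValueError(f"unknown setting {self.setting!r}; valid: {SETTINGS}")
        if not 1 <= self.replicate <= _N_REPLICATES:
            raise ValueError(f"replicate must be in [1, {_N_REPLICATES}]")
        s = self.setting
        if s == "type_sweep":
            if self.n_types not in _TYPE_SWEEP_RANGE:
                raise ValueError("type_sweep requires n_types in [5, 20]")
            if self.cells_per_major_type != 200 or self.cells_per_minor_type is not None:
                raise ValueError("type_sweep fixes 200 cells per type, no minor count")
        elif s == "cell_sweep":
            if self.n_types not in _CELL_SWEEP_TYPES:
                raise ValueError(f"cell_sweep requires n_types in {_CELL_SWEEP_TYPES}")
            if self.cells_per_major_type not in _CELL_SWEEP_CELLS:
                raise ValueError(f"cell_sweep requires cells per type in {_CELL_SWEEP_CELLS}")
            if self.cells_per_minor_type is not None:
                raise ValueError("cell_sweep has no minor count")
        elif s == "imbalance":
            if self.n_types not in _IMBALANCE_TYPES:
                raise ValueError(f"imbalance requires n_types in {_IMBALANCE_TYPES}")
            if self.cells_per_major_type != 200:
                raise ValueError("imbalance fixes major types at 200 cells")
            if self.cells_per_minor_type not in _IMBALANCE_MINOR:
                raise ValueError(f"imbalance requires minor cells in {_IMBALANCE_MINOR}")
        elif s == "large_n":
            if self.n_types not in _LARGE_N_TYPES:
                raise ValueError(f"large_n requires n_types in {_LARGE_N_TYPES}")
            if self.cells_per_major_type not in _LARGE_N_CELLS:
                raise ValueError(f"large_n requires cells per type in {_LARGE_N_CELLS}")
            if self.cells_per_minor_type is not None:
                raise ValueError("large_n has no minor count")
        if self.source not in _SOURCES:
            raise ValueError(f"source must be one of {_SOURCES}")

    @property
    def n_cells_total(self) -> int:
        if self.setting == "imbalance":
            n_major = self.n_types // 2
            n_minor = self.n_types - n_major
            return n_major * self.cells_per_major_type + n_minor * self.cells_per_minor_type
        return self.n_types * self.cells_per_major_type


@dataclass
class SampledDataset:
    config: DesignConfig
    data: CountMatrix
    true_k: int

    def __post_init__(self) -> None:
        if self.data.labels is None:
            raise ValueError("sampled dataset must carry labels")
        n_distinct = len(set(self.data.labels))
        if n_distinct != self.true_k or self.true_k != self.config.n_types:
            raise ValueError(
                f"label count {n_distinct} != true_k {self.true_k} != "
                f"config.n_types {self.config.n_types}"
            )


def filter_pool(pool: CountMatrix, min_cells_exclusive: int = 300) -> CountMatrix:
    """Keep only cell types with strictly more than ``min_cells_exclusive`` cells."""
    if pool.labels is None:
        raise ValueError("pool must carry per-cell type labels")
    labels = np.asarray(pool.labels)
    types, counts = np.unique(labels, return_counts=True)
    keep_types = set(types[counts > min_cells_exclusive])
    if not keep_types:
        raise ValueError(
            f"no cell type has more than {min_cells_exclusive} cells; nothing survives"
        )
    keep_idx = np.flatnonzero(np.isin(labels, list(keep_types)))
    return pool.subset_cells(keep_idx)


def enumerate_design(setting: str, base_seed: int = 0) -> list[DesignConfig]:
    """All configurations of a setting crossed with replicates 1..10."""
    if setting not in SETTINGS:
        raise ValueError(f"unknown setting {setting!r}; valid settings: {SETTINGS}")
    configs: list[DesignConfig] = []

    def add(**kw) -> None:
        seed = derive_seed(base_seed, kw["setting"], kw["n_types"],
                           kw["cells_per_major_type"], kw.get("cells_per_minor_type"),
                           kw.get("source", "pool_a"), kw["replicate"])
        configs.append(DesignConfig(seed=seed, **kw))

    if setting == "type_sweep":
        for t in _TYPE_SWEEP_RANGE:
            for r in range(1, _N_REPLICATES + 1):
                add(setting=setting, n_types=t, cells_per_major_type=200, replicate=r)
    elif setting == "cell_sweep":
        for t in _CELL_SWEEP_TYPES:
            for c in _CELL_SWEEP_CELLS:
                for r in range(1, _N_REPLICATES + 1):
                    add(setting=setting, n_types=t, cells_per_major_type=c, replicate=r)
    elif setting == "imbalance":
        for t in _IMBALANCE_TYPES:
            for minor in _IMBALANCE_MINOR:
                for r in range(1, _N_REPLICATES + 1):
                    add(setting=setting, n_types=t, cells_per_major_type=200,
                        cells_per_minor_type=minor, replicate=r)
    elif setting == "large_n":
        for src in _SOURCES:
            for t in _LARGE_N_TYPES:
                for c in _LARGE_N_CELLS:
                    for r in range(1, _N_REPLICATES + 1):
                        add(setting=setting, n_types=t, cells_per_major_type=c,
                            source=src, replicate=r)
    return configs


def design_to_frame(configs: list[DesignConfig]) -> pd.DataFrame:
    """Export a design enumeration as a table (one row per configuration)."""
    return pd.DataFrame([
        {
            "setting": c.setting, "n_types": c.n_types,
            "cells_per_major_type": c.cells_per_major_type,
            "cells_per_minor_type": c.cells_per_minor_type,
            "source": c.source, "replicate": c.replicate, "seed": c.seed,
            "n_cells_total": c.n_cells_total,
        }
        for c in configs
    ])


def sample_dataset(pool: CountMatrix, config: DesignConfig) -> SampledDataset:
    """Draw one benchmark dataset from a filtered pool per the configuration.

    Selects ``n_types`` cell types uniformly without replacement, then the
    configured number of cells per type without replacement, preserving raw
    counts.  In the imbalance setting the first half of the sampled type
    order becomes the major group (200 cells), the second half minor.
    """
    if pool.labels is None:
        raise ValueError("pool must carry per-cell type labels")
    rng = np.random.default_rng(config.seed)
    labels = np.asarray(pool.labels)
    types = np.unique(labels)
    if len(types) < config.n_types:
        raise ValueError(
            f"pool has {len(types)} cell types but the configuration needs {config.n_types}"
        )
    chosen = rng.choice(types, size=config.n_types, replace=False)

    if config.setting == "imbalance":
        n_major = config.n_types // 2
        per_type = [config.cells_per_major_type] * n_major + \
                   [config.cells_per_minor_type] * (config.n_types - n_major)
    else:
        per_type = [config.cells_per_major_type] * config.n_types

    idx_all: list[np.ndarray] = []
    for t, want in zip(chosen, per_type):
        avail = np.flatnonzero(labels == t)
        if len(avail) < want:
            raise ValueError(
                f"cell type {t!r} has {len(avail)} cells; configuration needs {want} "
                f"(deficit {want - len(avail)})"
            )
        idx_all.append(rng.choice(avail, size=want, replace=False))
    idx = np.concatenate(idx_all)
    data = pool.subset_cells(idx)
    return SampledDataset(config=config, data=data, true_k=config.n_types)
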