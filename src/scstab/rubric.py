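"""Good / intermediate / poor performance categorisation.

Five criteria summarise a method's behaviour over a benchmark run: magnitude
of the relative deviation of the estimated cluster number from the truth,
standard deviation of the estimates, mean clustering concordance (average of
ARI/NMI/FM/Jaccard against the reference labels), and externally measured
run time and peak memory.  Each criterion has a "good" cutoff and a "poor"
cutoff; values at a boundary take the adjacent better category for the good
cutoff and the worse for the poor cutoff (<= good -> good, >= poor -> poor,
else intermediate; concordance runs the other way: >= 0.7 good, <= 0.5
poor).  Methods are ranked by (number of good, number of intermediate)
criteria, descending.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

__all__ = ["CriterionThresholds", "PerformanceSummary", "categorize", "summarise",
           "CRITERIA"]

CRITERIA = ("deviation", "sd", "concordance", "time_s", "memory_gb")

GOOD, INTERMEDIATE, POOR, NOT_ASSESSED = "good", "intermediate", "poor", "not assessed"


@dataclass(frozen=True)
class CriterionThresholds:
    """Cutoffs for the five criteria (defaults are the benchmark's)."""

    deviation_good: float = 0.20
    deviation_poor: float = 0.50
    sd_good: float = 2.0
    sd_poor: float = 5.0
    concordance_good: float = 0.7
    concordance_poor: float = 0.5
    time_good_s: float = 120.0
    time_poor_s: float = 360.0
    mem_good_gb: float = 4.0
    mem_poor_gb: float = 8.0

    def __post_init__(self) -> None:
        for good, poor, name in [
            (self.deviation_good, self.deviation_poor, "deviation"),
            (self.sd_good, self.sd_poor, "sd"),
            (self.time_good_s, self.time_poor_s, "time"),
            (self.mem_good_gb, self.mem_poor_gb, "memory"),
        ]:
            if not good < poor:
                raise ValueError(f"{name}: good bound must be stricter than poor bound")
        if not self.concordance_good > self.concordance_poor:
            raise ValueError("concordance: good bound must be stricter than poor bound")

    def bounds(self, criterion: str) -> tuple[float, float, bool]:
        """(good cutoff, poor cutoff, higher_is_better) for a criterion."""
        table = {
            "deviation": (self.deviation_good, self.deviation_poor, False),
            "sd": (self.sd_good, self.sd_poor, False),
            "concordance": (self.concordance_good, self.concordance_poor, True),
            "time_s": (self.time_good_s, self.time_poor_s, False),
            "memory_gb": (self.mem_good_gb, self.mem_poor_gb, False),
        }
        if criterion not in table:
            raise ValueError(f"unknown criterion {criterion!r}; valid: {CRITERIA}")
        return table[criterion]


DEFAULT_THRESHOLDS = CriterionThresholds()


def categorize(criterion: str, value: float,
               thresholds: CriterionThresholds = DEFAULT_THRESHOLDS) -> str:
    """Map one measured criterion value to good / intermediate / poor.

    ``deviation`` is judged by magnitude (over- and under-estimation deviate
    equally), so a signed relative deviation may be passed directly.
    """
    if not np.isfinite(value):
        raise ValueError(f"{criterion}: value must be finite, got {value}")
    good, poor, higher_better = thresholds.bounds(criterion)
    if criterion == "deviation":
        value = abs(value)
    if higher_better:
        if value >= good:
            return GOOD
        if value <= poor:
            return POOR
        return INTERMEDIATE
    if value <= good:
        return GOOD
    if value >= poor:
        return POOR
    return INTERMEDIATE


@dataclass
class PerformanceSummary:
    """Per-criterion categories plus the (good, intermediate) rank key."""

    categories: dict
    values: dict
    rank_key: tuple[int, int] = field(init=False)

    def __post_init__(self) -> None:
        assessed = [c for c in self.categories.values() if c != NOT_ASSESSED]
        self.rank_key = (
            sum(c == GOOD for c in assessed),
            sum(c == INTERMEDIATE for c in assessed),
        )


def summarise(records: Sequence[Mapping[str, float]],
              time_s: Optional[float] = None, memory_gb: Optional[float] = None,
              thresholds: CriterionThresholds = DEFAULT_THRESHOLDS) -> PerformanceSummary:
    """Average per-dataset evaluation records and categorise every criterion.

    ``records`` holds one mapping per dataset with any of the keys
    ``relative_deviation``, ``sd``, ``concordance`` (mean of the four indices
    for that dataset).  Deviation magnitudes are averaged.  Run time and peak
    memory are externally measured scalars; criteria with no measurement are
    marked "not assessed" and excluded from the rank key.
    """
    if not records:
        raise ValueError("records must be non-empty")

    def mean_of(key: str, transform=lambda x: x) -> Optional[float]:
        vals = [transform(r[key]) for r in records if key in r and r[key] is not None]
        return float(np.mean(vals)) if vals else None

    values = {
        "deviation": mean_of("relative_deviation", abs),
        "sd": mean_of("sd"),
        "concordance": mean_of("concordance"),
        "time_s": time_s,
        "memory_gb": memory_gb,
    }
    categories = {
        crit: (NOT_ASSESSED if values[crit] is None
               else categorize(crit, values[crit], thresholds))
        for crit in CRITERIA
    }
    return PerformanceSummary(categories=categories, values=values)
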