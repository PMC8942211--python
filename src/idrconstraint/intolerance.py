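"""Median-threshold classification of mutation-intolerant and -tolerant IDRs.

For each of the four protein-changing mutation types, the median pathogenic
and population counts over all IDRs serve as the expected frequencies. An
IDR is intolerant to a mutation type when (i) its pathogenic count exceeds
its population count, (ii) its pathogenic count is at/above the pathogenic
median, and (iii) its population count is at/below the population median.
Tolerant is the mirror image. Condition (i) makes the two verdicts mutually
exclusive for any region.

The default ("non_strict") reading of condition (ii) uses >=; a strict
reading (>) is available via ``mode``. Thresholds are normally recomputed
from the supplied cohort but can be pinned, e.g. to the published values
(:data:`PUBLISHED_THRESHOLDS`: pathogenic medians 2/2/2/2, population medians
22 for missense and 2 otherwise).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .annotation_model import PROTEIN_CHANGING_TYPES
from .variant_burden import RegionVariantCounts

VERDICTS = ("intolerant", "tolerant", "neither")
MODES = ("non_strict", "strict")


@dataclass(frozen=True)
class IntoleranceThresholds:
    """Per-type median pathogenic and population counts (the expectations)."""

    median_pathogenic: dict[str, float]
    median_population: dict[str, float]


#: Published cohort medians: pathogenic 2 for every type; population 22 for
#: missense and 2 for nonsense/frameshift/inframe.
PUBLISHED_THRESHOLDS = IntoleranceThresholds(
    median_pathogenic={v: 2.0 for v in PROTEIN_CHANGING_TYPES},
    median_population={
        "missense": 22.0,
        "nonsense": 2.0,
        "frameshift": 2.0,
        "inframe": 2.0,
    },
)


@dataclass(frozen=True)
class IntoleranceCall:
    region_id: str
    verdicts: dict[str, str]  # vtype -> intolerant | tolerant | neither
    overall: str

    def intolerant_types(self) -> tuple[str, ...]:
        return tuple(v for v in PROTEIN_CHANGING_TYPES if self.verdicts[v] == "intolerant")


def compute_thresholds(counts: Sequence[RegionVariantCounts]) -> IntoleranceThresholds:
    """Medians over all supplied regions (zero-count regions included)."""
    if not counts:
        raise ValueError("cannot compute thresholds from an empty region set")
    return IntoleranceThresholds(
        median_pathogenic={
            v: float(np.median([c.pathogenic[v] for c in counts]))
            for v in PROTEIN_CHANGING_TYPES
        },
        median_population={
            v: float(np.median([c.population[v] for c in counts]))
            for v in PROTEIN_CHANGING_TYPES
        },
    )


def _meets(n_hi: int, n_lo: int, med_hi: float, med_lo: float, mode: str) -> bool:
    """The three conditions with n_hi as the side expected to be elevated."""
    cond_ii = n_hi > med_hi if mode == "strict" else n_hi >= med_hi
    return n_hi > n_lo and cond_ii and n_lo <= med_lo


def classify_region(
    c: RegionVariantCounts,
    t: IntoleranceThresholds,
    mode: str = "non_strict",
) -> IntoleranceCall:
    """Apply the three-condition rule per mutation type.

    The overall label is "intolerant" if any type is intolerant, else
    "tolerant" if any type is tolerant, else "neither"; intolerance always
    dominates.
    """
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}")
    verdicts: dict[str, str] = {}
    for vtype in PROTEIN_CHANGING_TYPES:
        n_path = c.pathogenic[vtype]
        n_pop = c.population[vtype]
        med_path = t.median_pathogenic[vtype]
        med_pop = t.median_population[vtype]
        if _meets(n_path, n_pop, med_path, med_pop, mode):
            verdicts[vtype] = "intolerant"
        elif _meets(n_pop, n_path, med_pop, med_path, mode):
            verdicts[vtype] = "tolerant"
        else:
            verdicts[vtype] = "neither"
    if any(v == "intolerant" for v in verdicts.values()):
        overall = "intolerant"
    elif any(v == "tolerant" for v in verdicts.values()):
        overall = "tolerant"
    else:
        overall = "neither"
    return IntoleranceCall(region_id=c.region_id, verdicts=verdicts, overall=overall)


def classify_all(
    counts: Sequence[RegionVariantCounts],
    thresholds: IntoleranceThresholds | None = None,
    mode: str = "non_strict",
) -> list[IntoleranceCall]:
    """Classify every region; thresholds default to the cohort's own medians."""
    t = thresholds if thresholds is not None else compute_thresholds(counts)
    return [classify_region(c, t, mode=mode) for c in counts]


@dataclass(frozen=True)
class CallSummary:
    n_intolerant_per_type: dict[str, int]
    intolerant_ids: tuple[str, ...]
    tolerant_ids: tuple[str, ...]


def summarize_calls(calls: Sequence[IntoleranceCall]) -> CallSummary:
    """Per-type intolerant counts and the overall intolerant/tolerant id sets
    (sorted by region id for stable output)."""
    per_type = {
        v: sum(1 for c in calls if c.verdicts[v] == "intolerant")
        for v in PROTEIN_CHANGING_TYPES
    }
    return CallSummary(
        n_intolerant_per_type=per_type,
        intolerant_ids=tuple(sorted(c.region_id for c in calls if c.overall == "intolerant")),
        tolerant_ids=tuple(sorted(c.region_id for c in calls if c.overall == "tolerant")),
    )
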