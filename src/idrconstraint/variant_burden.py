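"""Variant-to-region mapping and population/pathogenic burden statistics.

Each variant is anchored at a single residue (the first affected residue for
indels) and contributes to every region containing that residue — nested or
overlapping regions each count it, so region counts are not additive across
rows. Pathogenic counts include only pathogenic/likely-pathogenic records;
benign and uncertain-significance records are kept for the clinical-class
breakdown but never counted as pathogenic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .annotation_model import (
    PROTEIN_CHANGING_TYPES,
    AnnotationError,
    DisorderRegion,
    ResiduePartition,
    VariantRecord,
)
from .feature_enrichment import ContingencyTable, EnrichmentResult, enrich_table

AC_STRATA = ("all", "singleton", "multiton")
LENGTH_STRATA = ("short", "medium", "long")


@dataclass
class RegionVariantCounts:
    """Pathogenic and population variant counts for one IDR (one table row)."""

    region_id: str
    pathogenic: dict[str, int] = field(
        default_factory=lambda: {v: 0 for v in PROTEIN_CHANGING_TYPES}
    )
    population: dict[str, int] = field(
        default_factory=lambda: {v: 0 for v in PROTEIN_CHANGING_TYPES}
    )
    n_syn_population: int = 0

    @property
    def n_mis_population(self) -> int:
        return self.population["missense"]


@dataclass
class PartitionVariantTotals:
    """DR/NR variant totals: per vtype/source, and per allele-count stratum
    for the population missense/synonymous association."""

    population_dr: dict[str, int]
    population_nr: dict[str, int]
    pathogenic_dr: dict[str, int]
    pathogenic_nr: dict[str, int]
    # (stratum, vtype in {missense, synonymous}, dr/nr) -> count
    mis_syn: dict[tuple[str, str, str], int]


@dataclass
class BurdenSummary:
    stratum: str
    n_regions: int
    n_defined: int
    mean: float
    median: float
    max: float


def assign_variants(
    regions: Sequence[DisorderRegion],
    partition: ResiduePartition,
    variants: Sequence[VariantRecord],
) -> tuple[list[RegionVariantCounts], PartitionVariantTotals]:
    """Map variants onto regions and onto the DR/NR residue partition.

    Returns one :class:`RegionVariantCounts` per input region (input order
    preserved) and the partition-level totals. A variant outside its
    protein's length raises :class:`AnnotationError`.
    """
    counts = {r.region_id: RegionVariantCounts(region_id=r.region_id) for r in regions}
    ordered = [counts[r.region_id] for r in regions]
    by_acc: dict[str, list[DisorderRegion]] = {}
    for r in regions:
        by_acc.setdefault(r.accession, []).append(r)

    totals = PartitionVariantTotals(
        population_dr={v: 0 for v in PROTEIN_CHANGING_TYPES},
        population_nr={v: 0 for v in PROTEIN_CHANGING_TYPES},
        pathogenic_dr={v: 0 for v in PROTEIN_CHANGING_TYPES},
        pathogenic_nr={v: 0 for v in PROTEIN_CHANGING_TYPES},
        mis_syn={
            (s, v, side): 0
            for s in AC_STRATA
            for v in ("missense", "synonymous")
            for side in ("dr", "nr")
        },
    )

    for v in variants:
        if v.accession not in partition.masks:
            continue
        mask = partition.masks[v.accession]
        if v.position > mask.size:
            raise AnnotationError(
                f"variant at {v.accession}:{v.position} beyond protein length "
                f"{mask.size}"
            )
        is_dr = bool(mask[v.position - 1])
        side = "dr" if is_dr else "nr"

        if v.source == "population":
            if v.vtype in ("missense", "synonymous"):
                totals.mis_syn[("all", v.vtype, side)] += 1
                stratum = "singleton" if (v.allele_count or 0) == 1 else "multiton"
                totals.mis_syn[(stratum, v.vtype, side)] += 1
            if v.vtype in PROTEIN_CHANGING_TYPES:
                (totals.population_dr if is_dr else totals.population_nr)[v.vtype] += 1
        elif v.significance == "pathogenic" and v.vtype in PROTEIN_CHANGING_TYPES:
            (totals.pathogenic_dr if is_dr else totals.pathogenic_nr)[v.vtype] += 1

        for region in by_acc.get(v.accession, ()):
            if not (region.start <= v.position <= region.end):
                continue
            c = counts[region.region_id]
            if v.source == "population":
                if v.vtype == "synonymous":
                    c.n_syn_population += 1
                elif v.vtype in PROTEIN_CHANGING_TYPES:
                    c.population[v.vtype] += 1
            elif v.significance == "pathogenic" and v.vtype in PROTEIN_CHANGING_TYPES:
                c.pathogenic[v.vtype] += 1

    return ordered, totals


def mis_syn_ratio(c: RegionVariantCounts) -> float | None:
    """Population missense/synonymous ratio; None when no synonymous variant
    was observed (such regions are excluded from summary statistics)."""
    if c.n_syn_population < 1:
        return None
    return c.n_mis_population / c.n_syn_population


def length_stratum(region: DisorderRegion) -> str:
    """short: length <= 30; medium: 30 < length <= 100; long: > 100."""
    if region.length <= 30:
        return "short"
    if region.length <= 100:
        return "medium"
    return "long"


def burden_summary(
    regions: Sequence[DisorderRegion], counts: Sequence[RegionVariantCounts]
) -> list[BurdenSummary]:
    """Per-stratum (and overall) summary of defined missense/synonymous ratios."""
    by_id = {c.region_id: c for c in counts}
    groups: dict[str, list[float]] = {s: [] for s in ("all",) + LENGTH_STRATA}
    sizes: dict[str, int] = {s: 0 for s in ("all",) + LENGTH_STRATA}
    for r in regions:
        stratum = length_stratum(r)
        sizes["all"] += 1
        sizes[stratum] += 1
        ratio = mis_syn_ratio(by_id[r.region_id])
        if ratio is not None:
            groups["all"].append(ratio)
            groups[stratum].append(ratio)
    out = []
    for stratum in ("all",) + LENGTH_STRATA:
        vals = groups[stratum]
        out.append(
            BurdenSummary(
                stratum=stratum,
                n_regions=sizes[stratum],
                n_defined=len(vals),
                mean=float(np.mean(vals)) if vals else float("nan"),
                median=float(np.median(vals)) if vals else float("nan"),
                max=float(np.max(vals)) if vals else float("nan"),
            )
        )
    return out


def population_association(
    totals: PartitionVariantTotals, ac_stratum: str = "all", alpha: float = 0.05
) -> EnrichmentResult:
    """Fisher association of missense vs synonymous population variants with
    disordered vs non-annotated residues, optionally within an allele-count
    stratum (singleton: AC = 1, multiton: AC > 1). A single test: m = 1."""
    if ac_stratum not in AC_STRATA:
        raise ValueError(f"unknown allele-count stratum {ac_stratum!r}")
    t = ContingencyTable(
        a=totals.mis_syn[(ac_stratum, "missense", "dr")],
        b=totals.mis_syn[(ac_stratum, "synonymous", "dr")],
        c=totals.mis_syn[(ac_stratum, "missense", "nr")],
        d=totals.mis_syn[(ac_stratum, "synonymous", "nr")],
    )
    return enrich_table(f"missense_vs_synonymous[{ac_stratum}]", t, m=1, alpha=alpha)


def clinical_class_fractions(
    variants: Sequence[VariantRecord], partition: ResiduePartition
) -> dict[str, dict[str, float]]:
    """Fractions of benign/vus/pathogenic per variant type among
    clinical-database variants whose anchor residue is disordered."""
    tallies: dict[str, dict[str, int]] = {
        v: {"benign": 0, "vus": 0, "pathogenic": 0} for v in PROTEIN_CHANGING_TYPES
    }
    for v in variants:
        if v.source != "pathogenic_db" or v.vtype not in PROTEIN_CHANGING_TYPES:
            continue
        if v.significance not in ("benign", "vus", "pathogenic"):
            continue
        if v.accession not in partition.masks:
            continue
        if partition.is_disordered(v.accession, v.position):
            tallies[v.vtype][v.significance] += 1
    out: dict[str, dict[str, float]] = {}
    for vtype, tally in tallies.items():
        n = sum(tally.values())
        out[vtype] = {k: (c / n if n else float("nan")) for k, c in tally.items()}
    return out


def counts_to_frame(
    regions: Sequence[DisorderRegion], counts: Sequence[RegionVariantCounts]
) -> pd.DataFrame:
    by_id = {c.region_id: c for c in counts}
    rows = []
    for r in regions:
        c = by_id[r.region_id]
        ratio = mis_syn_ratio(c)
        rows.append(
            {
                "region_id": r.region_id,
                "accession": r.accession,
                "gene": r.gene,
                "start": r.start,
                "end": r.end,
                "length": r.length,
                "stratum": length_stratum(r),
                **{f"{v}_pathogenic": c.pathogenic[v] for v in PROTEIN_CHANGING_TYPES},
                **{f"{v}_population": c.population[v] for v in PROTEIN_CHANGING_TYPES},
                "synonymous_population": c.n_syn_population,
                "mis_syn_ratio": float("nan") if ratio is None else ratio,
            }
        )
    return pd.DataFrame(rows)
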