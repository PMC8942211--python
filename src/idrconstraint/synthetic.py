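"""Synthetic proteomes with planted enrichment and intolerance ground truth.

The generator emulates the statistical structure of the real inputs — IDR
placement on proteins, per-residue feature annotation with a controllable
disordered-vs-ordered odds ratio per class, and per-residue variant counts
with planted pathogenic-enriched / population-depleted regions — so every
pipeline stage can be exercised, with known truth, without any download.

Models are deliberately minimal: features are per-residue Bernoulli (runs
merged into interval records), population variants per-residue Poisson,
pathogenic variants per-planted-region Poisson. Amino-acid composition and
mutational opportunity are not modelled.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .annotation_model import (
    FEATURE_CLASSES,
    PROTEIN_CHANGING_TYPES,
    DisorderRegion,
    FeatureAnnotation,
    ProteinRecord,
    ResiduePartition,
    VariantRecord,
    build_partition,
)


@dataclass(frozen=True)
class FeatureSpec:
    """Per-class planting parameters.

    ``rate`` is the per-residue Bernoulli rate on non-disordered residues;
    disordered residues use the rate whose odds are ``odds_ratio`` times the
    baseline odds. ``interval_length`` > 1 plants intervals of that length
    anchored at sampled start residues (for region-type classes).
    """

    rate: float = 0.02
    odds_ratio: float = 1.0
    interval_length: int = 1


@dataclass(frozen=True)
class VariantSpec:
    """Population and pathogenic variant rates.

    ``lambda_syn``: per-residue Poisson rate of population synonymous
    variants; missense uses ``rho_mis * lambda_syn``. ``lambda_other``:
    per-residue rate for population nonsense/frameshift/inframe variants.
    ``pathogenic_rates``: expected pathogenic count per planted-intolerant
    region per type (zero elsewhere). ``population_suppression`` scales all
    population rates inside planted regions (0 = fully depleted).
    """

    lambda_syn: float = 0.05
    rho_mis: float = 2.3
    lambda_other: float = 0.002
    pathogenic_rates: dict[str, float] = field(
        default_factory=lambda: {
            "missense": 5.0,
            "nonsense": 5.0,
            "frameshift": 6.0,
            "inframe": 4.0,
        }
    )
    population_suppression: float = 0.0


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for a synthetic dataset.

    Defaults are sized so the full pipeline runs in well under a minute:
    300 proteins of mean length ~600 carrying ~600 IDRs whose length mixture
    follows the observed short/medium/long proportions (~0.48/0.32/0.20).
    """

    n_proteins: int = 300
    protein_length_range: tuple[int, int] = (300, 900)
    regions_per_protein_range: tuple[int, int] = (1, 3)
    region_length_weights: tuple[float, float, float] = (0.476, 0.324, 0.200)
    region_length_ranges: tuple[tuple[int, int], ...] = ((5, 30), (31, 100), (101, 300))
    region_fraction: float = 0.65  # fraction of proteins that carry any IDR
    feature_spec: dict[str, FeatureSpec] = field(
        default_factory=lambda: {k: FeatureSpec() for k in FEATURE_CLASSES}
    )
    variant_spec: VariantSpec = field(default_factory=VariantSpec)
    n_intolerant_planted: int = 20
    seed: int = 0


@dataclass
class GroundTruth:
    planted_log_or: dict[str, float] = field(default_factory=dict)
    intolerant_region_ids: set[str] = field(default_factory=set)


@dataclass
class SyntheticDataset:
    proteins: list[ProteinRecord]
    regions: list[DisorderRegion]
    features: list[FeatureAnnotation]
    variants: list[VariantRecord]
    partition: ResiduePartition
    truth: GroundTruth
    config: SyntheticConfig


def _published_cohort_overrides() -> dict:
    """Marginals approximating the published cohort: ~945 regions with
    variant data, pathogenic medians near 2, population missense median near
    20; used by integration tests wanting realistic scale."""
    return dict(
        n_proteins=550,
        regions_per_protein_range=(1, 3),
        n_intolerant_planted=34,
        variant_spec=VariantSpec(lambda_syn=0.15, rho_mis=2.3, lambda_other=0.01),
    )


def published_cohort_config(seed: int = 0) -> SyntheticConfig:
    return replace(SyntheticConfig(seed=seed), **_published_cohort_overrides())


def simulate_proteome(
    config: SyntheticConfig,
) -> tuple[list[ProteinRecord], list[DisorderRegion]]:
    """Sample protein lengths and place IDRs uniformly within each protein.

    Regions never extend past the protein end; overlap between regions of
    one protein is permitted (placement is independent).
    """
    rng = np.random.default_rng(config.seed)
    lo, hi = config.protein_length_range
    max_region = max(r[1] for r in config.region_length_ranges)
    if max_region > lo:
        raise ValueError(
            f"region length range up to {max_region} exceeds minimum protein "
            f"length {lo}"
        )
    proteins = [
        ProteinRecord(f"SP{i:05d}", f"G{i:05d}", int(rng.integers(lo, hi + 1)))
        for i in range(config.n_proteins)
    ]
    regions: list[DisorderRegion] = []
    weights = np.asarray(config.region_length_weights, dtype=float)
    weights = weights / weights.sum()
    for p in proteins:
        if rng.random() > config.region_fraction:
            continue
        r_lo, r_hi = config.regions_per_protein_range
        n_regions = int(rng.integers(r_lo, r_hi + 1))
        for j in range(n_regions):
            stratum = int(rng.choice(len(weights), p=weights))
            s_lo, s_hi = config.region_length_ranges[stratum]
            length = int(rng.integers(s_lo, min(s_hi, p.length) + 1))
            start = int(rng.integers(1, p.length - length + 2))
            regions.append(
                DisorderRegion(
                    region_id=f"{p.accession}r{j:03d}",
                    accession=p.accession,
                    gene=p.gene,
                    start=start,
                    end=start + length - 1,
                )
            )
    return proteins, regions


def _planted_rate(rate: float, odds_ratio: float) -> float:
    if not (0 <= rate < 1):
        raise ValueError(f"rate saturation: baseline rate {rate} not in [0, 1)")
    odds = odds_ratio * rate / (1 - rate)
    return odds / (1 + odds)


def plant_features(
    proteins: Sequence[ProteinRecord],
    partition: ResiduePartition,
    feature_spec: dict[str, FeatureSpec],
    seed: int,
) -> tuple[list[FeatureAnnotation], GroundTruth]:
    """Plant per-residue feature annotations at class-specific DR/NR odds.

    With interval_length 1, each residue is annotated independently and
    maximal runs are merged into interval records; with interval_length L,
    anchor residues are sampled at rate/L and expanded L residues rightward
    (clipped at the protein end), keeping per-residue coverage near ``rate``.
    """
    rng = np.random.default_rng(seed)
    truth = GroundTruth()
    features: list[FeatureAnnotation] = []
    for klass in FEATURE_CLASSES:
        spec = feature_spec.get(klass, FeatureSpec(rate=0.0))
        truth.planted_log_or[klass] = float(np.log(spec.odds_ratio))
        if spec.rate <= 0:
            continue
        dr_rate = _planted_rate(spec.rate, spec.odds_ratio)
        for p in proteins:
            mask = partition.masks[p.accession]
            if spec.interval_length <= 1:
                u = rng.random(p.length)
                hit = u < np.where(mask, dr_rate, spec.rate)
            else:
                anchor_rate_nr = spec.rate / spec.interval_length
                anchor_rate_dr = dr_rate / spec.interval_length
                u = rng.random(p.length)
                anchors = np.nonzero(u < np.where(mask, anchor_rate_dr, anchor_rate_nr))[0]
                hit = np.zeros(p.length, dtype=bool)
                for a in anchors:
                    hit[a : a + spec.interval_length] = True
            if not hit.any():
                continue
            # merge maximal runs of annotated residues into intervals
            idx = np.nonzero(hit)[0]
            breaks = np.nonzero(np.diff(idx) > 1)[0]
            starts = np.concatenate(([idx[0]], idx[breaks + 1]))
            ends = np.concatenate((idx[breaks], [idx[-1]]))
            for s, e in zip(starts, ends):
                features.append(
                    FeatureAnnotation(p.accession, klass, int(s) + 1, int(e) + 1)
                )
    return features, truth


def simulate_variants(
    proteins: Sequence[ProteinRecord],
    regions: Sequence[DisorderRegion],
    partition: ResiduePartition,
    variant_spec: VariantSpec,
    planted_ids: set[str],
    seed: int,
) -> list[VariantRecord]:
    """Sample population and pathogenic variants.

    Population variants are per-residue Poisson (synonymous at lambda_syn,
    missense at rho_mis * lambda_syn, other types at lambda_other), with all
    rates multiplied by ``population_suppression`` inside planted regions.
    Pathogenic variants are Poisson per planted region per type, placed
    uniformly within the region. Allele counts are geometric, so singleton
    and multiton strata are both populated.
    """
    rng = np.random.default_rng(seed)
    variants: list[VariantRecord] = []
    planted_by_acc: dict[str, list[DisorderRegion]] = {}
    for r in regions:
        if r.region_id in planted_ids:
            planted_by_acc.setdefault(r.accession, []).append(r)

    pop_rates = {
        "synonymous": variant_spec.lambda_syn,
        "missense": variant_spec.rho_mis * variant_spec.lambda_syn,
        "nonsense": variant_spec.lambda_other,
        "frameshift": variant_spec.lambda_other,
        "inframe": variant_spec.lambda_other,
    }
    for p in proteins:
        suppress = np.ones(p.length)
        for r in planted_by_acc.get(p.accession, ()):
            suppress[r.start - 1 : r.end] = variant_spec.population_suppression
        for vtype, lam in pop_rates.items():
            if lam <= 0:
                continue
            counts = rng.poisson(lam * suppress)
            for pos in np.nonzero(counts)[0]:
                for _ in range(int(counts[pos])):
                    variants.append(
                        VariantRecord(
                            accession=p.accession,
                            position=int(pos) + 1,
                            vtype=vtype,
                            source="population",
                            allele_count=int(rng.geometric(0.5)),
                        )
                    )
    for r in regions:
        if r.region_id not in planted_ids:
            continue
        for vtype in PROTEIN_CHANGING_TYPES:
            lam = variant_spec.pathogenic_rates.get(vtype, 0.0)
            n = int(rng.poisson(lam))
            for _ in range(n):
                variants.append(
                    VariantRecord(
                        accession=r.accession,
                        position=int(rng.integers(r.start, r.end + 1)),
                        vtype=vtype,
                        source="pathogenic_db",
                        significance="pathogenic",
                    )
                )
    return variants


def generate_dataset(config: SyntheticConfig) -> SyntheticDataset:
    """Full deterministic dataset: proteome, partition, features, variants.

    Planted-intolerant regions are drawn uniformly from the generated
    regions; sub-seeds for each stage are derived from ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    feature_seed, variant_seed, choice_seed = (
        int(rng.integers(0, 2**31 - 1)) for _ in range(3)
    )
    proteins, regions = simulate_proteome(config)
    partition = build_partition(proteins, regions)
    features, truth = plant_features(proteins, partition, config.feature_spec, feature_seed)
    pick = np.random.default_rng(choice_seed)
    n_plant = min(config.n_intolerant_planted, len(regions))
    planted = (
        set(pick.choice([r.region_id for r in regions], size=n_plant, replace=False))
        if n_plant
        else set()
    )
    truth.intolerant_region_ids = planted
    variants = simulate_variants(
        proteins, regions, partition, config.variant_spec, planted, variant_seed
    )
    return SyntheticDataset(
        proteins=proteins,
        regions=regions,
        features=features,
        variants=variants,
        partition=partition,
        truth=truth,
        config=config,
    )
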