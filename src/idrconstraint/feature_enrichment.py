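"""Per-feature 2x2 enrichment over a binary residue partition.

For each of the 25 feature classes, the counts of class-A and class-B
residues with and without the feature form a 2x2 table; a two-sided Fisher's
exact test quantifies the association. The sample (cross-product) odds ratio
OR = (a*d)/(b*c) is reported, with a Woolf log-normal 95% CI, and p-values
are Bonferroni-corrected across the 25 tests (q = p * 25, capped at 1).

The same machinery serves the disordered-vs-non-annotated residue contrast
and the mutation-intolerant-vs-tolerant IDR-residue contrast; class A is the
first partition class (DR, or intolerant) throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.special import gammaln, logsumexp
from scipy.stats import norm

from .annotation_model import (
    CATEGORY_AXES,
    FEATURE_CLASSES,
    DisorderRegion,
    FeatureAnnotation,
    ResiduePartition,
)

#: Reported q-values are floored here (more significant values are reported
#: at the floor with a flag); the exact value is retained internally.
Q_REPORT_FLOOR = 1e-100


class DegenerateTableError(ValueError):
    """A margin of the 2x2 table is zero; the exact test is uninformative."""


@dataclass(frozen=True)
class ContingencyTable:
    """Counts: a/b = class-A residues with/without the feature, c/d = class-B."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("negative cell count")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    def corrected_cells(self) -> tuple[float, float, float, float]:
        """Cells with the Haldane–Anscombe +0.5 applied iff any cell is zero."""
        cells = (self.a, self.b, self.c, self.d)
        if min(cells) == 0:
            return tuple(x + 0.5 for x in cells)  # type: ignore[return-value]
        return tuple(float(x) for x in cells)  # type: ignore[return-value]

    def _check_margins(self) -> None:
        if (
            self.a + self.b == 0
            or self.c + self.d == 0
            or self.a + self.c == 0
            or self.b + self.d == 0
        ):
            raise DegenerateTableError(f"degenerate table {self!r}")


@dataclass(frozen=True)
class EnrichmentResult:
    feature_class: str
    table: ContingencyTable
    odds_ratio: float
    ci_low: float
    ci_high: float
    p: float
    q: float
    q_exact: float
    q_floored: bool
    call: str  # class_A_enriched | class_B_enriched | none


def sample_odds_ratio(t: ContingencyTable) -> float:
    """Cross-product odds ratio on (possibly 0.5-corrected) cells."""
    a, b, c, d = t.corrected_cells()
    return (a * d) / (b * c)


def fisher_exact_two_sided(t: ContingencyTable) -> tuple[float, float]:
    """Two-sided Fisher's exact test.

    p is the sum, over all tables with the observed margins, of
    hypergeometric probabilities no larger than that of the observed table
    (the probability-mass rule), accumulated in log space so that extreme
    tables do not underflow. Returns (sample OR, p).
    """
    t._check_margins()
    r1 = t.a + t.b
    c1 = t.a + t.c
    n = t.total
    support = np.arange(max(0, r1 + c1 - n), min(r1, c1) + 1)
    # log hypergeometric pmf over the full support
    logpmf = (
        gammaln(c1 + 1)
        - gammaln(support + 1)
        - gammaln(c1 - support + 1)
        + gammaln(n - c1 + 1)
        - gammaln(r1 - support + 1)
        - gammaln(n - c1 - (r1 - support) + 1)
        - (gammaln(n + 1) - gammaln(r1 + 1) - gammaln(n - r1 + 1))
    )
    log_obs = logpmf[int(t.a - support[0])]
    # tables at most as probable as the observed one, with slack for rounding
    include = logpmf <= log_obs + 1e-12
    p = float(np.exp(logsumexp(logpmf[include])))
    # keep p strictly positive for downstream log-scale reporting
    p = max(min(p, 1.0), 1e-300)
    return sample_odds_ratio(t), p


def woolf_ci(t: ContingencyTable, level: float = 0.95) -> tuple[float, float]:
    """Woolf log-normal CI for the odds ratio on (corrected) cells."""
    t._check_margins()
    a, b, c, d = t.corrected_cells()
    log_or = math.log((a * d) / (b * c))
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = float(norm.ppf((1 + level) / 2))
    return math.exp(log_or - z * se), math.exp(log_or + z * se)


def bonferroni(p: float, m: int = 25) -> tuple[float, float, bool]:
    """q = min(1, p * m); returns (reported q, exact q, floored flag).

    The reported q is floored at 1e-100 (the most significant value shown);
    the exact q is retained for downstream use.
    """
    if not (0 < p <= 1):
        raise ValueError(f"p must be in (0, 1], got {p}")
    if m < 1:
        raise ValueError("m must be >= 1")
    q_exact = min(1.0, p * m)
    floored = q_exact < Q_REPORT_FLOOR
    return (Q_REPORT_FLOOR if floored else q_exact, q_exact, floored)


def classify_association(odds_ratio: float, q: float, alpha: float = 0.05) -> str:
    if q < alpha and odds_ratio > 1:
        return "class_A_enriched"
    if q < alpha and odds_ratio < 1:
        return "class_B_enriched"
    return "none"


# ---------------------------------------------------------------------------
# Residue-level contingency construction


def _class_masks(
    features: Iterable[FeatureAnnotation], sizes: dict[str, int], feature_class: str
) -> dict[str, np.ndarray]:
    masks = {acc: np.zeros(size, dtype=bool) for acc, size in sizes.items()}
    for f in features:
        if f.feature_class != feature_class or f.accession not in masks:
            continue
        end = min(f.end, masks[f.accession].size)
        masks[f.accession][f.start - 1 : end] = True
    return masks


def contingency_for_feature(
    feature_class: str,
    partition: ResiduePartition,
    features: Sequence[FeatureAnnotation],
) -> ContingencyTable:
    """2x2 residue counts for one feature class over the partition.

    A residue "has" the feature iff covered by >= 1 annotation of that class;
    multiplicity within a class never double-counts a residue.
    """
    sizes = {acc: m.size for acc, m in partition.masks.items()}
    cov = _class_masks(features, sizes, feature_class)
    a = b = c = d = 0
    for acc, dr_mask in partition.masks.items():
        has = cov[acc]
        a += int(np.count_nonzero(dr_mask & has))
        b += int(np.count_nonzero(dr_mask & ~has))
        c += int(np.count_nonzero(~dr_mask & has))
        d += int(np.count_nonzero(~dr_mask & ~has))
    return ContingencyTable(a, b, c, d)


def enrich_table(
    feature_class: str, t: ContingencyTable, m: int = 25, alpha: float = 0.05
) -> EnrichmentResult:
    """Full enrichment result (OR, CI, p, q, call) for one 2x2 table."""
    odds_ratio, p = fisher_exact_two_sided(t)
    ci_low, ci_high = woolf_ci(t)
    q, q_exact, floored = bonferroni(p, m)
    return EnrichmentResult(
        feature_class=feature_class,
        table=t,
        odds_ratio=odds_ratio,
        ci_low=ci_low,
        ci_high=ci_high,
        p=p,
        q=q,
        q_exact=q_exact,
        q_floored=floored,
        call=classify_association(odds_ratio, q_exact, alpha),
    )


def enrichment_scan(
    partition: ResiduePartition,
    features: Sequence[FeatureAnnotation],
    m: int = 25,
    alpha: float = 0.05,
    classes: Sequence[str] = FEATURE_CLASSES,
) -> tuple[list[EnrichmentResult], dict[str, str]]:
    """Run the 25-feature enrichment scan over a residue partition.

    Returns (results, errors): feature classes whose table is degenerate
    (e.g. no residue carries the feature) are collected in ``errors`` rather
    than raising, so a sparse dataset never aborts the scan.
    """
    if partition.n_DR == 0 or partition.n_NR == 0:
        raise ValueError("both partition classes must be non-empty")
    results: list[EnrichmentResult] = []
    errors: dict[str, str] = {}
    for klass in classes:
        t = contingency_for_feature(klass, partition, features)
        try:
            results.append(enrich_table(klass, t, m=m, alpha=alpha))
        except DegenerateTableError as exc:
            errors[klass] = str(exc)
    return results, errors


# ---------------------------------------------------------------------------
# Median feature content by IDR category


def median_feature_content(
    regions: Sequence[DisorderRegion],
    features: Sequence[FeatureAnnotation],
    category_axis: str,
    classes: Sequence[str] = FEATURE_CLASSES,
):
    """Median fraction of region residues covered by each feature class,
    grouped by disorder-ontology category on the chosen axis.

    Content of a region = covered residues / region length. The median in a
    (feature, category) cell is taken over regions with >= 1 covered residue;
    ``n_regions`` counts those regions. Regions lacking a label on the axis
    are excluded; multi-valued labels (';'-separated) contribute to each of
    their categories. Returns a tidy DataFrame with columns feature_class,
    category, n_regions, median_content.
    """
    import pandas as pd

    if category_axis not in CATEGORY_AXES:
        raise ValueError(f"unknown category axis {category_axis!r}")
    sizes: dict[str, int] = {}
    for r in regions:
        sizes[r.accession] = max(sizes.get(r.accession, 0), r.end)
    for f in features:
        sizes[f.accession] = max(sizes.get(f.accession, 0), f.end)

    rows = []
    for klass in classes:
        cov = _class_masks(features, sizes, klass)
        cell: dict[str, list[float]] = {}
        for r in regions:
            label = r.category(category_axis)
            if not label:
                continue
            covered = int(cov[r.accession][r.start - 1 : r.end].sum())
            if covered == 0:
                continue
            content = covered / r.length
            for cat in (s.strip() for s in label.split(";")):
                if cat:
                    cell.setdefault(cat, []).append(content)
        for cat, contents in sorted(cell.items()):
            rows.append(
                {
                    "feature_class": klass,
                    "category": cat,
                    "n_regions": len(contents),
                    "median_content": float(np.median(contents)),
                }
            )
    return pd.DataFrame(rows, columns=["feature_class", "category", "n_regions", "median_content"])


def results_to_frame(results: Sequence[EnrichmentResult]):
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "feature_class": r.feature_class,
                "a": r.table.a,
                "b": r.table.b,
                "c": r.table.c,
                "d": r.table.d,
                "or": r.odds_ratio,
                "ci_low": r.ci_low,
                "ci_high": r.ci_high,
                "p": r.p,
                "q": r.q,
                "q_floored": r.q_floored,
                "call": r.call,
            }
            for r in results
        ]
    )
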