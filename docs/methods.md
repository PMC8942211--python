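# Methods

## Data model and coordinate conventions

All interfaces use 1-based inclusive residue coordinates (the UniProt and
DisProt convention); point sites have start = end. A protein residue is
**disordered (DR)** iff it is covered by at least one experimentally
annotated disordered region of that protein; all other residues of studied
proteins are **non-annotated (NR)**. No order/disorder prediction is
attempted for NR residues — they are simply "not annotated as disordered",
and in disorder-annotated proteomes they are mostly structured residues.
Regions of one protein may overlap or nest; the DR set is their union, so
duplicating a region row never changes the partition. Proteins referenced
by a region but missing from the protein table are rejected outright rather
than having a length inferred.

Variants are anchored at a single residue — for indels, the first affected
residue. A variant belongs to a region iff its anchor lies inside the
region; overlapping regions each receive it, so per-region counts are not
additive across rows. This anchor rule is a package choice for indels that
straddle a region boundary; no convention for such variants is established
in the source databases' protein-coordinate projections.

## Feature enrichment

For each of the 25 feature classes a 2×2 table is formed: (a) DR residues
covered by ≥ 1 annotation of the class, (b) DR residues not covered,
(c, d) likewise for NR. A residue with several annotations of one class
counts once; classes are tested independently.

* **Odds ratio.** The sample (cross-product) OR = (a·d)/(b·c). When any
  cell is zero, the Haldane–Anscombe correction (+0.5 on all four cells) is
  applied to the OR and CI. The conditional-MLE OR is *not* used: the
  published residue-level values are cross-product ORs (the printed
  missense/synonymous table gives 1.0728 → "1.1", the peptide table 5.50 →
  "5.5").
* **p-value.** Two-sided Fisher's exact test under the probability-mass
  rule: the sum over all tables with the observed margins whose
  hypergeometric probability is at most that of the observed table
  (relative slack 1e-12 for float rounding). The pmf is computed in log
  space via `gammaln` and accumulated with `logsumexp`, so extreme tables
  (p down to ~1e-300) do not underflow. The implementation is verified
  against exhaustive enumeration on every table with total ≤ 40 and against
  `scipy.stats.fisher_exact` on random tables.
* **Confidence interval.** Woolf log-normal:
  exp(ln OR ± z·√(1/a+1/b+1/c+1/d)) on the (possibly corrected) cells, z
  the standard-normal quantile at (1+level)/2. The CI construction behind
  the published figures is not documented, so CI bounds are a package
  choice and are validated only by coverage simulation (planted OR 3 at
  50k residues: ~95% coverage).
* **Multiple testing.** q = min(1, p·25), Bonferroni across the 25 classes.
  Reported q-values are floored at 1e-100 (flagged); the exact value is
  retained internally and used for classification. A feature is
  DR-associated when OR > 1 and q < 0.05, NR-associated when OR < 1 and
  q < 0.05. No FDR alternative is offered — the analysis is defined with
  Bonferroni.
* **Degenerate tables.** A zero margin (e.g. a feature class absent from
  the dataset) makes the exact test uninformative; `enrichment_scan`
  collects such classes as errors instead of crashing or emitting a
  meaningless OR.

The identical machinery serves the residue-level contrast between
mutation-intolerant and mutation-tolerant IDRs; residues in both an
intolerant and a tolerant region count as intolerant (intolerance
dominates), and unlabelled residues are excluded from that partition.

**Median feature content** (per disorder-ontology category axis) is the
median over regions, within a (feature, category) cell, of
covered-residues/region-length, restricted to regions with ≥ 1 covered
residue; the even-count median is the mean of the two central order
statistics (numpy's default). Multi-valued category labels
(";"-separated) contribute the region to each named category.

## Variant burden

Per-region ratios n_mis/n_syn use population counts only. Regions with no
synonymous variant have an undefined ratio and are excluded from means,
medians and maxima — the finite published maximum (12.0) implies unbounded
ratios were not part of those summaries. Length strata: short ≤ 30 <
medium ≤ 100 < long. The residue-level missense-vs-synonymous association
is a single Fisher test (m = 1) on (DR-mis, DR-syn, NR-mis, NR-syn),
optionally restricted to singleton (AC = 1) or multiton (AC > 1) population
variants first. Clinical-class fractions are computed per mutation type
over clinical-database variants anchored in DR residues only, with
"likely" labels folded into their parent class and unclassified records
excluded from the denominator.

## Intolerance rule

Thresholds are the per-type medians of pathogenic and of population counts
over all supplied IDRs (zero-count regions included). Verdict per type:

* intolerant: N^path > N^pop and N^path ⊵ median^path and N^pop ≤ median^pop
* tolerant: the three opposite conditions (N^pop > N^path, N^pop ⊵
  median^pop, N^path ≤ median^path)

where ⊵ is ≥ in the default `non_strict` mode and > in `strict` mode.
Non-strict is the default because the strict reading of the second
condition excludes several published intolerant regions whose qualifying
counts sit exactly at the median, while the non-strict reading reproduces
all 34 published rows and the published per-type missense (4) and inframe
(7) totals. Condition three is ≤ (at-or-below the median), as the rule is
stated. The first condition makes "intolerant" and "tolerant" mutually
exclusive for any region and type. The overall label is intolerant if any
type is intolerant; otherwise tolerant if any type is tolerant; otherwise
neither. Thresholds default to recomputation from the supplied cohort and
can be pinned (e.g. `PUBLISHED_THRESHOLDS`: pathogenic 2/2/2/2, population
22/2/2/2) for analyses of published count tables.

Reproduction note: applying either reading of the rule to the packaged
34-row table yields 25 frameshift- and 25 nonsense-intolerant regions,
not the published 24 and 21; those two totals cannot be derived from the
printed counts under any single consistent reading and are therefore
documented here but not asserted anywhere.

## Feature importance

Each labelled IDR contributes a 25-vector of annotation-record counts
(records overlapping ≥ 1 region residue, per class) and a binary label
with *intolerant* as the positive class. The classifier is a 100-tree
random forest with Gini splits (scikit-learn), seeded for determinism. The
score is average precision — with a ~34:533 class imbalance, accuracy is
uninformative — computed as AP = Σ_k (R_k − R_{k−1})·P_k over descending
score thresholds, with tied scores forming a single threshold group
(precision evaluated after the whole group). The implementation is checked
exhaustively against a brute-force definition and against
`sklearn.metrics.average_precision_score`.

Permutation importance shuffles one column at a time (10 repeats by
default), recording the drop in AP in percentage points; negative drops
are retained, a constant column drops exactly 0, and features with mean
drop ≥ 5 points are flagged important. Importance is evaluated on the
training cohort by default, mirroring the published protocol (no
train/test split is documented for it); held-out evaluation is available
by splitting before `train_classifier`. Resubstitution importance ranks
features but inflates absolute drops, so drop magnitudes should be read
comparatively, not as generalization estimates. Permutation importance
also shares signal between strongly correlated informative features; the
test suite constructs complementary (non-redundant) signals when asserting
recovery.

## Synthetic data

The generator produces proteins (lengths uniform in 300–900 by default),
~0.65 of proteins carrying 1–3 IDRs whose length stratum follows the
observed short/medium/long proportions (0.476/0.324/0.200), per-residue
Bernoulli feature planting, and Poisson variants:

* Features: NR rate r per class (default 0.02), DR rate r′ with
  odds(r′) = OR_target · odds(r); maximal runs merged into interval
  records. `interval_length` L > 1 plants anchors at rate/L expanded to
  L-residue intervals.
* Population variants: synonymous Poisson(λ_syn = 0.05/residue), missense
  Poisson(ρ_mis·λ_syn) with ρ_mis = 2.3 (the published mean per-region
  ratio), nonsense/frameshift/inframe at λ_other = 0.002/residue so the
  population medians of those types are non-degenerate; all population
  rates are multiplied by `population_suppression` (default 0) inside
  planted regions. Allele counts are geometric(0.5), populating both the
  singleton and multiton strata.
* Pathogenic variants: Poisson per planted-intolerant region per type
  (defaults 5/5/6/4 for missense/nonsense/frameshift/inframe), uniform
  position within the region, zero elsewhere.

All stages are deterministic given the config seed (stage sub-seeds are
derived from it). A `published_cohort_config` preset scales the cohort to ~550
proteins / ~950 regions with variant data for integration tests.

What the generator does **not** emulate: amino-acid composition, codon
structure and mutational opportunity, inter-protein annotation
correlations, database ascertainment bias, and benign/VUS clinical
records. Passing tests therefore demonstrate correctness and calibration
of the statistical machinery under the stated sampling models, not that
real cohorts satisfy those models.

## Problem sizes and numerical choices

Simulation-based tests use proteomes of 40–150 proteins (15k–75k residues)
and 30–500 replicates per property — sizes chosen so each property is
measured at useful power while the whole suite stays fast. Tolerances:
Fisher p vs enumeration 1e-12 absolute; AP vs brute force 1e-12; CI
coverage accepted in [0.92, 0.98] for a nominal 0.95 at 500 replicates.
Ties in importance ranking are broken by canonical feature order; the
canonical 25-class order is fixed in `FEATURE_CLASSES` and used for every
vector and output table. Output files are TSV (descriptions may contain
commas); all pipeline outputs are byte-reproducible given the same config
and seeds.

## Known limitations

* The intolerance rule is a deterministic threshold rule; no uncertainty
  is attached to verdicts near the medians, and cohort-recomputed
  thresholds make verdicts cohort-dependent by construction.
* NR residues are a heterogeneous "everything else" class; enrichment
  against NR is not enrichment against verified order.
* The missense/synonymous ratio uses raw counts with no mutational-
  opportunity normalization.
* Genome-to-protein mapping, isoform handling, and live database access
  are out of scope; inputs must already be in protein coordinates on the
  canonical isoform.
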