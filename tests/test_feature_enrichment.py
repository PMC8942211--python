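"""Fisher exact enrichment, Woolf CIs, Bonferroni, and median feature content."""

import math

import numpy as np
import pytest
import scipy.stats
from hypothesis import given, settings
from hypothesis import strategies as st

from idrconstraint import (
    ContingencyTable,
    DisorderRegion,
    FeatureAnnotation,
    ProteinRecord,
    bonferroni,
    build_partition,
    classify_association,
    contingency_for_feature,
    enrichment_scan,
    fisher_exact_two_sided,
    median_feature_content,
    sample_odds_ratio,
    woolf_ci,
)
from idrconstraint.feature_enrichment import DegenerateTableError, enrich_table

from conftest import brute_force_fisher_p

cells = st.integers(0, 12)


class TestContingency:
    def test_brute_force_residue_count(self, tiny_partition):
        partition, _ = tiny_partition
        feats = [FeatureAnnotation("P1", "motif", 4, 8)]
        t = contingency_for_feature("motif", partition, feats)
        # region 3-5, motif 4-8: DR with = {4,5}, DR without = {3},
        # NR with = {6,7,8}, NR without = {1,2,9,10}
        assert (t.a, t.b, t.c, t.d) == (2, 1, 3, 4)

    def test_empty_feature_class(self, tiny_partition):
        partition, _ = tiny_partition
        t = contingency_for_feature("motif", partition, [])
        assert (t.a, t.b, t.c, t.d) == (0, 3, 0, 7)

    def test_multiplicity_counts_once(self, tiny_partition):
        partition, _ = tiny_partition
        feats = [
            FeatureAnnotation("P1", "motif", 4, 8),
            FeatureAnnotation("P1", "motif", 4, 6),
        ]
        t = contingency_for_feature("motif", partition, feats)
        assert (t.a, t.b, t.c, t.d) == (2, 1, 3, 4)


class TestFisher:
    def test_symmetric_table(self):
        orr, p = fisher_exact_two_sided(ContingencyTable(5, 5, 5, 5))
        assert orr == 1.0 and p == 1.0

    def test_enumerated_margins(self):
        _, p = fisher_exact_two_sided(ContingencyTable(3, 1, 1, 3))
        assert p == pytest.approx(34 / 70, abs=1e-12)

    def test_printed_missense_synonymous_table(self):
        orr, p = fisher_exact_two_sided(
            ContingencyTable(41691, 20282, 176888, 92314)
        )
        assert round(orr, 1) == 1.1
        assert p == pytest.approx(1.12e-13, rel=0.05)

    def test_degenerate_table_errors(self):
        with pytest.raises(DegenerateTableError):
            fisher_exact_two_sided(ContingencyTable(0, 0, 0, 0))
        with pytest.raises(DegenerateTableError):
            fisher_exact_two_sided(ContingencyTable(0, 5, 0, 7))

    @given(a=cells, b=cells, c=cells, d=cells)
    @settings(max_examples=200, deadline=None)
    def test_matches_enumeration_and_scipy(self, a, b, c, d):
        if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
            return
        t = ContingencyTable(a, b, c, d)
        _, p = fisher_exact_two_sided(t)
        assert p == pytest.approx(brute_force_fisher_p(a, b, c, d), abs=1e-12)
        assert p == pytest.approx(
            scipy.stats.fisher_exact([[a, b], [c, d]])[1], rel=1e-6
        )

    @given(a=st.integers(1, 12), b=st.integers(1, 12), c=st.integers(1, 12),
           d=st.integers(1, 12))
    @settings(max_examples=100, deadline=None)
    def test_or_inversion_and_swap_invariance(self, a, b, c, d):
        t = ContingencyTable(a, b, c, d)
        swapped = ContingencyTable(b, a, d, c)
        assert sample_odds_ratio(t) * sample_odds_ratio(swapped) == pytest.approx(1.0)
        # simultaneous row and column swap leaves p unchanged
        _, p1 = fisher_exact_two_sided(t)
        _, p2 = fisher_exact_two_sided(ContingencyTable(d, c, b, a))
        assert p1 == pytest.approx(p2, rel=1e-12)


class TestWoolfCI:
    def test_closed_form(self):
        lo, hi = woolf_ci(ContingencyTable(10, 10, 5, 20))
        se = math.sqrt(1 / 10 + 1 / 10 + 1 / 5 + 1 / 20)
        assert lo == pytest.approx(math.exp(math.log(4) - 1.959964 * se), rel=1e-6)
        assert hi == pytest.approx(math.exp(math.log(4) + 1.959964 * se), rel=1e-6)

    def test_symmetric_about_one_on_log_scale(self):
        lo, hi = woolf_ci(ContingencyTable(5, 5, 5, 5))
        assert lo * hi == pytest.approx(1.0)

    @given(a=cells, b=cells, c=cells, d=cells)
    @settings(max_examples=100, deadline=None)
    def test_contains_odds_ratio(self, a, b, c, d):
        if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
            return
        t = ContingencyTable(a, b, c, d)
        lo, hi = woolf_ci(t)
        assert lo <= sample_odds_ratio(t) <= hi


class TestBonferroni:
    def test_direct_and_capped(self):
        assert bonferroni(0.001)[0] == pytest.approx(0.025)
        assert bonferroni(0.2)[0] == 1.0

    def test_floor_with_flag(self):
        q, q_exact, floored = bonferroni(1e-120)
        assert q == 1e-100 and floored
        assert q_exact == pytest.approx(25e-120)

    def test_classification_calls(self):
        assert classify_association(3.2, 1e-101) == "class_A_enriched"
        assert classify_association(0.05, 1.8e-05) == "class_B_enriched"
        assert classify_association(1.4, 0.2) == "none"


class TestEnrichmentScan:
    def test_all_features_absent_collects_25_errors(self, tiny_partition):
        partition, _ = tiny_partition
        results, errors = enrichment_scan(partition, [])
        assert results == [] and len(errors) == 25

    def test_empty_class_errors(self):
        partition = build_partition([ProteinRecord("P1", "G", 10)], [])
        with pytest.raises(ValueError, match="non-empty"):
            enrichment_scan(partition, [])

    def test_planted_feature_is_the_only_call(self):
        """With one feature planted at OR 3 over 50k residues, the scan calls
        exactly that feature enriched in nearly every seeded replicate."""
        from idrconstraint import FEATURE_CLASSES, FeatureSpec, plant_features

        proteins = [ProteinRecord(f"P{i}", "G", 500) for i in range(100)]
        regions = [DisorderRegion(f"P{i}r", f"P{i}", 101, 200) for i in range(100)]
        partition = build_partition(proteins, regions)
        spec = {k: FeatureSpec(rate=0.02, odds_ratio=1.0) for k in FEATURE_CLASSES}
        spec["motif"] = FeatureSpec(rate=0.02, odds_ratio=3.0)
        hits = 0
        n_rep = 30
        for seed in range(n_rep):
            feats, _ = plant_features(proteins, partition, spec, seed)
            results, _ = enrichment_scan(partition, feats)
            calls = {r.feature_class for r in results if r.call == "class_A_enriched"}
            hits += calls == {"motif"}
        assert hits / n_rep >= 0.95

    def test_label_permutation_null_rate(self):
        """Shuffling residue class labels kills every association: per-feature
        uncorrected calls at alpha = 0.05 stay within binomial tolerance."""
        from idrconstraint import FEATURE_CLASSES, FeatureSpec, plant_features
        from idrconstraint.annotation_model import ResiduePartition

        proteins = [ProteinRecord(f"P{i}", "G", 400) for i in range(50)]
        regions = [DisorderRegion(f"P{i}r", f"P{i}", 51, 150) for i in range(50)]
        partition = build_partition(proteins, regions)
        spec = {k: FeatureSpec(rate=0.02, odds_ratio=3.0) for k in FEATURE_CLASSES}
        feats, _ = plant_features(proteins, partition, spec, seed=11)
        rng = np.random.default_rng(11)
        n_shuffles, n_calls, n_tests = 200, 0, 0
        flat = np.concatenate([partition.masks[p.accession] for p in proteins])
        sizes = [p.length for p in proteins]
        for _ in range(n_shuffles):
            shuffled = flat[rng.permutation(flat.size)]
            masks, off = {}, 0
            for p, n in zip(proteins, sizes):
                masks[p.accession] = shuffled[off : off + n]
                off += n
            results, _ = enrichment_scan(
                ResiduePartition(masks=masks), feats, m=1,
                classes=("motif", "domain", "site"),
            )
            n_tests += len(results)
            n_calls += sum(r.call != "none" for r in results)
        # expected false-call rate alpha = 0.05; allow 4 sigma binomial slack
        bound = 0.05 + 4 * math.sqrt(0.05 * 0.95 / n_tests)
        assert n_calls / n_tests <= bound


class TestMedianFeatureContent:
    def _setup(self):
        regions = [
            DisorderRegion("r1", "P1", 1, 10, function_category="Inhibitor"),
            DisorderRegion("r2", "P1", 21, 30, function_category="Inhibitor"),
            DisorderRegion("r3", "P2", 1, 10, function_category="Inhibitor"),
            DisorderRegion("r4", "P2", 11, 20),  # unannotated: excluded
        ]
        feats = [
            FeatureAnnotation("P1", "region of interest", 1, 10),
            FeatureAnnotation("P1", "motif", 22, 23),
            FeatureAnnotation("P2", "region of interest", 1, 8),
            FeatureAnnotation("P2", "region of interest", 15, 18),
        ]
        return regions, feats

    def test_full_coverage_content(self):
        regions, feats = self._setup()
        df = median_feature_content(regions[:1], feats[:1], "function")
        row = df.iloc[0]
        assert row.median_content == 1.0 and row.n_regions == 1

    def test_partial_coverage_fraction(self):
        regions, feats = self._setup()
        df = median_feature_content([regions[1]], [feats[1]], "function")
        assert df.iloc[0].median_content == pytest.approx(0.2)

    def test_median_over_cell_and_axis_exclusion(self):
        regions, feats = self._setup()
        df = median_feature_content(regions, feats, "function")
        roi = df[(df.feature_class == "region of interest")]
        assert roi.iloc[0].n_regions == 2  # r1 (1.0) and r3 (0.8); r4 unlabelled
        assert roi.iloc[0].median_content == pytest.approx(0.9)

    def test_odd_count_median(self):
        regions = [
            DisorderRegion(f"r{i}", "P1", s, s + 9, function_category="Effector")
            for i, s in enumerate((1, 21, 41))
        ]
        feats = [
            FeatureAnnotation("P1", "motif", 1, 5),    # 0.5
            FeatureAnnotation("P1", "motif", 21, 28),  # 0.8
            FeatureAnnotation("P1", "motif", 41, 50),  # 1.0
        ]
        df = median_feature_content(regions, feats, "function")
        assert df.iloc[0].median_content == pytest.approx(0.8)
        assert df.iloc[0].n_regions == 3


def test_enrich_table_result_invariants():
    r = enrich_table("motif", ContingencyTable(30, 70, 10, 90))
    assert r.ci_low <= r.odds_ratio <= r.ci_high
    assert 0 < r.p <= 1 and r.q_exact >= r.p
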