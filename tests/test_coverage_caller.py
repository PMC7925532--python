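"""Fold-change computation, exact 1-D 2-means, and the coverage call rule."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kddcall import (
    CoverageCallerConfig,
    CoverageSimConfig,
    ExonCoverageTable,
    FoldChangeProfile,
    call_kdd_from_coverage,
    compute_fold_change,
    kd_spanning_truth,
    simulate_exon_coverage,
    two_means_1d,
)
from kddcall.coverage import CoverageError


def table(gene, depths, sample="S"):
    return ExonCoverageTable.from_gene(sample, gene, depths)


def brute_force_two_means(values):
    """Independent oracle: minimum SSE over all 2-partitions (any subsets)."""
    v = np.asarray(values, dtype=float)
    n = len(v)
    best = np.inf
    for mask in range(1, 2 ** (n - 1)):  # element 0 pinned to one side
        sel = np.array([(mask >> i) & 1 for i in range(n)], dtype=bool)
        a, b = v[sel], v[~sel]
        if len(a) == 0 or len(b) == 0:
            continue
        sse = ((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()
        best = min(best, sse)
    return best


class TestFoldChange:
    def test_identical_samples_give_zero(self, toy_gene):
        depths = [100.0] * 10
        prof = compute_fold_change(table(toy_gene, depths, "t"),
                                   table(toy_gene, depths, "n"))
        assert (prof.fold_change == 0.0).all()

    def test_ratio_1p5_gives_log2(self, toy_gene):
        t = [100.0] * 10
        t[4] = 150.0
        prof = compute_fold_change(table(toy_gene, t, "t"),
                                   table(toy_gene, [100.0] * 10, "n"))
        assert prof.fold_change[5] == pytest.approx(np.log2(1.5))

    def test_library_size_effect_removed(self):
        from conftest import make_gene
        g = make_gene("G5", [(i * 1000, i * 1000 + 100) for i in range(1, 6)],
                      (2000, 2100))
        base = [80.0, 120.0, 100.0, 90.0, 110.0]
        doubled = [2 * d for d in base]
        prof = compute_fold_change(table(g, doubled, "t"), table(g, base, "n"))
        assert np.allclose(prof.fold_change, 0.0)

    def test_mismatched_exons_rejected(self, toy_gene, gene70):
        with pytest.raises(CoverageError):
            compute_fold_change(table(toy_gene, [1.0] * 10),
                                table(gene70, [1.0] * 5))

    def test_all_zero_normal_rejected(self, gene70):
        with pytest.raises(CoverageError, match="all-zero"):
            compute_fold_change(table(gene70, [1.0] * 5),
                                table(gene70, [0.0] * 5))

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(scale=st.floats(0.1, 50.0))
    def test_invariant_to_depth_scaling(self, toy_gene, scale):
        rng = np.random.default_rng(4)
        t = rng.uniform(50, 150, 10)
        n = rng.uniform(50, 150, 10)
        a = compute_fold_change(table(toy_gene, t), table(toy_gene, n))
        b = compute_fold_change(table(toy_gene, t * scale), table(toy_gene, n))
        assert np.allclose(a.fold_change, b.fold_change)


class TestTwoMeans:
    def test_simple_binary_split(self):
        res = two_means_1d([0, 0, 0, 1, 1])
        assert list(res.assignment) == ["low", "low", "low", "high", "high"]
        assert res.median_low == 0.0
        assert res.median_high == 1.0
        assert res.sse == pytest.approx(0.0)
        assert not res.degenerate

    def test_all_equal_is_degenerate(self):
        res = two_means_1d([0.3, 0.3, 0.3])
        assert res.degenerate
        assert res.median_diff == 0.0

    def test_split_at_largest_gap(self):
        res = two_means_1d([0.0, 0.1, 0.5, 0.6])
        assert list(res.assignment) == ["low", "low", "high", "high"]
        assert res.median_low == pytest.approx(0.05)
        assert res.median_high == pytest.approx(0.55)

    def test_too_few_values_rejected(self):
        with pytest.raises(CoverageError):
            two_means_1d([1.0])

    def test_assignment_preserved_in_original_order(self):
        res = two_means_1d([1.0, 0.0, 1.0, 0.0])
        assert list(res.assignment) == ["high", "low", "high", "low"]

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(
        st.lists(
            st.floats(-5, 5, allow_nan=False, width=32),
            min_size=2, max_size=12,
        )
    )
    def test_matches_exhaustive_partition_enumeration(self, values):
        res = two_means_1d(values, degenerate_tol=0.0)
        if res.degenerate:
            return
        assert res.sse == pytest.approx(brute_force_two_means(values), abs=1e-9)


class TestCoverageCall:
    def make_profile(self, gene, fc_values):
        return FoldChangeProfile(
            sample_id="S", gene_id=gene.gene_id,
            fold_change=pd.Series(
                fc_values, index=[e.ordinal for e in sorted(
                    gene.exons, key=lambda e: e.ordinal)]
            ),
            tumor_norm_factor=1.0, normal_norm_factor=1.0,
        )

    def test_boundary_exactly_70pct_and_0p4_is_positive(self, gene70):
        # high cluster = exon 2 only: 700/1000 kinase-domain bases = 0.70;
        # cluster medians 0.4 vs 0.0: both thresholds met inclusively
        prof = self.make_profile(gene70, [0.0, 0.4, 0.0, 0.0, 0.0])
        call = call_kdd_from_coverage(prof, gene70)
        assert call.metrics["kd_overlap_fraction"] == pytest.approx(0.70)
        assert call.metrics["median_diff"] == pytest.approx(0.4)
        assert call.positive

    def test_flat_profile_negative(self, gene70):
        call = call_kdd_from_coverage(
            self.make_profile(gene70, [0.0] * 5), gene70
        )
        assert not call.positive
        assert call.metrics["degenerate"]

    def test_simulated_duplication_positive_with_expected_metrics(self, egfr):
        truth = kd_spanning_truth(egfr)
        cfg = CoverageSimConfig(baseline_depth=500, dispersion=0, purity=1.0)
        t, n = simulate_exon_coverage(egfr, cfg, truth)
        call = call_kdd_from_coverage(compute_fold_change(t, n), egfr)
        assert call.positive
        assert call.metrics["median_diff"] == pytest.approx(np.log2(1.5))
        assert call.metrics["kd_overlap_fraction"] == 1.0
        assert call.metrics["duplicated_exons"] == list(range(18, 26))

    def test_high_cluster_below_70pct_negative(self, gene70):
        # high cluster = exon 3 only: 300/1000 = 0.30 < 0.70
        prof = self.make_profile(gene70, [0.0, 0.0, 0.6, 0.0, 0.0])
        call = call_kdd_from_coverage(prof, gene70)
        assert not call.positive
        assert call.metrics["kd_overlap_fraction"] == pytest.approx(0.30)

    def test_median_diff_below_threshold_negative(self, gene70):
        prof = self.make_profile(gene70, [0.0, 0.39, 0.0, 0.0, 0.0])
        assert not call_kdd_from_coverage(prof, gene70).positive

    def test_whole_gene_amplification_negative(self, egfr):
        # uniform 4x amplification: median normalization flattens the
        # profile, so no intragenic structure remains to call
        cfg = CoverageSimConfig(baseline_depth=500, dispersion=0)
        t, n = simulate_exon_coverage(egfr, cfg, None)
        t.depths = t.depths * 4.0
        call = call_kdd_from_coverage(compute_fold_change(t, n), egfr)
        assert not call.positive

    def test_monotone_in_median_diff(self, gene70):
        # raising the high cluster (holding assignment fixed) never flips
        # a positive call negative
        base = [0.0, 0.4, 0.0, 0.0, 0.0]
        assert call_kdd_from_coverage(
            self.make_profile(gene70, base), gene70
        ).positive
        for bump in (0.1, 0.5, 2.0):
            vals = list(base)
            vals[1] += bump
            assert call_kdd_from_coverage(
                self.make_profile(gene70, vals), gene70
            ).positive
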