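"""Discordant-pair clustering, duplication derivation, KDD classification."""

import numpy as np
import pandas as pd
import pytest

from kddcall import (
    DuplicationCall,
    KDDCall,
    OrientationError,
    ReadPairSimConfig,
    call_kdd_from_pairs,
    classify_kdd_breakpoints,
    cluster_discordant_pairs,
    combine_calls,
    derive_duplication,
    kd_spanning_truth,
    simulate_read_pairs,
)
from kddcall.calls import CallError
from kddcall.simulate import BEDPE_COLUMNS


def pair_row(l_mid, r_mid, name="p", strands=("-", "+"), pair_class="chimeric",
             chrom="chr7", read_len=100):
    half = read_len // 2
    if r_mid is None:
        return (chrom, l_mid - half, l_mid + half, ".", -1, -1,
                name, 60, strands[0], ".", "semi_mapped")
    return (chrom, l_mid - half, l_mid + half, chrom, r_mid - half,
            r_mid + half, name, 60, strands[0], strands[1], pair_class)


def frame(rows):
    return pd.DataFrame(rows, columns=BEDPE_COLUMNS)


class TestClustering:
    def test_empty_input(self, egfr):
        assert cluster_discordant_pairs(frame([]), egfr) == []

    def test_single_cluster_consensus_is_per_side_median(self, egfr):
        span = egfr.span
        base_l, base_r = span[0] + 10_000, span[0] + 60_000
        offsets = [0, 10, 20, 30, 40]
        rows = [
            pair_row(base_l + o, base_r + o, name=f"p{i}")
            for i, o in enumerate(offsets)
        ]
        clusters = cluster_discordant_pairs(frame(rows), egfr, window=300)
        assert len(clusters) == 1
        c = clusters[0]
        assert c.support_chimeric == 5
        assert c.consensus_left == base_l + 20   # median of offsets
        assert c.consensus_right == base_r + 20

    def test_groups_10kb_apart_stay_separate(self, egfr):
        span = egfr.span
        rows = [pair_row(span[0] + 10_000 + o, span[0] + 60_000 + o,
                         name=f"a{o}") for o in (0, 30, 60)]
        rows += [pair_row(span[0] + 20_000 + o, span[0] + 70_000 + o,
                          name=f"b{o}") for o in (0, 30, 60)]
        clusters = cluster_discordant_pairs(frame(rows), egfr, window=300)
        assert len(clusters) == 2

    def test_order_invariant(self, egfr):
        span = egfr.span
        rows = [pair_row(span[0] + 10_000 + o, span[0] + 60_000 + o,
                         name=f"p{o}") for o in (0, 20, 40, 10_500, 10_540)]
        a = cluster_discordant_pairs(frame(rows), egfr, min_support=1)
        b = cluster_discordant_pairs(frame(rows[::-1]), egfr, min_support=1)
        key = lambda c: (c.consensus_left, c.consensus_right, c.members)
        assert sorted(map(key, a)) == sorted(map(key, b))

    def test_min_support_filter_is_monotone(self, egfr):
        span = egfr.span
        rows = [pair_row(span[0] + 10_000 + o, span[0] + 60_000 + o,
                         name=f"p{o}") for o in (0, 20, 11_000, 11_030, 11_060)]
        counts = [
            len(cluster_discordant_pairs(frame(rows), egfr, min_support=m))
            for m in (1, 2, 3, 4)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_concordant_pairs_ignored(self, egfr):
        span = egfr.span
        rows = [pair_row(span[0] + 1000 * i, span[0] + 1000 * i + 350,
                         name=f"c{i}", strands=("+", "-"),
                         pair_class="concordant") for i in range(10)]
        assert cluster_discordant_pairs(frame(rows), egfr, min_support=1) == []

    def test_semi_mapped_reinforce_but_never_seed(self, egfr):
        span = egfr.span
        l, r = span[0] + 10_000, span[0] + 60_000
        semi_only = frame([pair_row(l, None, name=f"s{i}") for i in range(5)])
        assert cluster_discordant_pairs(semi_only, egfr, min_support=1) == []
        mixed = frame(
            [pair_row(l, r, name="c1"), pair_row(l + 20, r + 20, name="c2")]
            + [pair_row(l + 50, None, name=f"s{i}") for i in range(3)]
        )
        clusters = cluster_discordant_pairs(mixed, egfr, min_support=1)
        assert len(clusters) == 1
        assert clusters[0].support_chimeric == 2
        assert clusters[0].support_semi_mapped == 3


class TestDeriveDuplication:
    def test_zero_jitter_recovers_truth_exactly(self, egfr):
        truth = kd_spanning_truth(egfr)
        cfg = ReadPairSimConfig(n_support=6, jitter_sd=0,
                                chimeric_fraction=1.0, n_background=0, seed=1)
        pairs = simulate_read_pairs(egfr, truth, cfg)
        clusters = cluster_discordant_pairs(pairs, egfr)
        assert len(clusters) == 1
        dup = derive_duplication(clusters[0], egfr)
        assert (dup.bp_left, dup.bp_right) == (truth.bp_left, truth.bp_right)

    def test_jittered_call_equals_emitted_anchor_medians(self, egfr):
        truth = kd_spanning_truth(egfr)
        cfg = ReadPairSimConfig(n_support=20, jitter_sd=30,
                                chimeric_fraction=1.0, n_background=0, seed=8)
        pairs = simulate_read_pairs(egfr, truth, cfg)
        dup = derive_duplication(
            cluster_discordant_pairs(pairs, egfr)[0], egfr
        )
        lmid = pairs["start1"] + (pairs["end1"] - pairs["start1"]) // 2
        rmid = pairs["start2"] + (pairs["end2"] - pairs["start2"]) // 2
        assert dup.bp_left == int(round(float(np.median(lmid))))
        assert dup.bp_right == int(round(float(np.median(rmid))))
        assert abs(dup.bp_left - truth.bp_left) <= 30
        assert abs(dup.bp_right - truth.bp_right) <= 30

    def test_deletion_orientation_rejected(self, egfr):
        span = egfr.span
        rows = [pair_row(span[0] + 10_000 + o, span[0] + 60_000 + o,
                         name=f"d{o}", strands=("+", "-")) for o in (0, 20)]
        cluster = cluster_discordant_pairs(frame(rows), egfr)[0]
        with pytest.raises(OrientationError) as exc:
            derive_duplication(cluster, egfr)
        assert exc.value.reason == "deletion_signature"


class TestClassification:
    def test_flanking_duplication_positive(self, egfr):
        truth = kd_spanning_truth(egfr)
        dup = DuplicationCall("EGFR", "S", truth.bp_left, truth.bp_right, 10)
        call = classify_kdd_breakpoints(dup, egfr)
        assert call.positive
        assert call.metrics["duplicated_kd_exons"] == list(range(18, 26))

    def test_breakpoint_inside_kd_negative(self, egfr):
        kd_start, kd_end = egfr.kinase_domain
        dup = DuplicationCall("EGFR", "S", kd_start - 500, kd_end - 100, 10)
        assert not classify_kdd_breakpoints(dup, egfr).positive

    def test_breakpoints_beyond_gene_span_negative(self, egfr):
        span = egfr.span
        dup = DuplicationCall("EGFR", "S", span[0] - 50_000, span[1] + 50_000, 10)
        call = classify_kdd_breakpoints(dup, egfr)
        assert not call.positive
        assert not call.metrics["intragenic"]

    def test_background_only_sample_yields_no_call(self, egfr):
        cfg = ReadPairSimConfig(n_background=40, seed=4)
        pairs = simulate_read_pairs(egfr, None, cfg, background_only=True)
        assert call_kdd_from_pairs(pairs, egfr) is None


class TestCombine:
    def mk(self, positive, method="coverage"):
        return KDDCall("S", "EGFR", method, positive,
                       "candidate" if positive else "negative")

    @pytest.mark.parametrize(
        "cov_pos,bp_pos,tier",
        [
            (True, True, "confident"),
            (True, False, "candidate"),
            (False, True, "candidate"),
            (False, False, "negative"),
        ],
    )
    def test_consensus_policy(self, cov_pos, bp_pos, tier):
        merged = combine_calls(self.mk(cov_pos),
                               self.mk(bp_pos, method="breakpoint"))
        assert merged.tier == tier
        assert merged.positive == (tier != "negative")

    def test_missing_breakpoint_call_is_breakpoint_negative(self):
        assert combine_calls(self.mk(True), None).tier == "candidate"

    def test_tier_monotone_in_each_input(self):
        # upgrading either method's result never downgrades the tier
        from kddcall.calls import TIER_ORDER
        for bp_pos in (False, True):
            t0 = TIER_ORDER[combine_calls(
                self.mk(False), self.mk(bp_pos, "breakpoint")).tier]
            t1 = TIER_ORDER[combine_calls(
                self.mk(True), self.mk(bp_pos, "breakpoint")).tier]
            assert t1 >= t0

    def test_sample_mismatch_rejected(self):
        a = self.mk(True)
        b = KDDCall("OTHER", "EGFR", "breakpoint", True, "candidate")
        with pytest.raises(CallError):
            combine_calls(a, b)
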