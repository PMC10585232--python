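"""Segmentation, calling, gene mapping and burden statistics."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mpnstkit.containers import SEGMENT_COLUMNS, SegmentedProfile
from mpnstkit.copynumber import (BurdenSummary, CallThresholds, call_segments,
                                 detect_disproportionate_loh, genome_burden,
                                 map_genes_to_cn, pcf_segment)
from mpnstkit.errors import ArgumentError, DataError


def brute_force_pcf_objective(x: np.ndarray, gamma: float) -> float:
    """Exhaustive minimum of the penalised least-squares objective."""
    n = len(x)
    best = np.inf
    for k in range(n):
        for cuts in combinations(range(1, n), k):
            bounds = [0] + list(cuts) + [n]
            cost = gamma * k
            for i, j in zip(bounds[:-1], bounds[1:]):
                seg = x[i:j]
                cost += float(((seg - seg.mean()) ** 2).sum())
            best = min(best, cost)
    return best


def pcf_objective(x: np.ndarray, gamma: float, segs) -> float:
    return gamma * (len(segs) - 1) + sum(
        float(((x[s - 1:e] - np.mean(x[s - 1:e])) ** 2).sum()) for s, e, _ in segs)


class TestPCF:
    def test_constant_signal_is_one_segment(self):
        segs = pcf_segment(np.full(30, 2.5), gamma=1.0)
        assert segs == [(1, 30, 2.5)]

    def test_noiseless_step_recovers_single_breakpoint(self):
        x = np.concatenate([np.zeros(25), np.ones(25)])
        segs = pcf_segment(x, gamma=1.0)
        assert segs == [(1, 25, 0.0), (26, 50, 1.0)]

    def test_segments_tile_signal_and_means_are_exact(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=50)
        segs = pcf_segment(x, gamma=2.0)
        assert segs[0][0] == 1 and segs[-1][1] == 50
        for (s, e, m), (s2, _, _) in zip(segs, segs[1:] + [(51, None, None)]):
            assert s2 == e + 1
            assert m == pytest.approx(np.mean(x[s - 1:e]))

    @pytest.mark.parametrize("length", range(1, 13))
    def test_matches_exhaustive_enumeration(self, length):
        rng = np.random.default_rng(length)
        x = rng.normal(size=length)
        for gamma in (0.05, 0.5, 2.0):
            segs = pcf_segment(x, gamma)
            assert pcf_objective(x, gamma, segs) == pytest.approx(
                brute_force_pcf_objective(x, gamma), abs=1e-9)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ArgumentError):
            pcf_segment([], 1.0)
        with pytest.raises(ArgumentError):
            pcf_segment([1.0, 2.0], -1.0)
        with pytest.raises(ArgumentError):
            pcf_segment([1.0, np.nan], 1.0)


def make_profile(rows, ploidy=2.0, sample="S1"):
    seg = pd.DataFrame(rows, columns=["chrom", "start", "end", "total_cn", "minor_cn"])
    seg["n_probes"] = 10
    seg["log_ratio"] = np.log2(np.maximum(seg["total_cn"], 0.25) / ploidy)
    return SegmentedProfile(sample_id=sample, segments=seg[SEGMENT_COLUMNS], ploidy=ploidy)


class TestCalling:
    def test_neutral_segment_without_loh(self):
        prof = make_profile([("chr1", 1, 100, 2, 1)])
        calls = call_segments(prof)
        assert calls["call"].iloc[0] == "neutral" and not calls["loh"].iloc[0]

    def test_ten_extra_copies_is_high_level_amplification(self):
        prof = make_profile([("chr1", 1, 100, 12, 1)])
        calls = call_segments(prof)
        row = calls.iloc[0]
        assert row["call"] == "gain" and row["amp"] and row["high_amp"]

    def test_copy_neutral_loh(self):
        prof = make_profile([("chr1", 1, 100, 2, 0)])
        calls = call_segments(prof)
        assert calls["call"].iloc[0] == "neutral" and calls["loh"].iloc[0]

    def test_calls_relative_to_triploid_ploidy(self):
        prof = make_profile([("chr1", 1, 100, 3, 1), ("chr1", 101, 200, 2, 0),
                             ("chr1", 201, 300, 4, 1)], ploidy=3.0)
        calls = call_segments(prof)
        assert list(calls["call"]) == ["neutral", "loss", "gain"]

    def test_call_hierarchy_consistency(self, default_cohort):
        for prof in default_cohort.segmented_profiles[:10]:
            calls = call_segments(prof)
            assert (calls.loc[calls["high_amp"], "amp"]).all()
            assert (calls.loc[calls["amp"], "call"] == "gain").all()
            assert (calls.loc[calls["total_cn"] == 0, "call"] == "homdel").all()

    def test_log_ratio_mode_agrees_on_direction(self):
        prof = make_profile([("chr1", 1, 100, 4, 1), ("chr1", 101, 200, 1, 0),
                             ("chr1", 201, 300, 2, 1)])
        lr_calls = call_segments(prof, CallThresholds(mode="log_ratio"))
        assert list(lr_calls["call"]) == ["gain", "loss", "neutral"]


class TestBurden:
    def hand_calls(self):
        prof = make_profile([("chr1", 1, 30, 4, 1), ("chr1", 31, 100, 2, 1),
                             ("chr2", 1, 50, 1, 0), ("chr2", 51, 100, 2, 1),
                             ("chr3", 1, 100, 2, 1)])
        return call_segments(prof)

    def test_hand_computed_percentages(self):
        b = genome_burden(self.hand_calls())
        assert b.pct_gain == pytest.approx(10.0)
        assert b.pct_loss == pytest.approx(100 * 50 / 300)
        assert b.pct_total_cna == pytest.approx(100 * 80 / 300)

    def test_all_neutral_and_all_gained_extremes(self):
        none = call_segments(make_profile([("chr1", 1, 100, 2, 1)]))
        assert genome_burden(none).pct_total_cna == 0.0
        allg = call_segments(make_profile([("chr1", 1, 100, 4, 1)]))
        assert genome_burden(allg).pct_gain == 100.0

    def test_subdivision_invariance(self):
        whole = call_segments(make_profile([("chr1", 1, 100, 4, 1),
                                            ("chr1", 101, 200, 2, 1)]))
        split = call_segments(make_profile([("chr1", 1, 50, 4, 1), ("chr1", 51, 100, 4, 1),
                                            ("chr1", 101, 200, 2, 1)]))
        ba, bb = genome_burden(whole), genome_burden(split)
        assert ba.pct_gain == bb.pct_gain and ba.pct_loh == bb.pct_loh

    def test_zero_coverage_rejected(self):
        calls = self.hand_calls().iloc[:0]
        with pytest.raises(DataError):
            genome_burden(calls)

    @given(st.integers(0, 100), st.integers(0, 100))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_total_cna_bounds(self, gain_len, loss_len):
        rows = [("chr1", 1, 200, 2, 1)]
        if gain_len:
            rows.append(("chr2", 1, gain_len, 4, 1))
        if loss_len:
            rows.append(("chr3", 1, loss_len, 1, 0))
        b = genome_burden(call_segments(make_profile(rows)))
        assert b.pct_total_cna <= b.pct_gain + b.pct_loss + 1e-9
        assert b.pct_total_cna >= max(b.pct_gain, b.pct_loss) - 1e-9


class TestDisproportionateLOH:
    @pytest.mark.parametrize("loh,loss,expected", [
        (30.0, 2.0, True),
        (30.0, 10.0, False),
        (5.0, 2.0, False),
        (24.0, 5.9, True),   # boundary: LOH inclusive, loss strict
        (23.9, 2.0, False),
    ])
    def test_rule(self, loh, loss, expected):
        b = BurdenSummary("s", 0.0, loss, loss, loh)
        assert detect_disproportionate_loh(b) is expected


class TestGeneMapping:
    def models(self):
        return pd.DataFrame({
            "gene": ["inside", "spanning", "orphan"],
            "chrom": ["chr1", "chr1", "chrX"],
            "start": [10, 81, 10],
            "end": [50, 180, 50],
        })

    def profile(self):
        return make_profile([("chr1", 1, 120, 2, 1), ("chr1", 121, 300, 4, 1)])

    def test_weighted_mean_and_calls(self):
        gcn = map_genes_to_cn([self.profile()], self.models())
        assert gcn.continuous.loc["inside", "S1"] == pytest.approx(2.0)
        # spanning gene: 40 bases at CN 2, 60 bases at CN 4 -> 3.2
        assert gcn.continuous.loc["spanning", "S1"] == pytest.approx(3.2)
        assert gcn.calls.loc["spanning", "S1"] == "gain"
        assert np.isnan(gcn.continuous.loc["orphan", "S1"])
        assert gcn.calls.loc["orphan", "S1"] == "missing"

    def test_majority_rule(self):
        gcn = map_genes_to_cn([self.profile()], self.models(), rule="majority")
        assert gcn.continuous.loc["spanning", "S1"] == pytest.approx(4.0)

    def test_gene_loh_flag_from_any_overlapping_segment(self):
        prof = make_profile([("chr1", 1, 120, 2, 0), ("chr1", 121, 300, 4, 1)])
        gcn = map_genes_to_cn([prof], self.models())
        assert bool(gcn.loh.loc["inside", "S1"])
        assert bool(gcn.loh.loc["spanning", "S1"])

    def test_malformed_gene_model_rejected(self):
        with pytest.raises(DataError):
            map_genes_to_cn([self.profile()], pd.DataFrame({"gene": ["a"]}))
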