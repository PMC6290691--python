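"""Coverage statistics, GC correction, segmentation and interval matching."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from driftprof import cnvseg, simgenome
from driftprof.cnvseg import (SegmentationConfig, compare_interval_sets,
                              coverage_stats, filter_common,
                              gc_correct_and_normalize, segment_and_call)
from driftprof.vardata import CoverageProfile, IntervalCall

from conftest import small_config


def profile_from_depths(depths, gc=None, bin_size=1000, chrom="chr1"):
    n = len(depths)
    bins = pd.DataFrame({
        "chrom": chrom, "bin_start": np.arange(n) * bin_size,
        "bin_end": (np.arange(n) + 1) * bin_size,
        "raw_depth": np.asarray(depths, dtype=float),
    })
    if gc is not None:
        bins["gc_fraction"] = gc
    return CoverageProfile(bins, bin_size)


def profile_from_ratios(ratios, bin_size=1000, chrom="chr1"):
    prof = profile_from_depths(np.full(len(ratios), 30.0), bin_size=bin_size,
                               chrom=chrom)
    prof.bins["corrected_ratio"] = np.asarray(ratios, dtype=float)
    return prof


EXACT = SegmentationConfig(smooth_window=1, bridge_gap=0, merge_gap=0,
                           refine_window=0)


class TestCoverageStats:
    def test_uniform_depth(self):
        s = coverage_stats(profile_from_depths([30.0] * 10))
        assert (s.mean_coverage, s.frac_above_20x) == (30.0, 1.0)

    def test_mixed_depth(self):
        s = coverage_stats(profile_from_depths([10.0] * 5 + [30.0] * 5))
        assert (s.mean_coverage, s.frac_above_20x) == (20.0, 0.5)

    def test_single_zero_bin(self):
        s = coverage_stats(profile_from_depths([0.0]))
        assert (s.mean_coverage, s.frac_above_20x) == (0.0, 0.0)

    def test_empty_profile_is_an_error(self):
        with pytest.raises((ValueError, Exception)):
            coverage_stats(profile_from_depths([]))


class TestGcCorrection:
    def test_self_normalization_is_identity(self, rng):
        depths = rng.poisson(30, 2000).astype(float)
        gc = rng.uniform(0.3, 0.6, 2000)
        prof = profile_from_depths(depths, gc)
        out = gc_correct_and_normalize(prof, prof)
        ratio = out.bins["corrected_ratio"].dropna()
        assert np.allclose(ratio, 1.0)

    def test_binning_mismatch_rejected(self, rng):
        a = profile_from_depths([30.0] * 10, [0.4] * 10)
        b = profile_from_depths([30.0] * 12, [0.4] * 12)
        with pytest.raises(ValueError, match="binned differently"):
            gc_correct_and_normalize(a, b)

    def test_zero_reference_bins_masked(self, rng):
        gc = rng.uniform(0.3, 0.6, 1500)
        sample = profile_from_depths(rng.poisson(30, 1500).astype(float), gc)
        ref_depths = rng.poisson(30, 1500).astype(float)
        ref_depths[7] = 0.0
        ref = profile_from_depths(ref_depths, gc)
        out = gc_correct_and_normalize(sample, ref)
        assert np.isnan(out.bins["corrected_ratio"].iloc[7])

    def test_planted_tetraploid_region_doubles_ratio(self):
        cfg = small_config(gc_bias_amplitude=0.0)
        ref_seq, _ = simgenome.simulate_reference(cfg)
        plant = simgenome.PlantedCNV("chr1", 200_000, 240_000, 4.0, "shared")
        cov, refp = simgenome.simulate_coverage(ref_seq, [plant], cfg, "a")
        out = gc_correct_and_normalize(cov, refp)
        b = out.bins
        inside = b[(b.chrom == "chr1") & (b.bin_start >= 200_000)
                   & (b.bin_end <= 240_000)]["corrected_ratio"]
        assert 1.8 <= inside.median() <= 2.2

    def test_removes_planted_gc_bias(self):
        cfg = small_config(gc_bias_amplitude=0.3, cnv_plant_list=())
        ref_seq, _ = simgenome.simulate_reference(cfg)
        cov, refp = simgenome.simulate_coverage(ref_seq, [], cfg, "a")
        raw_r = np.corrcoef(cov.bins["raw_depth"], cov.bins["gc_fraction"])[0, 1]
        out = gc_correct_and_normalize(cov, refp)
        ok = out.bins["corrected_ratio"].notna()
        corr_r = np.corrcoef(out.bins.loc[ok, "corrected_ratio"],
                             out.bins.loc[ok, "gc_fraction"])[0, 1]
        assert raw_r > 0.3          # the planted bias is real before correction
        assert abs(corr_r) < 0.05   # and gone afterwards


class TestSegmentation:
    def test_constant_diploid_profile_yields_no_calls(self):
        assert segment_and_call(profile_from_ratios([1.0] * 50), EXACT) == []

    @pytest.mark.parametrize("config", [EXACT, SegmentationConfig()])
    def test_ten_bin_half_ratio_block(self, config):
        ratios = [1.0] * 20 + [0.5] * 10 + [1.0] * 20
        (call,) = segment_and_call(profile_from_ratios(ratios), config)
        assert (call.start, call.end) == (20_000, 30_000)
        assert call.call_type == "cnv_loss"
        assert call.ploidy == pytest.approx(1.0)
        assert len(call) == 10_000

    def test_single_bin_not_longer_than_1kb_not_called(self):
        ratios = [1.0] * 20 + [0.5] + [1.0] * 20
        assert segment_and_call(profile_from_ratios(ratios), EXACT) == []

    def test_gain_block_called_with_mean_ploidy(self):
        ratios = [1.0] * 20 + [1.6] * 8 + [1.0] * 20
        (call,) = segment_and_call(profile_from_ratios(ratios), EXACT)
        assert call.call_type == "cnv_gain"
        assert call.ploidy == pytest.approx(3.2)

    def test_masked_bins_break_no_calls(self):
        ratios = [1.0] * 10 + [np.nan] * 3 + [1.0] * 10
        assert segment_and_call(profile_from_ratios(ratios), EXACT) == []

    def test_requires_corrected_ratio(self):
        with pytest.raises(ValueError, match="corrected_ratio"):
            segment_and_call(profile_from_depths([30.0] * 10), EXACT)


class TestFilterCommon:
    def test_half_overlap_is_removed_inclusively(self):
        call = IntervalCall("chr1", 0, 10_000, "cnv_loss", 1.0)
        db = [IntervalCall("chr1", 5_000, 15_000, "cnv_loss", 1.0)]
        retained, removed = filter_common([call], db)
        assert removed == [call] and retained == []

    def test_small_overlap_retained(self):
        call = IntervalCall("chr1", 0, 10_000, "cnv_loss", 1.0)
        db = [IntervalCall("chr1", 9_000, 19_000, "cnv_loss", 1.0)]
        retained, removed = filter_common([call], db)
        assert retained == [call] and removed == []

    def test_empty_db_retains_everything(self):
        calls = [IntervalCall("chr1", 0, 10_000, "cnv_loss", 1.0),
                 IntervalCall("chr2", 0, 20_000, "cnv_gain", 3.0)]
        retained, removed = filter_common(calls, [])
        assert retained == calls and removed == []

    def test_partition_is_exact(self, rng):
        calls = [IntervalCall("chr1", int(s), int(s) + 5000, "cnv_loss", 1.0)
                 for s in rng.choice(np.arange(0, 500_000, 10_000), 20,
                                     replace=False)]
        db = [IntervalCall("chr1", 0, 100_000, "cnv_loss", 1.0)]
        retained, removed = filter_common(calls, db)
        assert sorted(retained + removed, key=lambda c: c.start) \
            == sorted(calls, key=lambda c: c.start)


class TestCompareIntervalSets:
    def test_identical_lists_all_shared(self):
        calls = [IntervalCall("chr1", 0, 10_000, "cnv_loss", 1.0),
                 IntervalCall("chr1", 50_000, 80_000, "cnv_gain", 3.0)]
        shared, a_only, b_only = compare_interval_sets(calls, list(calls))
        assert len(shared) == 2 and not a_only and not b_only

    def test_reciprocal_half_overlap_is_shared(self):
        a = [IntervalCall("chr1", 0, 10_000, "cnv_loss", 1.0)]
        b = [IntervalCall("chr1", 5_000, 15_000, "cnv_loss", 1.0)]
        shared, a_only, b_only = compare_interval_sets(a, b)
        assert len(shared) == 1 and not a_only and not b_only

    def test_type_mismatch_never_matches(self):
        a = [IntervalCall("chr1", 0, 10_000, "cnv_loss", 1.0)]
        b = [IntervalCall("chr1", 0, 10_000, "cnv_gain", 3.0)]
        shared, a_only, b_only = compare_interval_sets(a, b)
        assert not shared and a_only == a and b_only == b

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(data=st.data())
    def test_greedy_matches_maximum_matching(self, data):
        """On disjoint-per-sample interval sets, greedy one-to-one matching
        attains the exhaustive maximum-cardinality matching."""
        import networkx as nx

        def draw_calls(label):
            n = data.draw(st.integers(0, 20), label=label)
            starts = sorted(data.draw(
                st.lists(st.integers(0, 80), min_size=n, max_size=n,
                         unique=True), label=label + "s"))
            calls = []
            prev_end = -1
            for s in starts:
                s = max(s * 10_000, (prev_end // 10_000 + 1) * 10_000)
                length = data.draw(st.integers(2, 9), label=label + "l") * 1000
                calls.append(IntervalCall("chr1", s, s + length,
                                          "cnv_loss", 1.0))
                prev_end = s + length
            return calls

        calls_a, calls_b = draw_calls("a"), draw_calls("b")
        config = SegmentationConfig()
        shared, a_only, b_only = compare_interval_sets(calls_a, calls_b, config)
        # conservation
        assert len(shared) + len(a_only) == len(calls_a)
        assert len(shared) + len(b_only) == len(calls_b)
        # oracle: maximum bipartite matching over eligible pairs
        g = nx.Graph()
        g.add_nodes_from((0, i) for i in range(len(calls_a)))
        g.add_nodes_from((1, j) for j in range(len(calls_b)))
        for i, a in enumerate(calls_a):
            for j, b in enumerate(calls_b):
                ov = max(0, min(a.end, b.end) - max(a.start, b.start))
                if ov >= 0.5 * len(a) and ov >= 0.5 * len(b):
                    g.add_edge((0, i), (1, j))
        best = nx.algorithms.matching.max_weight_matching(g, maxcardinality=True)
        assert len(shared) == len(best)


class TestRecoveryOnSimulation:
    def test_planted_cnvs_recovered_and_common_filtered(self):
        cfg = small_config(seed=21)
        ref_seq, _genes = simgenome.simulate_reference(cfg)
        calls = {}
        for sample in ("a", "b"):
            cov, refp = simgenome.simulate_coverage(
                ref_seq, cfg.cnvs_for(sample), cfg, sample)
            corrected = gc_correct_and_normalize(cov, refp)
            calls[sample] = segment_and_call(corrected)
        for sample in ("a", "b"):
            planted = cfg.cnvs_for(sample)
            assert len(calls[sample]) == len(planted)
            for p in planted:
                (match,) = [c for c in calls[sample]
                            if c.chrom == p.chrom
                            and abs(c.start - p.start) <= 1000
                            and abs(c.end - p.end) <= 1000]
                assert match.call_type == ("cnv_gain" if p.ploidy > 2
                                           else "cnv_loss")
        common_db = [p.as_call() for p in cfg.cnv_plant_list
                     if p.ownership == "common"]
        retained, removed = filter_common(calls["a"], common_db)
        assert len(removed) == 1 and len(retained) == len(calls["a"]) - 1
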