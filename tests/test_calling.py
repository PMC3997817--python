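"""Thresholds, absolute copy number and the high-confidence RD filter."""

import numpy as np
import pytest
from scipy.stats import chi2

from silkcnv import simdata
from silkcnv.binning import bin_counts, gc_correct
from silkcnv.calling import (
    CnvCall,
    DepthStats,
    Provenance,
    absolute_copy_number,
    call_cnvs,
    call_thresholds,
    depth_stats,
    rd_filter,
)
from silkcnv.segmentation import Segment, segment_bins


def _call(mean_rd, n_bins=20, state="gain", cn=4, sample="s"):
    return CnvCall(
        sample_id=sample, scaffold="s1", start=0, end=n_bins * 1000,
        state=state, copy_number=cn, mean_rd=mean_rd, n_bins=n_bins,
    )


class TestThresholds:
    def test_normal_quantile_value(self):
        t_loss, t_gain = call_thresholds(100, 0.01)
        assert t_gain == pytest.approx(100 + 2.5758 * 10, abs=0.01)
        assert t_loss == pytest.approx(100 - 2.5758 * 10, abs=0.01)

    def test_symmetric_about_lambda(self):
        t_loss, t_gain = call_thresholds(64, 0.05)
        assert t_gain - 64 == pytest.approx(64 - t_loss)

    def test_alpha_near_one_collapses_to_lambda(self):
        t_loss, t_gain = call_thresholds(100, 0.9999)
        assert t_loss == pytest.approx(100, abs=0.01)
        assert t_gain == pytest.approx(100, abs=0.01)

    def test_negative_loss_threshold_clamped(self):
        with pytest.warns(UserWarning, match="clamped"):
            t_loss, _ = call_thresholds(2, 0.001)
        assert t_loss == 0.0


class TestAbsoluteCopyNumber:
    @pytest.mark.parametrize(
        "seg,dip,expected", [(100, 100, 2), (150, 100, 3), (0, 100, 0)]
    )
    def test_known_values(self, seg, dip, expected):
        assert absolute_copy_number(seg, dip) == expected

    def test_matches_rounding_formula_oracle(self, rng):
        for _ in range(200):
            seg = float(rng.uniform(0, 500))
            dip = float(rng.uniform(10, 200))
            want = min(20, max(0, int(np.floor(2 * seg / dip + 0.5))))
            assert absolute_copy_number(seg, dip) == want

    def test_capped_at_twenty(self):
        assert absolute_copy_number(10_000, 10) == 20


class TestCallCnvs:
    def _seg(self, a, b, mean, scaf="s1"):
        return Segment(scaf, a, b, a * 1000, b * 1000, mean, b - a)

    def test_diploid_segments_yield_no_calls(self):
        segs = [self._seg(0, 50, 100.0), self._seg(50, 80, 101.0)]
        assert call_cnvs(segs, call_thresholds(100, 0.01), 100) == []

    def test_segment_exactly_at_threshold_not_called(self):
        t_loss, t_gain = call_thresholds(100, 0.01)
        segs = [self._seg(0, 50, t_gain), self._seg(50, 100, t_loss)]
        assert call_cnvs(segs, (t_loss, t_gain), 100) == []

    def test_adjacent_same_state_calls_merged(self):
        segs = [self._seg(0, 10, 200.0), self._seg(10, 20, 210.0),
                self._seg(20, 30, 100.0)]
        calls = call_cnvs(segs, call_thresholds(100, 0.01), 100)
        assert len(calls) == 1
        assert (calls[0].start, calls[0].end) == (0, 20_000)
        assert calls[0].copy_number == 4  # weighted mean 205 -> 4.1 -> 4

    def test_loss_gain_asymmetry_preserved(self, small_genome):
        # deletion-biased truth (NAHR-style): 5 losses vs 2 gains implanted
        layout = [
            ("scaffold1", 20_000, 35_000, 1),
            ("scaffold1", 60_000, 75_000, 0),
            ("scaffold1", 110_000, 125_000, 1),
            ("scaffold1", 160_000, 175_000, 0),
            ("scaffold1", 210_000, 225_000, 1),
            ("scaffold2", 40_000, 55_000, 4),
            ("scaffold2", 100_000, 115_000, 6),
        ]
        specs = [
            simdata.CnvSpec(s, a, b, cn, sharing="dom1") for s, a, b, cn in layout
        ]
        truths = simdata.implant_cnvs(small_genome, specs=specs, seed=31)
        t = next(tr for tr in truths if tr.sample_id == "dom1")
        n_loss_truth = sum(1 for *_, cn in t.cnv_intervals if cn < 2)
        n_gain_truth = len(t.cnv_intervals) - n_loss_truth
        assert n_loss_truth > n_gain_truth
        reads = simdata.simulate_reads(small_genome, t, 10.0, seed=32)
        bins = gc_correct(bin_counts(reads.read_starts, small_genome, 900))
        dip = float(bins.loc[~bins["partial"], "corrected"].median())
        calls = call_cnvs(
            segment_bins(bins, seed=33), call_thresholds(dip, 0.01), dip, "s"
        )
        n_loss = sum(1 for c in calls if c.state == "loss")
        n_gain = len(calls) - n_loss
        assert n_loss > n_gain


class TestRdFilter:
    def test_study_like_stats_pass_sd_gate(self):
        # per-sample depth 13.31 with SD 4.9: a 20 kb region at RD 30 clears
        # the 3-SD gate because |30 - 13.31| > 3 * 4.9
        stats = DepthStats("N4", 13.31, 4.9)
        [call] = rd_filter([_call(30.0)], stats)
        assert call.provenance.filtered_pass

    def test_call_at_genome_mean_fails_with_p_one(self):
        stats = DepthStats("s", 100.0, 10.0)
        [call] = rd_filter([_call(100.0)], stats)
        assert not call.provenance.filtered_pass
        assert call.chi_sq_p == pytest.approx(1.0)

    def test_chi_square_closed_form(self):
        # O=150, E=100 in one unit: X2 = 25, p ~ 5.7e-7
        stats = DepthStats("s", 100.0, 10.0)
        [call] = rd_filter([_call(150.0, n_bins=1)], stats)
        assert call.chi_sq_p == pytest.approx(chi2.sf(25, 1), rel=1e-9)
        assert call.chi_sq_p == pytest.approx(5.7e-7, rel=0.01)
        assert call.provenance.filtered_pass

    def test_monotone_in_k(self, rng):
        stats = DepthStats("s", 100.0, 8.0)
        calls = [_call(float(m)) for m in rng.uniform(60, 180, 40)]
        passing = []
        for k in (1, 2, 3, 4, 6):
            flagged = rd_filter([_call(c.mean_rd) for c in calls], stats, k=k)
            passing.append(sum(bool(c.provenance.filtered_pass) for c in flagged))
        assert passing == sorted(passing, reverse=True)

    def test_strong_signal_completeness(self, small_genome):
        # every implanted CN-0 and CN>=6 region >= 15 kb passes at 10x
        specs = [
            simdata.CnvSpec("scaffold1", 50_000, 70_000, 0, "all"),
            simdata.CnvSpec("scaffold1", 150_000, 166_000, 6, "all"),
            simdata.CnvSpec("scaffold2", 80_000, 100_000, 8, "all"),
        ]
        truths = simdata.implant_cnvs(small_genome, specs=specs, seed=41)
        reads = simdata.simulate_reads(small_genome, truths[0], 10.0, seed=42)
        bins = gc_correct(bin_counts(reads.read_starts, small_genome, 900))
        dip = float(bins.loc[~bins["partial"], "corrected"].median())
        calls = call_cnvs(
            segment_bins(bins, seed=43), call_thresholds(dip, 0.01), dip, "s"
        )
        stats = depth_stats(bins, small_genome.sd_intervals, "s")
        calls = rd_filter(calls, stats)
        for scaf, s, e, cn in truths[0].cnv_intervals:
            hit = [
                c for c in calls
                if c.scaffold == scaf and min(c.end, e) - max(c.start, s) > 0
                and c.provenance.filtered_pass
            ]
            assert hit, f"strong CNV {scaf}:{s}-{e} (CN {cn}) did not pass"


def test_depth_stats_robust_to_implanted_cnvs(small_genome, small_reads, small_truths):
    t = small_truths[0]
    reads = small_reads[t.sample_id]
    bins = gc_correct(bin_counts(reads.read_starts, small_genome, 900))
    stats = depth_stats(bins, small_genome.sd_intervals)
    usable = bins[~bins["masked"] & ~bins["partial"]]
    lam = usable["corrected"].median()
    # centre tracks the diploid level, scale tracks Poisson bin noise
    assert stats.genome_mean_rd == pytest.approx(lam, rel=0.05)
    assert stats.genome_sd_rd == pytest.approx(np.sqrt(lam), rel=0.35)
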