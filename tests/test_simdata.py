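"""Synthetic-data generator: determinism, GC control, truth and depth laws."""

import numpy as np
import pytest

from silkcnv import simdata
from silkcnv.binning import bin_counts


def _hash_files(*paths):
    import hashlib

    h = hashlib.sha256()
    for p in paths:
        h.update(p.read_bytes())
    return h.hexdigest()


class TestSimulateGenome:
    def test_flat_gc_degenerate_case(self):
        g = simdata.simulate_genome(1, (100_000, 100_000), gc_params=0.5, seed=1)
        assert g.lengths() == {"scaffold1": 100_000}
        assert np.all(g.gc_profile["scaffold1"] == 0.5)
        # realized sequence GC is exactly the target in every aligned window
        seq = g.scaffolds["scaffold1"]
        for i in range(0, 100_000, 1000):
            win = seq[i : i + 1000]
            assert (win.count("G") + win.count("C")) == 500

    def test_determinism_byte_identical_outputs(self, tmp_path):
        digests = []
        for run in range(2):
            g = simdata.simulate_genome(3, (50_000, 80_000), seed=42)
            fa = tmp_path / f"r{run}.fa"
            bed = tmp_path / f"r{run}.bed"
            g.write_fasta(fa)
            g.write_sd_bed(bed)
            digests.append(_hash_files(fa, bed))
        assert digests[0] == digests[1]

    def test_sd_density_near_target(self):
        g = simdata.simulate_genome(
            5, (50_000, 200_000), sd_density=0.014, seed=7
        )
        span = sum(e - s for _, s, e in g.sd_intervals)
        assert 0.005 <= span / g.total_length <= 0.03

    def test_gc_landscape_spans_requested_range(self):
        g = simdata.simulate_genome(
            4, (200_000, 200_000), gc_params=(0.3, 0.6), seed=3
        )
        gc = np.concatenate(list(g.gc_profile.values()))
        assert gc.min() <= 0.33 and gc.max() >= 0.57
        assert np.all((gc >= 0.3) & (gc <= 0.6))

    def test_rejects_non_positive_lengths(self):
        with pytest.raises(ValueError, match="length_range"):
            simdata.simulate_genome(1, (0, 0), seed=1)


class TestImplantCnvs:
    def test_all_shared_gain_present_in_every_sample(self, small_genome):
        spec = simdata.CnvSpec("scaffold1", 10_000, 30_000, 4, sharing="all")
        truths = simdata.implant_cnvs(small_genome, specs=[spec], seed=0)
        assert len(truths) == 4
        for t in truths:
            assert ("scaffold1", 10_000, 30_000, 4) in t.cnv_intervals

    def test_group_specific_loss_in_exactly_that_group(self, small_genome):
        spec = simdata.CnvSpec(
            "scaffold1", 50_000, 70_000, 1, sharing="domesticated"
        )
        truths = simdata.implant_cnvs(small_genome, specs=[spec], seed=0)
        carriers = {t.sample_id for t in truths if t.cnv_intervals}
        assert carriers == {"dom1", "dom2"}

    def test_random_layout_intervals_non_overlapping(self, small_genome):
        truths = simdata.implant_cnvs(
            small_genome,
            random_params=simdata.RandomCnvParams(
                n_individual=10, n_group=5, n_all=5, length_range=(5_000, 12_000)
            ),
            seed=5,
        )
        for t in truths:
            assert len(t.cnv_intervals) == 20
            ivs = sorted(t.cnv_intervals)
            # brute-force pairwise sweep
            for a in range(len(ivs)):
                for b in range(a + 1, len(ivs)):
                    sa, s0, e0, _ = ivs[a]
                    sb, s1, e1, _ = ivs[b]
                    assert not (sa == sb and s0 < e1 and s1 < e0)

    def test_overlapping_requested_intervals_rejected(self, small_genome):
        specs = [
            simdata.CnvSpec("scaffold1", 10_000, 30_000, 4, "all"),
            simdata.CnvSpec("scaffold1", 25_000, 45_000, 1, "all"),
        ]
        with pytest.raises(ValueError, match="overlap"):
            simdata.implant_cnvs(small_genome, specs=specs, seed=0)

    def test_copy_number_two_rejected(self, small_genome):
        with pytest.raises(ValueError, match="!= 2"):
            simdata.implant_cnvs(
                small_genome,
                specs=[simdata.CnvSpec("scaffold1", 0, 10_000, 2, "all")],
                seed=0,
            )


class TestSimulateReads:
    def test_total_reads_poisson_mean(self):
        g = simdata.simulate_genome(1, (1_000_000, 1_000_000), gc_params=0.5, seed=1)
        t = simdata.SyntheticTruth("s", "domesticated")
        reads = simdata.simulate_reads(g, t, 10.0, read_length=100, seed=2)
        expected = 100_000
        assert abs(reads.total_reads - expected) <= 3 * np.sqrt(expected)
        assert abs(reads.coverage(g.total_length) - 10.0) / 10.0 < 0.01

    def test_homozygous_deletion_has_no_read_starts(self, small_genome):
        t = simdata.SyntheticTruth(
            "s", "wild", [("scaffold1", 100_000, 120_000, 0)]
        )
        reads = simdata.simulate_reads(small_genome, t, 10.0, seed=3)
        starts = reads.read_starts["scaffold1"]
        assert not np.any((starts >= 100_000) & (starts < 120_000))

    def test_duplication_doubles_local_depth(self):
        g = simdata.simulate_genome(1, (500_000, 500_000), gc_params=0.5, seed=4)
        t = simdata.SyntheticTruth("s", "wild", [("scaffold1", 200_000, 210_000, 4)])
        reads = simdata.simulate_reads(g, t, 10.0, seed=5)
        starts = reads.read_starts["scaffold1"]
        inside = np.sum((starts >= 200_000) & (starts < 210_000)) / 10_000
        outside = (len(starts) - inside * 10_000) / 490_000
        assert 1.8 <= inside / outside <= 2.2

    def test_depth_proportionality_over_random_truths(self, small_genome, rng):
        # per-interval depth ratio estimates copy/2 within 10% (>=10 kb, 10x)
        checked = 0
        for k in range(20):
            cn = int(rng.choice([0, 1, 3, 4, 6]))
            start = int(rng.integers(0, 250_000))
            t = simdata.SyntheticTruth(
                "s", "wild", [("scaffold1", start, start + 15_000, cn)]
            )
            reads = simdata.simulate_reads(small_genome, t, 12.0, seed=1000 + k)
            starts = reads.read_starts["scaffold1"]
            n_in = np.sum((starts >= start) & (starts < start + 15_000))
            depth_in = n_in / 15_000
            n_out = len(starts) - n_in
            depth_out = n_out / (300_000 - 15_000)
            if cn == 0:
                assert n_in == 0
                continue
            assert abs(depth_in / depth_out - cn / 2) <= 0.1 * (cn / 2) + 0.02
            checked += 1
        assert checked >= 10

    def test_gc_bias_modulates_rate_but_preserves_mean(self):
        g = simdata.simulate_genome(4, (300_000, 300_000), seed=6)
        t = simdata.SyntheticTruth("s", "wild")
        bias = simdata.sin_bump_bias(0.5)
        plain = simdata.simulate_reads(g, t, 10.0, seed=7)
        biased = simdata.simulate_reads(g, t, 10.0, gc_bias_fn=bias, seed=7)
        # renormalisation keeps genome-wide totals comparable
        assert abs(biased.total_reads - plain.total_reads) < 0.03 * plain.total_reads

    def test_short_scaffold_skipped_with_warning(self):
        g = simdata.SyntheticGenome(scaffolds={"tiny": "ACGT" * 10})
        t = simdata.SyntheticTruth("s", "wild")
        with pytest.warns(UserWarning, match="shorter than read length"):
            reads = simdata.simulate_reads(g, t, 10.0, read_length=100, seed=1)
        assert "tiny" not in reads.read_starts


def test_truth_bed_round_trip(tmp_path, small_truths):
    path = tmp_path / "truth.bed"
    simdata.write_truth_bed(small_truths, path)
    back = simdata.read_truth_bed(path)
    by_id = {t.sample_id: t for t in back}
    for t in small_truths:
        assert by_id[t.sample_id].cnv_intervals == sorted(t.cnv_intervals)
        assert by_id[t.sample_id].group_label == t.group_label


def test_sam_round_trip_read_count(tmp_path, small_genome):
    from silkcnv.seqio import read_alignments

    t = simdata.SyntheticTruth("s", "wild", [("scaffold1", 50_000, 60_000, 4)])
    reads = simdata.simulate_reads(small_genome, t, 2.0, seed=8)
    sam = tmp_path / "s.sam"
    reads.write_sam(small_genome, sam)
    loaded = read_alignments(sam)
    assert sum(len(v) for v in loaded.values()) == reads.total_reads
    for scaf, starts in reads.read_starts.items():
        assert np.array_equal(np.sort(starts), loaded[scaf])


def test_binned_depth_is_poissonian(small_genome, control_reads):
    bins = bin_counts(control_reads.read_starts, small_genome, 1000)
    full = bins[~bins["partial"]]
    ratio = full["raw_count"].var() / full["raw_count"].mean()
    assert 0.8 <= ratio <= 1.3
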