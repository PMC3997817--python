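"""Ratio windows, total-variation smoothing and dual-caller intersection."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize

from silkcnv.calling import CnvCall, Provenance
from silkcnv.consensus import (
    intersect_calls,
    ratio_calls,
    ratio_windows,
    smooth_and_snap,
    tv_denoise,
)


def _uniformish_reads(rng, length, n):
    return {"s1": np.sort(rng.integers(0, length, n))}


class TestRatioWindows:
    def test_identical_sets_give_unit_ratios(self, rng):
        reads = _uniformish_reads(rng, 1_000_000, 30_000)
        w = ratio_windows(reads, reads, {"s1": 1_000_000}, 150)
        assert np.allclose(w["ratio"], 1.0)

    def test_duplicated_region_doubles_ratio(self, rng):
        length = 1_000_000
        ctrl = _uniformish_reads(rng, length, 30_000)["s1"]
        extra = ctrl[(ctrl >= 400_000) & (ctrl < 500_000)]
        smp = {"s1": np.sort(np.concatenate([ctrl, extra]))}
        w = ratio_windows(smp, {"s1": ctrl}, {"s1": length}, 150)
        mid = w[(w.start >= 405_000) & (w.end <= 495_000)]
        out = w[(w.end <= 395_000) | (w.start >= 505_000)]
        scale = (len(ctrl) + len(extra)) / len(ctrl)
        assert np.median(mid["ratio"]) * scale == pytest.approx(2.0, rel=0.05)
        assert np.median(out["ratio"]) * scale == pytest.approx(1.0, rel=0.05)

    def test_window_count_and_control_occupancy(self, rng):
        reads = {"s1": np.sort(rng.choice(2_000_000, 20_000, replace=False))}
        w = ratio_windows(reads, reads, {"s1": 2_000_000}, 150)
        assert abs(len(w) - 20_000 // 150) <= 1
        assert (w["control_count"].iloc[:-1] == 150).all()

    def test_sparse_scaffold_flagged_whole(self, rng):
        smp = {"s1": np.arange(100)}
        w = ratio_windows(smp, smp, {"s1": 10_000}, 150)
        assert len(w) == 1 and bool(w["flagged"].iloc[0])


class TestTvDenoise:
    def test_zero_weight_is_identity(self, rng):
        y = rng.normal(0, 1, 50)
        assert np.array_equal(tv_denoise(y, 0.0), y)

    def test_infinite_weight_is_mean(self, rng):
        y = rng.normal(3, 1, 50)
        assert np.allclose(tv_denoise(y, np.inf), y.mean())

    def test_minimises_the_tv_objective(self, rng):
        def obj(x, y, lam):
            return 0.5 * np.sum((x - y) ** 2) + lam * np.sum(np.abs(np.diff(x)))

        for _ in range(25):
            n = int(rng.integers(2, 20))
            y = rng.normal(0, 1, n)
            lam = float(rng.uniform(0.05, 2))
            x = tv_denoise(y, lam)
            r = minimize(
                obj, y, args=(y, lam), method="Nelder-Mead",
                options={"maxiter": 20_000, "fatol": 1e-12, "xatol": 1e-10},
            )
            assert obj(x, y, lam) <= r.fun + 1e-8


def _window_frame(ratios, width=1000):
    return pd.DataFrame(
        {
            "scaffold": "s1",
            "start": np.arange(len(ratios)) * width,
            "end": (np.arange(len(ratios)) + 1) * width,
            "sample_count": 150,
            "control_count": 150,
            "ratio": ratios,
            "flagged": False,
        }
    )


class TestSmoothAndSnap:
    BLOCKS = np.repeat([1.0, 1.0, 2.0, 2.0, 1.0], 20)

    def test_noise_free_levels_snapped_exactly(self):
        out = smooth_and_snap(_window_frame(self.BLOCKS), 7.0)
        assert out["smoothed_cn"].tolist() == list(
            np.repeat([2, 2, 4, 4, 2], 20)
        )

    def test_gaussian_noise_does_not_change_levels(self, rng):
        noisy = self.BLOCKS + rng.normal(0, 0.1, self.BLOCKS.size)
        out = smooth_and_snap(_window_frame(noisy), 7.0)
        assert out["smoothed_cn"].tolist() == list(
            np.repeat([2, 2, 4, 4, 2], 20)
        )

    def test_huge_lambda_collapses_to_single_level(self, rng):
        noisy = self.BLOCKS + rng.normal(0, 0.1, self.BLOCKS.size)
        out = smooth_and_snap(_window_frame(noisy), 1e9)
        assert out["smoothed_cn"].nunique() == 1

    def test_level_count_monotone_in_lambda(self, rng):
        noisy = self.BLOCKS + rng.normal(0, 0.25, self.BLOCKS.size)
        levels = [
            smooth_and_snap(_window_frame(noisy), lam)["fitted"].round(9).nunique()
            for lam in (0.5, 2, 7, 30, 1000)
        ]
        assert levels == sorted(levels, reverse=True)

    def test_degenerate_equal_ratios_give_diploid(self):
        out = smooth_and_snap(_window_frame(np.ones(20)), 7.0)
        assert (out["smoothed_cn"] == 2).all()

    def test_ratio_calls_merge_consecutive_windows(self):
        out = smooth_and_snap(_window_frame(self.BLOCKS), 7.0)
        calls = ratio_calls(out, "s")
        assert len(calls) == 1
        c = calls[0]
        assert (c.start, c.end, c.state, c.copy_number) == (40_000, 80_000, "gain", 4)


def _mk(scaf, start, end, state="gain", sample="s"):
    cn = 4 if state == "gain" else 1
    return CnvCall(
        sample_id=sample, scaffold=scaf, start=start, end=end, state=state,
        copy_number=cn, mean_rd=0.0, provenance=Provenance(rd_caller=True),
    )


class TestIntersectCalls:
    def test_disjoint_sets_empty(self):
        res = intersect_calls([_mk("s1", 0, 100)], [_mk("s1", 500, 600)])
        assert res.consensus == [] and len(res.dropped_rd) == 1
        assert len(res.unmatched_ratio) == 1

    def test_identical_sets_identity(self):
        a = [_mk("s1", 0, 100), _mk("s2", 50, 80, "loss")]
        res = intersect_calls(a, [_mk("s1", 0, 100), _mk("s2", 50, 80, "loss")])
        assert [(c.scaffold, c.start, c.end) for c in res.consensus] == [
            ("s1", 0, 100), ("s2", 50, 80)
        ]
        assert all(c.provenance.ratio_caller for c in res.consensus)

    def test_state_mismatch_not_consensus(self):
        res = intersect_calls([_mk("s1", 0, 100, "gain")], [_mk("s1", 0, 100, "loss")])
        assert res.consensus == []

    def test_matches_quadratic_oracle(self, rng):
        def rand_calls(n):
            out = []
            for _ in range(n):
                a = int(rng.integers(0, 10_000))
                out.append(
                    _mk("s1", a, a + int(rng.integers(50, 500)),
                        "gain" if rng.random() < 0.5 else "loss")
                )
            return out

        A, B = rand_calls(50), rand_calls(50)
        res = intersect_calls(A, B)
        expect = [
            a for a in A
            if any(
                b.state == a.state
                and min(a.end, b.end) - max(a.start, b.start) >= 1
                for b in B
            )
        ]
        assert [(c.start, c.end) for c in res.consensus] == [
            (c.start, c.end) for c in expect
        ]

    def test_result_subset_of_rd_intervals(self, rng):
        A = [_mk("s1", i * 100, i * 100 + 80) for i in range(10)]
        B = [_mk("s1", 50, 3000)]
        res = intersect_calls(A, B)
        a_keys = {(c.scaffold, c.start, c.end) for c in A}
        assert all((c.scaffold, c.start, c.end) in a_keys for c in res.consensus)
        assert len(res.consensus) <= len(A)

    def test_reciprocal_threshold(self):
        # 10% overlap passes the 1-bp rule but fails 50% reciprocal
        res = intersect_calls(
            [_mk("s1", 0, 1000)], [_mk("s1", 900, 1900)], reciprocal=0.5
        )
        assert res.consensus == []


def test_consensus_precision_not_worse_than_single_caller(
    small_genome, small_truths, small_reads, control_reads, config, tmp_path
):
    from silkcnv.pipeline import run_sample
    from conftest import precision_recall

    t = small_truths[0]
    cons, filt, _, _ = run_sample(
        t.sample_id,
        small_reads[t.sample_id].read_starts,
        small_genome,
        control_reads.read_starts,
        config,
        seed=55,
    )
    truth = [
        (s, a, b, "gain" if cn > 2 else "loss") for s, a, b, cn in t.cnv_intervals
    ]
    p_cons, _ = precision_recall(
        [(c.scaffold, c.start, c.end, c.state) for c in cons], truth
    )
    p_filt, _ = precision_recall(
        [(c.scaffold, c.start, c.end, c.state) for c in filt], truth
    )
    assert p_cons >= p_filt
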