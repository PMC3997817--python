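"""Truth-based validation benchmarks on synthetic data.

Each function here sets up a synthetic study with known truth, runs the
relevant part of the pipeline, and measures how well it recovers that truth:
consensus precision/recall at reciprocal overlap, sharing-class fidelity and
group clustering, GC-correction effectiveness, segmentation changepoints
against exhaustive search, and comparative-Ct copy-number recovery. The
acceptance script and the test suite both run these.

All entry points take an explicit ``seed``; derived seeds stay below 2**31.
"""

from __future__ import annotations

import numpy as np

from . import binning, comparative, simdata
from .config import PipelineConfig
from .pipeline import run_sample
from .qpcr import analyze_ct_table, simulate_ct_table
from .segmentation import best_split

__all__ = [
    "precision_recall",
    "consensus_recovery",
    "sharing_and_clustering",
    "gc_correction_metrics",
    "cbs_oracle_agreement",
    "qpcr_recovery",
]


def _overlap(a, b):
    return max(0, min(a[2], b[2]) - max(a[1], b[1])) if a[0] == b[0] else 0


def _reciprocal(a, b, frac):
    ov = _overlap(a, b)
    return ov >= frac * (a[2] - a[1]) and ov >= frac * (b[2] - b[1])


def precision_recall(predicted, truth, frac=0.5):
    """Interval-set precision/recall at reciprocal overlap ``frac``.

    Both inputs are (scaffold, start, end, state) tuples; a predicted call is
    a true positive when some same-state truth interval matches it
    reciprocally.
    """
    tp = sum(
        any(_reciprocal(p[:3], q[:3], frac) and p[3] == q[3] for q in truth)
        for p in predicted
    )
    found = sum(
        any(_reciprocal(p[:3], q[:3], frac) and p[3] == q[3] for p in predicted)
        for q in truth
    )
    prec = tp / len(predicted) if predicted else float("nan")
    rec = found / len(truth) if truth else float("nan")
    return prec, rec


def _seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(n)]


def consensus_recovery(
    seed: int,
    n_scaffolds: int = 10,
    length_range: tuple[int, int] = (450_000, 550_000),
    coverage: float = 10.0,
    gc_bias_amplitude: float = 0.3,
    config: PipelineConfig | None = None,
) -> dict:
    """Four-sample study-design recovery benchmark.

    Simulates a ~5 Mb genome, implants 20 CNVs per sample (CN in
    {0, 1, 3, 4, 6}, 10-35 kb) with the study's sharing structure, samples
    GC-biased reads at the given coverage, runs the full per-sample pipeline
    (binning, GC correction, CBS, calling, 3-SD + chi-square filter, ratio-
    caller consensus) and scores consensus calls against the implanted truth
    at 50% reciprocal overlap.
    """
    config = config or PipelineConfig()
    s_genome, s_truth, s_ctrl, *s_samples = _seeds(seed, 7)
    genome = simdata.simulate_genome(n_scaffolds, length_range, seed=s_genome)
    truths = simdata.implant_cnvs(
        genome, random_params=simdata.RandomCnvParams(), seed=s_truth
    )
    bias = (
        simdata.sin_bump_bias(gc_bias_amplitude) if gc_bias_amplitude else None
    )
    control = simdata.simulate_reads(
        genome, simdata.SyntheticTruth("control", "control"), coverage,
        gc_bias_fn=bias, seed=s_ctrl,
    )
    predicted, truth_ivs = [], []
    for t, s in zip(truths, s_samples):
        reads = simdata.simulate_reads(
            genome, t, coverage, gc_bias_fn=bias, seed=s
        )
        cons, _, _, _ = run_sample(
            t.sample_id, reads.read_starts, genome, control.read_starts,
            config, seed=s,
        )
        predicted += [
            (c.scaffold, c.start, c.end, c.state, t.sample_id) for c in cons
        ]
        truth_ivs += [
            (scaf, a, b, "gain" if cn > 2 else "loss", t.sample_id)
            for scaf, a, b, cn in t.cnv_intervals
        ]
    # score per sample: fold the sample id into the scaffold key
    pred = [(f"{p[4]}:{p[0]}", p[1], p[2], p[3]) for p in predicted]
    tr = [(f"{q[4]}:{q[0]}", q[1], q[2], q[3]) for q in truth_ivs]
    prec, rec = precision_recall(pred, tr)
    return {
        "precision": prec,
        "recall": rec,
        "n_consensus_calls": len(pred),
        "n_truth_cnvs": len(tr),
    }


SHARING_LAYOUT = (
    ("scaffold1", 50_000, 70_000, 4, "all", "all-possessed"),
    ("scaffold2", 100_000, 120_000, 1, "domesticated", "domesticated-specific"),
    ("scaffold3", 150_000, 170_000, 6, "wild", "wild-specific"),
    ("scaffold4", 80_000, 100_000, 0, "dom1", "individual-specific"),
    ("scaffold4", 200_000, 220_000, 4, "wild2", "individual-specific"),
)


def sharing_and_clustering(
    seed: int, coverage: float = 10.0, config: PipelineConfig | None = None
) -> dict:
    """Implant one CNV per sharing class and check the comparative stage.

    Runs the full pipeline per sample, builds the copy-number matrix from the
    consensus calls, classifies region sharing, and clusters the samples.
    Returns the fraction of implanted regions classified into exactly their
    class and whether each group's two samples are sisters in the dendrogram.
    """
    config = config or PipelineConfig()
    s_genome, s_ctrl, *s_samples = _seeds(seed, 6)
    genome = simdata.simulate_genome(4, (300_000, 300_000), seed=s_genome)
    specs = [
        simdata.CnvSpec(scaf, a, b, cn, sharing)
        for scaf, a, b, cn, sharing, _ in SHARING_LAYOUT
    ]
    truths = simdata.implant_cnvs(genome, specs=specs, seed=seed)
    control = simdata.simulate_reads(
        genome, simdata.SyntheticTruth("control", "control"), coverage,
        seed=s_ctrl,
    )
    all_cons = []
    for t, s in zip(truths, s_samples):
        reads = simdata.simulate_reads(genome, t, coverage, seed=s)
        cons, _, _, _ = run_sample(
            t.sample_id, reads.read_starts, genome, control.read_starts,
            config, seed=s,
        )
        all_cons.extend(cons)
    samples = [t.sample_id for t in truths]
    groups = {t.sample_id: t.group_label for t in truths}
    cnm = comparative.build_matrix(all_cons, samples)
    classes = comparative.classify_sharing(cnm, groups)

    correct = 0
    for scaf, a, b, _, _, want in SHARING_LAYOUT:
        hit = classes[
            (classes["scaffold"] == scaf)
            & (classes["start"] < b)
            & (classes["end"] > a)
        ]
        if len(hit) == 1 and hit["sharing_class"].iloc[0] == want:
            correct += 1
    newick = comparative.cluster_samples(cnm)

    def sisters(pair):
        from io import StringIO

        from Bio import Phylo

        tree = Phylo.read(StringIO(newick), "newick")
        for clade in tree.find_clades():
            if sorted(x.name for x in clade.get_terminals()) == sorted(pair):
                return True
        return False

    return {
        "classification_accuracy": correct / len(SHARING_LAYOUT),
        "n_regions": len(cnm.regions),
        "domesticated_pair_sisters": sisters(("dom1", "dom2")),
        "wild_pair_sisters": sisters(("wild1", "wild2")),
        "newick": newick,
    }


def gc_correction_metrics(
    seed: int,
    amplitude: float = 0.3,
    n_scaffolds: int = 10,
    scaffold_length: int = 1_000_000,
    coverage: float = 10.0,
) -> dict:
    """Slope of count-vs-GC before/after LOESS, plus the null-bias change.

    One genome, two read sets: one with a sin-bump GC bias of the given
    amplitude, one unbiased. Reports the linear-fit slope reduction on the
    biased set and the maximum per-bin relative change on the null set.
    """
    s_genome, s_biased, s_null = _seeds(seed, 3)
    genome = simdata.simulate_genome(
        n_scaffolds, (scaffold_length, scaffold_length), seed=s_genome
    )
    t = simdata.SyntheticTruth("s", "wild")

    biased = simdata.simulate_reads(
        genome, t, coverage,
        gc_bias_fn=simdata.sin_bump_bias(amplitude), seed=s_biased,
    )
    bins = binning.gc_correct(
        binning.bin_counts(biased.read_starts, genome, 1000)
    )
    ok = (~bins["masked"] & ~bins["partial"]).to_numpy()
    gc = bins.loc[ok, "gc"].to_numpy()
    slope_raw = float(
        np.polyfit(gc, bins.loc[ok, "raw_count"].to_numpy(), 1)[0]
    )
    slope_cor = float(
        np.polyfit(gc, bins.loc[ok, "corrected"].to_numpy(), 1)[0]
    )

    null_reads = simdata.simulate_reads(genome, t, coverage, seed=s_null)
    nbins = binning.gc_correct(
        binning.bin_counts(null_reads.read_starts, genome, 1000)
    )
    nok = ~nbins["masked"] & ~nbins["partial"] & (nbins["raw_count"] > 0)
    rel = np.abs(
        nbins.loc[nok, "corrected"] / nbins.loc[nok, "raw_count"] - 1
    )
    return {
        "slope_raw": slope_raw,
        "slope_corrected": slope_cor,
        "slope_reduction_fold": abs(slope_raw) / max(abs(slope_cor), 1e-12),
        "null_max_relative_change": float(rel.max()),
        "n_bins": int(ok.sum()),
    }


def _exhaustive_best_split(x, min_width=2):
    """Reference changepoint search: direct double loop over all arcs."""
    x = np.asarray(x, dtype=float)
    n = x.size
    best = None
    for i in range(n + 1):
        for j in range(i + min_width, n + 1):
            k = j - i
            if k > n - min_width:
                continue
            arc, rest = x[i:j], np.concatenate([x[:i], x[j:]])
            mi, mo = arc.mean(), rest.mean()
            sp2 = (((arc - mi) ** 2).sum() + ((rest - mo) ** 2).sum()) / max(
                n - 2, 1
            )
            t = abs(mi - mo) / np.sqrt(max(sp2, 1e-12) * (1 / k + 1 / (n - k)))
            if best is None or t > best[2] + 1e-12:
                best = (i, j, t)
    return best


def cbs_oracle_agreement(seed: int, n_cases: int = 100) -> dict:
    """Fraction of short random series where the CBS split matches
    exhaustive max-statistic search (changepoint sets compared; an arc and
    its complement are the same split)."""
    rng = np.random.default_rng(seed)
    agree = 0
    for _ in range(n_cases):
        n = int(rng.integers(4, 13))
        x = rng.normal(0, 1, n)
        if rng.random() < 0.5:
            a, b = sorted(rng.choice(n + 1, size=2, replace=False))
            x[a:b] += rng.normal(0, 3)
        got = best_split(x)
        want = _exhaustive_best_split(x)
        if ({got[0], got[1]} - {0, n}) == ({want[0], want[1]} - {0, n}):
            agree += 1
    return {"agreement": agree / n_cases, "n_cases": n_cases}


def qpcr_recovery(
    seed: int,
    n_trials: int = 200,
    copy_numbers: tuple[int, ...] = (1, 2, 4, 8),
    ct_noise_sd: float = 0.1,
    n_replicates: int = 12,
) -> dict:
    """Comparative-Ct recovery rate of known copy numbers.

    For each trial a Ct table is simulated at perfect efficiency with
    Gaussian Ct noise, analysed, and the estimate rounded; the rate is the
    fraction of trials whose rounded estimate equals the truth. The replicate
    count defaults to 12: sd(ddCt) = 2*sigma/sqrt(r) must stay well below
    log2(8.5/8) to resolve CN 8 to the nearest copy.
    """
    hits = 0
    for k, s in enumerate(_seeds(seed, n_trials)):
        truth = copy_numbers[k % len(copy_numbers)]
        table = simulate_ct_table(
            {"ref": {"t": 2.0}, "test": {"t": float(truth)}},
            reference_sample_id="ref",
            ct_noise_sd=ct_noise_sd,
            n_replicates=n_replicates,
            seed=s,
        )
        res = analyze_ct_table(table)
        row = res[(res["sample_id"] == "test") & (res["target_id"] == "t")]
        if round(float(row["copy_number"].iloc[0])) == truth:
            hits += 1
    return {"recovery_rate": hits / n_trials, "n_trials": n_trials}
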