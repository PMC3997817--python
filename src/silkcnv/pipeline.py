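"""End-to-end orchestration of the CNV discovery workflow.

Runs the stages in order — depth loading, binning, GC correction,
segmentation, calling, high-confidence filtering, ratio-caller consensus,
cross-sample comparison, SD/gene annotation — from one configuration, and
records a manifest (config hash, seeds, per-stage counts and output paths).
Stage outputs are plain text (TSV/BED/newick/JSON); a stage whose output
already exists is reloaded rather than recomputed, so a run is resumable.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import annotate as annotate_mod
from . import binning, calling, comparative, consensus, seqio
from .config import PipelineConfig
from .segmentation import segment_bins
from .simdata import SyntheticGenome

logger = logging.getLogger("silkcnv")

__all__ = ["RunManifest", "run_sample", "run_all"]


@dataclass
class RunManifest:
    config_digest: str
    seed: int | None
    counts: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True))


def _calls_to_frame(calls) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (
                c.sample_id, c.scaffold, c.start, c.end, c.state,
                c.copy_number, c.mean_rd, c.n_bins, c.chi_sq_p,
                c.provenance.rd_caller, c.provenance.ratio_caller,
                c.provenance.filtered_pass,
            )
            for c in calls
        ],
        columns=[
            "sample_id", "scaffold", "start", "end", "state", "copy_number",
            "mean_rd", "n_bins", "chi_sq_p", "rd_caller", "ratio_caller",
            "filtered_pass",
        ],
    )


def calls_from_frame(frame: pd.DataFrame) -> list:
    """Inverse of the call-table writer used by the CLI stages."""
    out = []
    for r in frame.itertuples(index=False):
        out.append(
            calling.CnvCall(
                sample_id=r.sample_id,
                scaffold=r.scaffold,
                start=int(r.start),
                end=int(r.end),
                state=r.state,
                copy_number=int(r.copy_number),
                mean_rd=float(r.mean_rd),
                n_bins=int(r.n_bins),
                chi_sq_p=None if pd.isna(r.chi_sq_p) else float(r.chi_sq_p),
                provenance=calling.Provenance(
                    rd_caller=bool(r.rd_caller),
                    ratio_caller=bool(r.ratio_caller),
                    filtered_pass=None
                    if pd.isna(r.filtered_pass)
                    else bool(r.filtered_pass),
                ),
            )
        )
    return out


def run_sample(
    sample_id: str,
    read_starts: Mapping[str, np.ndarray],
    genome: SyntheticGenome,
    control_reads: Mapping[str, np.ndarray],
    config: PipelineConfig,
    seed: int | None = None,
    read_length: int | None = None,
):
    """Full single-sample pipeline: bins -> segments -> calls -> consensus.

    Returns (consensus_calls, filtered_calls, all_calls, bins). ``seed``
    drives the segmentation permutation test only.
    """
    rl = read_length or config.read_length
    total = sum(len(v) for v in read_starts.values())
    coverage = total * rl / genome.total_length
    width = binning.select_bin_size(
        coverage, rl, alpha=config.fdr_alpha, p_min=config.detection_power
    )
    logger.info("%s: coverage %.2fx, bin width %d bp", sample_id, coverage, width)
    bins = binning.bin_counts(read_starts, genome, width)
    bins = binning.gc_correct(bins, loess_span=config.loess_span)
    segments = segment_bins(
        bins,
        perm_alpha=config.perm_alpha,
        n_perm=config.n_perm,
        min_width=config.min_width,
        seed=seed,
    )
    usable = bins[~bins["masked"] & ~bins["partial"]]
    diploid_mean = float(usable["corrected"].median())
    thresholds = calling.call_thresholds(diploid_mean, alpha=config.fdr_alpha)
    calls = calling.call_cnvs(segments, thresholds, diploid_mean, sample_id)
    stats = calling.depth_stats(bins, genome.sd_intervals, sample_id)
    calls = calling.rd_filter(
        calls, stats, k=config.sd_multiplier, chi_sq_alpha=config.chi_sq_alpha
    )
    filtered = [c for c in calls if c.provenance.filtered_pass]

    windows = consensus.ratio_windows(
        read_starts, control_reads, genome.lengths(), read_num=config.read_num
    )
    smoothed = consensus.smooth_and_snap(
        windows, lambda_s=config.smoothing_lambda,
        ploidy_offset=config.ploidy_offset,
    )
    rcalls = consensus.ratio_calls(smoothed, sample_id)
    result = consensus.intersect_calls(filtered, rcalls)
    return result.consensus, filtered, calls, bins


def run_all(
    sample_reads: Mapping[str, Mapping[str, np.ndarray]],
    genome: SyntheticGenome,
    control_reads: Mapping[str, np.ndarray],
    groups: Mapping[str, str],
    config: PipelineConfig,
    outdir: str | Path,
    seed: int | None = None,
    genes=None,
) -> RunManifest:
    """Run every sample plus the cross-sample comparative stages.

    Writes per-sample call TSV/BED, the copy-number matrix, sharing classes,
    the sample dendrogram, the SD-overlap report and a run manifest under
    ``outdir``; returns the manifest. The per-call funnel (all >= filtered >=
    consensus) is recorded in the manifest counts.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config_digest=config.digest(), seed=seed)
    prior_counts: dict = {}
    if (outdir / "manifest.json").exists():
        prior_counts = json.loads((outdir / "manifest.json").read_text()).get(
            "counts", {}
        )
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(sample_reads))

    all_consensus = []
    for (sid, reads), child in zip(sample_reads.items(), children):
        sample_seed = int(child.generate_state(1)[0] % (2**31))
        calls_path = outdir / f"{sid}.calls.tsv"
        cons_path = outdir / f"{sid}.consensus.tsv"
        n_bins = None
        if calls_path.exists() and cons_path.exists():
            logger.info("%s: resuming from existing call tables", sid)
            calls = calls_from_frame(pd.read_csv(calls_path, sep="\t"))
            cons = calls_from_frame(pd.read_csv(cons_path, sep="\t"))
            filtered = [c for c in calls if c.provenance.filtered_pass]
            n_bins = prior_counts.get(sid, {}).get("bins")
        else:
            cons, filtered, calls, bins = run_sample(
                sid, reads, genome, control_reads, config, seed=sample_seed
            )
            n_bins = int(len(bins))
            _calls_to_frame(calls).to_csv(calls_path, sep="\t", index=False)
            _calls_to_frame(cons).to_csv(cons_path, sep="\t", index=False)
            seqio.write_calls_bed(cons, outdir / f"{sid}.consensus.bed")
        if not (len(calls) >= len(filtered) >= len(cons)):
            raise AssertionError("call funnel must be non-increasing")
        manifest.counts[sid] = {
            "reads": int(sum(len(v) for v in reads.values())),
            "bins": n_bins,
            "calls": len(calls),
            "filtered": len(filtered),
            "consensus": len(cons),
        }
        manifest.outputs[sid] = f"{sid}.calls.tsv"
        all_consensus.extend(cons)

    if all_consensus:
        cnm = comparative.build_matrix(all_consensus, samples=list(sample_reads))
        cnm.to_tsv(outdir / "copy_number_matrix.tsv")
        classes = comparative.classify_sharing(cnm, groups)
        classes.to_csv(outdir / "sharing_classes.tsv", sep="\t", index=False)
        newick = comparative.cluster_samples(cnm)
        (outdir / "samples.nwk").write_text(newick + "\n")
        report = annotate_mod.sd_overlap(all_consensus, genome.sd_intervals)
        summary = {
            "n_cnvs": report.n_cnvs,
            "n_overlapping_sd": report.n_overlapping_sd,
            "sd_overlap_fraction": report.fraction,
        }
        if genes is not None:
            _, flat = annotate_mod.genes_in_cnvs(all_consensus, genes)
            summary["n_genes_in_cnvs"] = len(flat)
        (outdir / "annotation.json").write_text(json.dumps(summary, indent=2))
        manifest.counts["regions"] = len(cnm.regions)
        manifest.outputs["matrix"] = "copy_number_matrix.tsv"
        manifest.outputs["dendrogram"] = "samples.nwk"

    manifest.save(outdir / "manifest.json")
    return manifest
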