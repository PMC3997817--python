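"""Gain/loss CNV calling and the high-confidence read-depth filter.

Segments become calls when their mean corrected count crosses Normal-
approximation thresholds around the diploid level (strict inequalities);
absolute copy number is ``round(2 * segment_mean / diploid_mean)``, floored
at 0 and capped at 20. The high-confidence filter keeps a call only when its
read depth lies more than ``k`` standard deviations from the genome mean
computed over unique regions (genome minus segmental duplications) *and* a
per-region 1-df chi-square test of total observed vs expected reads gives
p below ``chi_sq_alpha``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2, norm

from .segmentation import Segment

__all__ = [
    "CnvCall",
    "Provenance",
    "DepthStats",
    "call_thresholds",
    "absolute_copy_number",
    "call_cnvs",
    "depth_stats",
    "rd_filter",
]


@dataclass
class Provenance:
    rd_caller: bool = False
    ratio_caller: bool = False
    filtered_pass: bool | None = None


@dataclass
class CnvCall:
    """A gain/loss interval with its absolute copy number."""

    sample_id: str
    scaffold: str
    start: int
    end: int
    state: str  # "gain" | "loss"
    copy_number: int
    mean_rd: float
    n_bins: int = 0
    chi_sq_p: float | None = None
    provenance: Provenance = field(default_factory=Provenance)

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("call must have end > start")
        if self.state == "gain" and not self.copy_number > 2:
            raise ValueError("gain requires copy_number > 2")
        if self.state == "loss" and not self.copy_number < 2:
            raise ValueError("loss requires copy_number < 2")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class DepthStats:
    """Genome read-depth mean and SD over unique (non-SD) regions."""

    sample_id: str
    genome_mean_rd: float
    genome_sd_rd: float

    def __post_init__(self) -> None:
        if self.genome_mean_rd <= 0:
            raise ValueError("genome mean read depth must be > 0")
        if self.genome_sd_rd < 0:
            raise ValueError("genome read-depth SD must be >= 0")


def call_thresholds(lam_diploid: float, alpha: float = 0.01) -> tuple[float, float]:
    """(t_loss, t_gain) around the diploid per-bin mean ``lam_diploid``.

    Normal approximation: t = lambda +/- z(1 - alpha/2) * sqrt(lambda);
    a negative loss threshold is clamped to 0 with a warning.
    """
    if lam_diploid <= 0:
        raise ValueError("lam_diploid must be > 0")
    z = norm.ppf(1 - alpha / 2)
    half = z * np.sqrt(lam_diploid)
    t_loss, t_gain = lam_diploid - half, lam_diploid + half
    if t_loss < 0:
        warnings.warn("loss threshold below 0; clamped", stacklevel=2)
        t_loss = 0.0
    return float(t_loss), float(t_gain)


def absolute_copy_number(
    segment_mean: float, diploid_mean: float, cap: int = 20
) -> int:
    """round(2 * segment_mean / diploid_mean), half away from zero; in [0, cap]."""
    if diploid_mean <= 0:
        raise ValueError("diploid_mean must be > 0")
    cn = int(np.floor(2.0 * segment_mean / diploid_mean + 0.5))
    return max(0, min(cap, cn))


def call_cnvs(
    segments: list[Segment],
    thresholds: tuple[float, float],
    diploid_mean: float,
    sample_id: str = "sample",
) -> list[CnvCall]:
    """Convert segments to merged gain/loss calls.

    Segments whose mean strictly exceeds t_gain become gains, strictly below
    t_loss losses; the rest are dropped. Adjacent same-state calls on one
    scaffold are merged (bin-weighted mean, copy number re-derived).
    """
    t_loss, t_gain = thresholds
    raw: list[CnvCall] = []
    for seg in segments:
        if seg.mean_level > t_gain:
            state = "gain"
        elif seg.mean_level < t_loss:
            state = "loss"
        else:
            continue
        cn = absolute_copy_number(seg.mean_level, diploid_mean)
        if state == "gain":
            cn = max(cn, 3)
        else:
            cn = min(cn, 1)
        raw.append(
            CnvCall(
                sample_id=sample_id,
                scaffold=seg.scaffold,
                start=seg.start_bp,
                end=seg.end_bp,
                state=state,
                copy_number=cn,
                mean_rd=seg.mean_level,
                n_bins=seg.n_bins,
                provenance=Provenance(rd_caller=True),
            )
        )

    merged: list[CnvCall] = []
    for call in sorted(raw, key=lambda c: (c.scaffold, c.start)):
        prev = merged[-1] if merged else None
        if (
            prev is not None
            and prev.scaffold == call.scaffold
            and prev.state == call.state
            and call.start <= prev.end
        ):
            w1, w2 = prev.n_bins, call.n_bins
            mean = (prev.mean_rd * w1 + call.mean_rd * w2) / (w1 + w2)
            cn = absolute_copy_number(mean, diploid_mean)
            cn = max(cn, 3) if call.state == "gain" else min(cn, 1)
            merged[-1] = CnvCall(
                sample_id=sample_id,
                scaffold=prev.scaffold,
                start=prev.start,
                end=call.end,
                state=prev.state,
                copy_number=cn,
                mean_rd=mean,
                n_bins=w1 + w2,
                provenance=Provenance(rd_caller=True),
            )
        else:
            merged.append(call)
    return merged


def depth_stats(
    bins: pd.DataFrame,
    sd_intervals: list[tuple[str, int, int]],
    sample_id: str = "sample",
    level_column: str = "corrected",
) -> DepthStats:
    """Per-bin background depth level and SD over unique (non-SD) regions.

    A bin is "unique" when less than half of it overlaps a segmental
    duplication. The centre is the median of unique-region bins (the diploid
    level) and the scale is the scaled MAD of successive bin differences,
    1.4826 * median|x[i+1] - x[i]| / sqrt(2), computed within scaffolds:
    copy-number segments are locally constant, so genuine CNVs inflate
    neither estimate, only their boundaries contribute outlying differences.
    """
    by_scaf: dict[str, list[tuple[int, int]]] = {}
    for scaf, s, e in sd_intervals:
        by_scaf.setdefault(scaf, []).append((s, e))

    keep = np.ones(len(bins), dtype=bool)
    starts = bins["start"].to_numpy()
    ends = bins["end"].to_numpy()
    scafs = bins["scaffold"].to_numpy()
    for i in range(len(bins)):
        ivs = by_scaf.get(scafs[i])
        if not ivs:
            continue
        ov = sum(
            max(0, min(ends[i], e) - max(starts[i], s)) for s, e in ivs
        )
        if ov * 2 >= ends[i] - starts[i]:
            keep[i] = False
    keep &= ~bins["masked"].to_numpy()
    x = bins.loc[keep, level_column].to_numpy(dtype=float)
    if x.size == 0:
        raise ValueError("no unique-region bins available for depth statistics")
    diffs = []
    for scaf in dict.fromkeys(scafs[keep]):
        v = bins.loc[keep & (scafs == scaf), level_column].to_numpy(dtype=float)
        if v.size > 1:
            diffs.append(np.diff(v))
    if diffs:
        d = np.concatenate(diffs)
        sd = 1.4826 * float(np.median(np.abs(d))) / np.sqrt(2)
    else:
        sd = float(x.std(ddof=1)) if x.size > 1 else 0.0
    return DepthStats(
        sample_id=sample_id, genome_mean_rd=float(np.median(x)), genome_sd_rd=sd
    )


def rd_filter(
    calls: list[CnvCall],
    stats: DepthStats,
    k: float = 3.0,
    chi_sq_alpha: float = 0.05,
) -> list[CnvCall]:
    """Set ``filtered_pass`` on each call per the high-confidence rule.

    Keep iff |mean_rd - genome_mean| > k * genome_sd AND the 1-df chi-square
    of observed total reads in the region against the genome-rate expectation
    gives p < chi_sq_alpha. Calls are returned with flags set (none removed);
    use ``[c for c in calls if c.provenance.filtered_pass]`` to subset.
    """
    out = []
    for call in calls:
        gate_sd = abs(call.mean_rd - stats.genome_mean_rd) > k * stats.genome_sd_rd
        n_bins = max(call.n_bins, 1)
        observed = call.mean_rd * n_bins
        expected = stats.genome_mean_rd * n_bins
        x2 = (observed - expected) ** 2 / expected
        p = float(chi2.sf(x2, df=1))
        call.chi_sq_p = p
        call.provenance.filtered_pass = bool(gate_sd and p < chi_sq_alpha)
        out.append(call)
    return out
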