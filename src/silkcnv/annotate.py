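"""Overlap of CNV calls with segmental duplications and gene models.

Segmental duplications are CNV-formation hotspots; the fraction of calls
touching an SD is a standard sanity statistic for a read-depth call set. A
call "overlaps" an SD (or contains a gene) when they share at least
``min_bp`` base pairs (default 1); intervals are 0-based half-open, so an
abutting gene (gene end == call start) does not count.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from intervaltree import IntervalTree

from .calling import CnvCall
from .comparative import merge_intervals

__all__ = ["OverlapReport", "sd_overlap", "genes_in_cnvs"]


@dataclass
class OverlapReport:
    n_cnvs: int
    n_overlapping_sd: int
    fraction: float | None  # None when the call set is empty
    per_cnv_overlap_bp: list[int]


def _build_trees(
    intervals: Sequence[tuple[str, int, int]],
) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for scaf, start, end in intervals:
        trees.setdefault(scaf, IntervalTree()).addi(start, end)
    return trees


def sd_overlap(
    calls: Sequence[CnvCall],
    sd_intervals: Sequence[tuple[str, int, int]],
    min_bp: int = 1,
) -> OverlapReport:
    """How many calls share >= ``min_bp`` bp with a segmental duplication.

    SD intervals are union-merged first so per-call overlap bp never exceeds
    the call length. An empty call set yields fraction None (NA).
    """
    if min_bp < 1:
        raise ValueError("min_bp must be >= 1")
    trees = _build_trees(merge_intervals(sd_intervals))
    per_call = []
    n_hit = 0
    for c in calls:
        tree = trees.get(c.scaffold)
        ov = 0
        if tree is not None:
            for iv in tree.overlap(c.start, c.end):
                ov += min(iv.end, c.end) - max(iv.begin, c.start)
        per_call.append(ov)
        if ov >= min_bp:
            n_hit += 1
    n = len(per_call)
    return OverlapReport(
        n_cnvs=n,
        n_overlapping_sd=n_hit,
        fraction=(n_hit / n) if n else None,
        per_cnv_overlap_bp=per_call,
    )


def genes_in_cnvs(
    calls: Sequence[CnvCall],
    genes: Sequence[tuple[str, int, int, str, str]],
    min_bp: int = 1,
) -> tuple[list[list[str]], set[str]]:
    """Gene ids overlapping each call, plus the deduplicated union.

    ``genes`` rows are (scaffold, start, end, gene_id, strand), 0-based
    half-open. Returns (per-call sorted gene-id lists, flat unique set).
    """
    trees: dict[str, IntervalTree] = {}
    for scaf, start, end, gid, _strand in genes:
        trees.setdefault(scaf, IntervalTree()).addi(start, end, gid)
    per_call: list[list[str]] = []
    flat: set[str] = set()
    for c in calls:
        tree = trees.get(c.scaffold)
        hits = []
        if tree is not None:
            for iv in tree.overlap(c.start, c.end):
                if min(iv.end, c.end) - max(iv.begin, c.start) >= min_bp:
                    hits.append(iv.data)
        hits = sorted(set(hits))
        per_call.append(hits)
        flat.update(hits)
    return per_call, flat
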