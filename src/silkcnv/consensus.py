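"""Ratio-based second caller and dual-caller consensus.

The second caller mirrors a tumour/control-style ratio pipeline: the genome
is cut into variable-width windows each holding a fixed number of control
read starts (``read_num``, default 150), the library-size-scaled sample /
control count ratio per window is converted to a copy-number scale, denoised
with a 1-D total-variation fit whose strength is set by ``smoothing_lambda``
(default 7), rescaled so the modal level is diploid, and snapped to integer
copy numbers. Calls from the primary read-depth caller that are corroborated
by a same-state ratio-caller call become the high-confidence consensus set.

The total-variation weight is noise-calibrated: effective weight =
lambda * sigma_hat / 2, sigma_hat being a robust estimate of the window-level
noise from successive differences. This keeps noise-free series untouched,
flattens everything as lambda -> infinity, and makes the level count monotone
non-increasing in lambda.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .calling import CnvCall, Provenance, absolute_copy_number

__all__ = [
    "ratio_windows",
    "tv_denoise",
    "smooth_and_snap",
    "ratio_calls",
    "intersect_calls",
    "ConsensusResult",
]


def ratio_windows(
    sample_reads: Mapping[str, np.ndarray],
    control_reads: Mapping[str, np.ndarray],
    scaffold_lengths: Mapping[str, int],
    read_num: int = 150,
) -> pd.DataFrame:
    """Variable-width windows each holding ``read_num`` control read starts.

    Returns columns ``scaffold, start, end, sample_count, control_count,
    ratio, flagged``; ``ratio`` is the sample/control count ratio scaled by
    total library sizes. A scaffold with fewer than ``read_num`` control
    reads becomes a single flagged whole-scaffold window. Window boundaries
    fall on control read-start positions; when several control reads share a
    boundary position a window may hold a few more than ``read_num``.
    """
    total_sample = sum(len(v) for v in sample_reads.values())
    total_control = sum(len(v) for v in control_reads.values())
    if total_sample == 0 or total_control == 0:
        raise ValueError("both read sets must be non-empty")
    scale = total_control / total_sample

    rows = []
    for scaf, length in scaffold_lengths.items():
        ctrl = np.sort(np.asarray(control_reads.get(scaf, ()), dtype=np.int64))
        smp = np.sort(np.asarray(sample_reads.get(scaf, ()), dtype=np.int64))
        if ctrl.size < read_num:
            flagged = True
            bounds = np.array([0, length], dtype=np.int64)
        else:
            flagged = False
            cut_pos = ctrl[read_num::read_num]
            bounds = np.unique(np.concatenate(([0], cut_pos, [length])))
        c_counts = np.diff(np.searchsorted(ctrl, bounds, side="left"))
        s_counts = np.diff(np.searchsorted(smp, bounds, side="left"))
        for b0, b1, cc, sc in zip(bounds, bounds[1:], c_counts, s_counts):
            ratio = (sc / cc) * scale if cc > 0 else np.nan
            rows.append((scaf, int(b0), int(b1), int(sc), int(cc), ratio, flagged))
    return pd.DataFrame(
        rows,
        columns=[
            "scaffold", "start", "end",
            "sample_count", "control_count", "ratio", "flagged",
        ],
    )


def tv_denoise(y: np.ndarray, weight: float) -> np.ndarray:
    """Exact 1-D total-variation denoising (taut-string / direct algorithm).

    Minimises 0.5 * sum (x - y)^2 + weight * sum |x[k+1] - x[k]|.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    if n == 0:
        return y.copy()
    if weight <= 0 or n == 1:
        return y.copy()
    if not np.isfinite(weight):
        return np.full(n, y.mean())
    x = np.empty(n)
    lam = float(weight)
    k = k0 = km = kp = 0
    vmin = y[0] - lam
    vmax = y[0] + lam
    umin = lam
    umax = -lam
    while True:
        while k == n - 1:
            # end of the series: resolve the pending segment(s)
            if umin < 0.0:
                x[k0 : km + 1] = vmin
                k0 = km + 1
                km = k = k0
                vmin = y[k]
                umin = lam
                umax = vmin + lam - vmax
            elif umax > 0.0:
                x[k0 : kp + 1] = vmax
                k0 = kp + 1
                kp = k = k0
                vmax = y[k]
                umax = -lam
                umin = vmax - lam - vmin
            else:
                x[k0:n] = vmin + umin / (k - k0 + 1)
                return x
        if y[k + 1] + umin < vmin - lam:
            # the taut string hits the lower tube boundary: negative jump
            x[k0 : km + 1] = vmin
            k0 = km + 1
            kp = km = k = k0
            vmin = y[k]
            vmax = vmin + 2 * lam
            umin = lam
            umax = -lam
        elif y[k + 1] + umax > vmax + lam:
            # upper tube boundary: positive jump
            x[k0 : kp + 1] = vmax
            k0 = kp + 1
            kp = km = k = k0
            vmax = y[k]
            vmin = vmax - 2 * lam
            umin = lam
            umax = -lam
        else:
            k += 1
            umin += y[k] - vmin
            umax += y[k] - vmax
            if umin >= lam:
                vmin += (umin - lam) / (k - k0 + 1)
                umin = lam
                km = k
            if umax <= -lam:
                vmax += (umax + lam) / (k - k0 + 1)
                umax = -lam
                kp = k


def smooth_and_snap(
    windows: pd.DataFrame,
    lambda_s: float = 7.0,
    ploidy_offset: int = 0,
) -> pd.DataFrame:
    """Total-variation denoise window ratios and snap to integer copy number.

    Adds ``fitted`` (denoised level on the copy-number scale) and
    ``smoothed_cn`` (integer) columns. Fitted levels are rescaled so the modal
    level maps to CN ``2 + ploidy_offset``. Requires >= 10 windows overall.
    """
    if len(windows) < 10:
        raise ValueError("need >= 10 windows for smoothing")
    if lambda_s < 0:
        raise ValueError("lambda_s must be >= 0")
    out = windows.copy()
    cn_raw = 2.0 * out["ratio"].to_numpy(dtype=float)
    cn_raw = np.where(np.isfinite(cn_raw), cn_raw, 2.0)

    diffs = []
    for scaf in dict.fromkeys(out["scaffold"]):
        v = cn_raw[(out["scaffold"] == scaf).to_numpy()]
        if v.size > 1:
            diffs.append(np.diff(v))
    sigma = 0.0
    if diffs:
        d = np.concatenate(diffs)
        sigma = 1.4826 * float(np.median(np.abs(d))) / np.sqrt(2)
    weight = lambda_s * max(sigma, 1e-8) / 2.0

    fitted = np.empty_like(cn_raw)
    for scaf in dict.fromkeys(out["scaffold"]):
        m = (out["scaffold"] == scaf).to_numpy()
        fitted[m] = tv_denoise(cn_raw[m], weight)

    # modal fitted level: peak of a quarter-copy histogram (the diploid bulk),
    # refined to the mean fitted value inside the peak bin
    lo, hi = float(fitted.min()), float(fitted.max())
    if hi - lo < 1e-9:
        modal = lo
    else:
        edges = np.arange(lo - 0.125, hi + 0.375, 0.25)
        counts, _ = np.histogram(fitted, bins=edges)
        b = int(np.argmax(counts))
        sel = (fitted >= edges[b]) & (fitted < edges[b + 1])
        modal = float(fitted[sel].mean())
    if modal <= 0:
        pos = fitted[fitted > 0]
        modal = float(np.median(pos)) if pos.size else 1.0
    target = 2 + ploidy_offset
    snapped = np.floor(fitted * target / modal + 0.5).astype(int)
    out["fitted"] = fitted
    out["smoothed_cn"] = np.maximum(snapped, 0)
    return out


def ratio_calls(
    smoothed: pd.DataFrame, sample_id: str = "sample"
) -> list[CnvCall]:
    """Merge consecutive non-diploid windows into ratio-caller CNV calls."""
    calls: list[CnvCall] = []
    for scaf in dict.fromkeys(smoothed["scaffold"]):
        sub = smoothed[smoothed["scaffold"] == scaf]
        cur: list[tuple[int, int, int, float]] = []  # start, end, cn, fitted
        prev_cn = 2

        def flush() -> None:
            if not cur:
                return
            start, end = cur[0][0], cur[-1][1]
            cn = cur[0][2]
            mean_fit = float(np.mean([c[3] for c in cur]))
            calls.append(
                CnvCall(
                    sample_id=sample_id,
                    scaffold=scaf,
                    start=start,
                    end=end,
                    state="gain" if cn > 2 else "loss",
                    copy_number=cn,
                    mean_rd=mean_fit,
                    n_bins=len(cur),
                    provenance=Provenance(ratio_caller=True),
                )
            )

        for row in sub.itertuples(index=False):
            cn = int(row.smoothed_cn)
            if cn != 2 and cn == prev_cn and cur:
                cur.append((row.start, row.end, cn, row.fitted))
            elif cn != 2:
                flush()
                cur = [(row.start, row.end, cn, row.fitted)]
            else:
                flush()
                cur = []
            prev_cn = cn
        flush()
    return calls


@dataclass
class ConsensusResult:
    """High-confidence calls plus a symmetric report of what was dropped."""

    consensus: list[CnvCall]
    dropped_rd: list[CnvCall]
    unmatched_ratio: list[CnvCall]


def _overlap(a: CnvCall, b: CnvCall) -> int:
    if a.scaffold != b.scaffold:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def intersect_calls(
    calls_rd: list[CnvCall],
    calls_ratio: list[CnvCall],
    min_overlap: int = 1,
    reciprocal: float | None = None,
) -> ConsensusResult:
    """Retain read-depth calls corroborated by a same-state ratio call.

    A read-depth call survives when some ratio-caller call of the same state
    overlaps it by at least ``min_overlap`` bp (or, if ``reciprocal`` is
    given, by at least that fraction of both call lengths). Retained calls
    keep the read-depth intervals and gain ``ratio_caller`` provenance.
    """
    consensus, dropped = [], []
    matched_ratio: set[int] = set()
    for a in calls_rd:
        hit = False
        for idx, b in enumerate(calls_ratio):
            if b.state != a.state:
                continue
            ov = _overlap(a, b)
            if ov < max(min_overlap, 1):
                continue
            if reciprocal is not None and (
                ov < reciprocal * a.length or ov < reciprocal * b.length
            ):
                continue
            hit = True
            matched_ratio.add(idx)
        if hit:
            consensus.append(
                replace(
                    a,
                    provenance=Provenance(
                        rd_caller=True,
                        ratio_caller=True,
                        filtered_pass=a.provenance.filtered_pass,
                    ),
                )
            )
        else:
            dropped.append(a)
    unmatched = [b for i, b in enumerate(calls_ratio) if i not in matched_ratio]
    return ConsensusResult(
        consensus=consensus, dropped_rd=dropped, unmatched_ratio=unmatched
    )
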