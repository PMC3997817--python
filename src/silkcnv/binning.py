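"""Bin-size selection, read binning and LOESS GC correction.

The preprocessing stage of read-depth CNV calling: choose a bin width from
the per-bin false-discovery setting so that single-copy gains and losses are
detectable with high power, count read starts per bin, attach per-bin GC
content from the reference, and divide out the GC trend with a LOESS fit
(corrected = raw * median(raw) / fit(GC)).
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.stats import norm
from statsmodels.nonparametric.smoothers_lowess import lowess

from .simdata import SyntheticGenome

__all__ = ["select_bin_size", "bin_counts", "gc_correct", "write_bins", "read_bins"]


def select_bin_size(
    coverage: float,
    read_length: int,
    alpha: float = 0.01,
    p_min: float = 0.95,
    step: int = 100,
    max_width: int = 1_000_000,
) -> int:
    """Smallest bin width (multiple of ``step`` bp) with adequate power.

    With per-bin mean count lambda = w * coverage / read_length and two-sided
    per-bin significance ``alpha`` (alpha/2 per tail) under Normal(lambda,
    lambda), the width must let a 3-copy bin ~ Normal(1.5*lambda, 1.5*lambda)
    exceed the gain threshold and a 1-copy bin ~ Normal(0.5*lambda,
    0.5*lambda) undershoot the loss threshold, each with probability >=
    ``p_min``. Raises if no width up to ``max_width`` suffices.
    """
    if coverage <= 0 or read_length <= 0:
        raise ValueError("coverage and read_length must be > 0")
    z_a = norm.ppf(1 - alpha / 2)
    for w in range(step, max_width + 1, step):
        lam = w * coverage / read_length
        t_gain = lam + z_a * np.sqrt(lam)
        t_loss = lam - z_a * np.sqrt(lam)
        p_gain = norm.sf(t_gain, loc=1.5 * lam, scale=np.sqrt(1.5 * lam))
        p_loss = norm.cdf(t_loss, loc=0.5 * lam, scale=np.sqrt(0.5 * lam))
        if p_gain >= p_min and p_loss >= p_min:
            return w
    raise ValueError(
        f"no bin width <= {max_width} bp achieves power {p_min} at "
        f"coverage {coverage}; coverage too low"
    )


def _bin_gc(seq: str, width: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-bin GC fraction (N bases excluded) and N fraction."""
    b = np.frombuffer(seq.upper().encode(), dtype="S1")
    is_gc = (b == b"G") | (b == b"C")
    is_n = ~((b == b"A") | (b == b"T") | is_gc)
    n_bins = (len(seq) + width - 1) // width
    idx = np.arange(len(seq)) // width
    gc_sum = np.bincount(idx, weights=is_gc, minlength=n_bins)
    n_sum = np.bincount(idx, weights=is_n, minlength=n_bins)
    sizes = np.bincount(idx, minlength=n_bins)
    denom = sizes - n_sum
    with np.errstate(invalid="ignore"):
        gc = np.where(denom > 0, gc_sum / np.maximum(denom, 1), np.nan)
    return gc, n_sum / sizes


def bin_counts(
    read_starts: Mapping[str, np.ndarray],
    genome: SyntheticGenome | Mapping[str, str] | str | Path,
    width: int,
    max_n_fraction: float = 0.5,
) -> pd.DataFrame:
    """Count read starts in uniform bins and attach GC content.

    ``genome`` may be a :class:`SyntheticGenome`, a name->sequence mapping, or
    a FASTA path (read via pyfaidx). Returns a DataFrame with columns
    ``scaffold, start, end, raw_count, gc, partial, masked``; bins with more
    than ``max_n_fraction`` ambiguous bases are masked. Counts conserve the
    total number of read starts exactly.
    """
    if width < 100:
        raise ValueError("bin width must be >= 100 bp")
    if isinstance(genome, SyntheticGenome):
        seqs: Mapping[str, str] = genome.scaffolds
    elif isinstance(genome, (str, Path)):
        from pyfaidx import Fasta

        fa = Fasta(str(genome))
        seqs = {name: str(fa[name][:]) for name in fa.keys()}
    else:
        seqs = genome

    rows = []
    for scaf, seq in seqs.items():
        length = len(seq)
        n_bins = max(1, (length + width - 1) // width)
        starts = np.asarray(read_starts.get(scaf, np.empty(0, dtype=np.int64)))
        counts = np.bincount(
            np.minimum(starts // width, n_bins - 1), minlength=n_bins
        )
        gc, n_frac = _bin_gc(seq, width)
        for i in range(n_bins):
            b0, b1 = i * width, min((i + 1) * width, length)
            rows.append(
                (
                    scaf,
                    b0,
                    b1,
                    int(counts[i]),
                    gc[i],
                    b1 - b0 < width,
                    n_frac[i] > max_n_fraction or not np.isfinite(gc[i]),
                )
            )
    return pd.DataFrame(
        rows,
        columns=["scaffold", "start", "end", "raw_count", "gc", "partial", "masked"],
    )


def gc_correct(bins: pd.DataFrame, loess_span: float = 0.3) -> pd.DataFrame:
    """Divide out the GC trend of the raw counts with a LOESS fit.

    corrected = raw * median(raw) / fit(gc), fitted on full, unmasked bins.
    Bins where the fit is non-positive are masked. If all bins share one GC
    value the correction is the identity. Requires >= 50 usable bins.
    """
    bins = bins.copy()
    usable = ~bins["masked"] & ~bins["partial"]
    if usable.sum() < 50:
        raise ValueError("need >= 50 usable bins for GC correction")
    gc = bins.loc[usable, "gc"].to_numpy(dtype=float)
    raw = bins.loc[usable, "raw_count"].to_numpy(dtype=float)
    med = float(np.median(raw))
    corrected = bins["raw_count"].to_numpy(dtype=float).copy()
    if np.ptp(gc) < 1e-9:
        bins["corrected"] = corrected
        return bins
    fit_at = bins["gc"].to_numpy(dtype=float)
    fitted = lowess(
        raw, gc, frac=loess_span, it=2, xvals=np.where(np.isfinite(fit_at), fit_at, gc.mean())
    )
    bad = ~np.isfinite(fitted) | (fitted <= 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        corrected = np.where(bad, np.nan, corrected * med / fitted)
    bins["corrected"] = corrected
    bins.loc[bad, "masked"] = True
    return bins


def write_bins(bins: pd.DataFrame, path: str | Path) -> None:
    bins.to_csv(path, sep="\t", index=False)


def read_bins(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
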