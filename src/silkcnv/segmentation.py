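"""Circular binary segmentation (CBS) of per-bin depth signals.

Each scaffold's bin series is treated as a circle; the candidate changepoint
pair (i, j) maximises a two-sample t-like statistic comparing the arc [i, j)
with its complement, a split is accepted when a within-scaffold permutation
test gives p <= perm_alpha, and the procedure recurses into the resulting
sub-regions. A final merging pass joins adjacent segments whose means differ
by less than one MAD of the bin-level noise (raw CBS over-segments long
scaffolds).

The statistic: for an arc of k bins with mean m_in against the remaining
n - k bins with mean m_out,

    t(i, j) = (m_in - m_out) / (s_p * sqrt(1/k + 1/(n-k)))

with s_p the pooled within-group standard deviation. Ties in the argmax of
|t| are broken by smallest i, then smallest j; the arc and its complement
give the same boundaries, so the reported pair is well defined.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["Segment", "best_split", "cbs_segment", "segment_bins"]

_EPS = 1e-12


@dataclass
class Segment:
    """A constant-level stretch of bins (half-open bin indices)."""

    scaffold: str
    start_bin: int
    end_bin: int
    start_bp: int
    end_bp: int
    mean_level: float
    n_bins: int


def _pair_indices(n: int, min_width: int) -> tuple[np.ndarray, np.ndarray]:
    """All (i, j) with min_width <= j - i <= n - min_width, lexicographic."""
    i, j = np.triu_indices(n + 1, k=min_width)
    keep = (j - i) <= n - min_width
    return i[keep], j[keep]


def _all_stats(x: np.ndarray, ii: np.ndarray, jj: np.ndarray) -> np.ndarray:
    """|t(i, j)| for every candidate arc, vectorised via cumulative sums."""
    n = x.size
    S = np.concatenate(([0.0], np.cumsum(x)))
    Q = np.concatenate(([0.0], np.cumsum(x * x)))
    k = (jj - ii).astype(float)
    m = n - k
    sum_in = S[jj] - S[ii]
    sq_in = Q[jj] - Q[ii]
    mean_in = sum_in / k
    mean_out = (S[n] - sum_in) / m
    ss_in = sq_in - k * mean_in**2
    ss_out = (Q[n] - sq_in) - m * mean_out**2
    sp2 = np.maximum(ss_in + ss_out, 0.0) / max(n - 2, 1)
    denom = np.sqrt(np.maximum(sp2, _EPS) * (1.0 / k + 1.0 / m))
    return np.abs(mean_in - mean_out) / denom


def best_split(
    x: np.ndarray, min_width: int = 2
) -> tuple[int, int, float] | None:
    """Maximising changepoint pair for one region.

    Returns (i, j, |t|) with ties broken lexicographically, or None when the
    region is too short to split (< 2 * min_width bins).
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 2 * min_width:
        return None
    ii, jj = _pair_indices(n, min_width)
    stats = _all_stats(x, ii, jj)
    b = int(np.argmax(stats))  # first maximum in (i, j) lexicographic order
    return int(ii[b]), int(jj[b]), float(stats[b])


def _perm_test(
    x: np.ndarray,
    observed: float,
    ii: np.ndarray,
    jj: np.ndarray,
    perm_alpha: float,
    n_perm: int,
    rng: np.random.Generator,
    batch: int = 100,
) -> bool:
    """Sequential permutation test of the max statistic.

    Permutes bin labels within the region; stops early when the p-value bound
    is decisive: reject a split once exceedances guarantee p > perm_alpha,
    accept once the running estimate (1+e)/(1+m) is <= perm_alpha with zero
    exceedances over >= 2 batches.
    """
    reject_at = int(np.ceil(perm_alpha * (n_perm + 1)))
    exceed = 0
    done = 0
    while done < n_perm:
        m = min(batch, n_perm - done)
        for _ in range(m):
            perm = rng.permutation(x)
            if _all_stats(perm, ii, jj).max() >= observed:
                exceed += 1
        done += m
        if exceed >= reject_at:
            return False
        if exceed == 0 and done >= 2 * batch and (1.0 / (1 + done)) <= perm_alpha:
            return True
    return (1 + exceed) / (1 + n_perm) <= perm_alpha


def cbs_segment(
    levels: np.ndarray,
    perm_alpha: float = 0.01,
    n_perm: int = 1000,
    min_width: int = 2,
    seed: int | None = None,
    merge: bool = True,
) -> list[tuple[int, int, float]]:
    """Segment one scaffold's bin levels; returns (start, end, mean) triples.

    Recursive CBS with a permutation test per candidate split, followed by a
    MAD-based merge of adjacent segments (disable with ``merge=False``).
    Deterministic for a fixed seed.
    """
    x = np.asarray(levels, dtype=float)
    if x.size == 0:
        return []
    if not np.all(np.isfinite(x)):
        raise ValueError("levels must be finite")
    rng = np.random.default_rng(seed)
    boundaries: set[int] = {0, x.size}

    def recurse(lo: int, hi: int) -> None:
        seg = x[lo:hi]
        n = seg.size
        if n < 2 * min_width:
            return
        split = best_split(seg, min_width)
        if split is None:
            return
        i, j, stat = split
        if stat <= 0:
            return
        ii, jj = _pair_indices(n, min_width)
        if not _perm_test(seg, stat, ii, jj, perm_alpha, n_perm, rng):
            return
        cuts = sorted({lo + i, lo + j} - {lo, hi})
        if not cuts:
            return
        boundaries.update(cuts)
        prev = lo
        for c in cuts + [hi]:
            if c > prev:
                recurse(prev, c)
            prev = c

    recurse(0, x.size)
    bounds = sorted(boundaries)
    segs = [
        (a, b, float(x[a:b].mean())) for a, b in zip(bounds, bounds[1:])
    ]

    if merge and len(segs) > 1:
        resid = np.concatenate([x[a:b] - m for a, b, m in segs])
        mad = 1.4826 * float(np.median(np.abs(resid - np.median(resid))))
        tol = max(mad, _EPS)
        merged = True
        while merged and len(segs) > 1:
            merged = False
            gaps = [abs(segs[t + 1][2] - segs[t][2]) for t in range(len(segs) - 1)]
            t = int(np.argmin(gaps))
            if gaps[t] < tol:
                a, b = segs[t][0], segs[t + 1][1]
                segs[t : t + 2] = [(a, b, float(x[a:b].mean()))]
                merged = True
    return segs


def segment_bins(
    bins: pd.DataFrame,
    perm_alpha: float = 0.01,
    n_perm: int = 1000,
    min_width: int = 2,
    seed: int | None = None,
    level_column: str = "corrected",
) -> list[Segment]:
    """Run CBS per scaffold on a binned-depth table.

    Masked bins are excluded from the series; segment bp coordinates span
    from the first to the last member bin. Scaffolds are processed in input
    order with per-scaffold RNG streams derived from ``seed``.
    """
    out: list[Segment] = []
    ss = np.random.SeedSequence(seed)
    scaffolds = list(dict.fromkeys(bins["scaffold"]))
    children = ss.spawn(len(scaffolds))
    for scaf, child in zip(scaffolds, children):
        sub = bins[(bins["scaffold"] == scaf) & (~bins["masked"])]
        if sub.empty:
            continue
        x = sub[level_column].to_numpy(dtype=float)
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        rng_seed = int(child.generate_state(1)[0] % (2**31))
        for a, b, mean in cbs_segment(
            x, perm_alpha=perm_alpha, n_perm=n_perm,
            min_width=min_width, seed=rng_seed,
        ):
            out.append(
                Segment(
                    scaffold=scaf,
                    start_bin=a,
                    end_bin=b,
                    start_bp=int(starts[a]),
                    end_bp=int(ends[b - 1]),
                    mean_level=mean,
                    n_bins=b - a,
                )
            )
    return out
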