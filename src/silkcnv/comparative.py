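"""Cross-sample copy-number matrix, sharing classes and sample clustering.

Calls from all samples are merged into a union of copy-number-variable
regions; each (sample, region) cell holds the sample's absolute copy number
there (2 where the sample has no call). Regions are then classified by their
sharing pattern — individual-specific, group-specific (e.g. domesticated- or
wild-specific), possessed by all samples, or other sharing — and samples are
clustered on the integer matrix with average-linkage agglomeration, emitted
as a newick dendrogram.

"Shared" requires the same direction of change (copy number != 2 in every
carrier) but not an identical copy number.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .calling import CnvCall

__all__ = [
    "CopyNumberMatrix",
    "build_matrix",
    "classify_sharing",
    "cluster_samples",
]

SHARING_CLASSES = (
    "individual-specific",
    "group-specific",
    "all-possessed",
    "shared-other",
    "none",
)


@dataclass
class CopyNumberMatrix:
    """samples x regions matrix of absolute integer copy numbers."""

    regions: list[tuple[str, int, int]]
    matrix: pd.DataFrame  # index: sample ids; columns: region index

    @property
    def samples(self) -> list[str]:
        return list(self.matrix.index)

    def to_tsv(self, path) -> None:
        out = self.matrix.copy()
        out.columns = [f"{s}:{a}-{b}" for s, a, b in self.regions]
        out.to_csv(path, sep="\t")


def merge_intervals(
    intervals: Sequence[tuple[str, int, int]],
) -> list[tuple[str, int, int]]:
    """Union-merge intervals overlapping by >= 1 bp (abutting kept apart)."""
    out: list[tuple[str, int, int]] = []
    for scaf, start, end in sorted(intervals):
        if out and out[-1][0] == scaf and start < out[-1][2]:
            out[-1] = (scaf, out[-1][1], max(out[-1][2], end))
        else:
            out.append((scaf, start, end))
    return out


def build_matrix(
    calls: Sequence[CnvCall], samples: Sequence[str] | None = None
) -> CopyNumberMatrix:
    """Union-merge call intervals across samples and fill the CN matrix.

    A cell takes the copy number of the sample's call overlapping the region
    (length-weighted mode when several calls overlap it), else 2.
    """
    if samples is None:
        samples = list(dict.fromkeys(c.sample_id for c in calls))
    regions = merge_intervals([(c.scaffold, c.start, c.end) for c in calls])
    mat = np.full((len(samples), len(regions)), 2, dtype=int)
    region_index: dict[str, list[tuple[int, int, int]]] = {}
    for ridx, (scaf, start, end) in enumerate(regions):
        region_index.setdefault(scaf, []).append((start, end, ridx))

    weights: dict[tuple[int, int], dict[int, int]] = {}
    sample_pos = {s: i for i, s in enumerate(samples)}
    for c in calls:
        si = sample_pos[c.sample_id]
        for start, end, ridx in region_index.get(c.scaffold, ()):
            ov = min(end, c.end) - max(start, c.start)
            if ov >= 1:
                cell = weights.setdefault((si, ridx), {})
                cell[c.copy_number] = cell.get(c.copy_number, 0) + ov
    for (si, ridx), cns in weights.items():
        # length-weighted mode, ties toward the smaller copy number
        best = sorted(cns.items(), key=lambda kv: (-kv[1], kv[0]))[0][0]
        mat[si, ridx] = best
    return CopyNumberMatrix(
        regions=regions,
        matrix=pd.DataFrame(mat, index=list(samples), columns=range(len(regions))),
    )


def classify_sharing(
    cnm: CopyNumberMatrix, group_labels: Mapping[str, str]
) -> pd.DataFrame:
    """Classify each region's sharing pattern across samples.

    individual-specific: exactly one sample differs from diploid;
    <group>-specific: every member of one group differs and no one else does;
    all-possessed: every sample differs; otherwise shared-other (or none when
    no sample differs, which cannot arise from real calls).
    """
    missing = [s for s in cnm.samples if s not in group_labels]
    if missing:
        raise ValueError(f"missing group labels for samples: {missing}")
    groups: dict[str, list[str]] = {}
    for s in cnm.samples:
        groups.setdefault(group_labels[s], []).append(s)

    rows = []
    for ridx, (scaf, start, end) in enumerate(cnm.regions):
        col = cnm.matrix[ridx]
        carriers = {s for s in cnm.samples if col[s] != 2}
        if not carriers:
            cls = "none"
        elif len(carriers) == 1:
            cls = "individual-specific"
        elif carriers == set(cnm.samples):
            cls = "all-possessed"
        else:
            cls = "shared-other"
            for label, members in groups.items():
                if carriers == set(members):
                    cls = f"{label}-specific"
                    break
        rows.append((scaf, start, end, cls, ",".join(sorted(carriers))))
    return pd.DataFrame(
        rows, columns=["scaffold", "start", "end", "sharing_class", "carriers"]
    )


def _newick(node, names, heights) -> str:
    if isinstance(node, int):
        return names[node]
    (left, right), h = node, heights[id(node)]
    hl = heights.get(id(left), 0.0) if not isinstance(left, int) else 0.0
    hr = heights.get(id(right), 0.0) if not isinstance(right, int) else 0.0
    return (
        f"({_newick(left, names, heights)}:{h - hl:.10g},"
        f"{_newick(right, names, heights)}:{h - hr:.10g})"
    )


def cluster_samples(
    cnm: CopyNumberMatrix,
    distance: str = "euclidean",
    linkage: str = "average",
) -> str:
    """Agglomerative clustering of samples; returns a newick string.

    Average (UPGMA) or complete/single linkage on pairwise distances of the
    integer copy-number rows. Deterministic: on equal merge distances the
    lexicographically smallest cluster pair (by smallest member sample name)
    merges first. Branch lengths are differences of merge heights.
    """
    from scipy.spatial.distance import pdist, squareform

    if len(cnm.samples) < 2:
        raise ValueError("need >= 2 samples to cluster")
    names = cnm.samples
    dm = squareform(pdist(cnm.matrix.to_numpy(dtype=float), metric=distance))

    # active clusters: key -> (node, member leaf indices)
    clusters: dict[int, tuple[object, list[int]]] = {
        i: (i, [i]) for i in range(len(names))
    }
    dist: dict[tuple[int, int], float] = {
        (i, j): dm[i, j] for i in clusters for j in clusters if i < j
    }
    heights: dict[int, float] = {}
    next_key = len(names)
    key_rank = {i: (names[i],) for i in range(len(names))}

    while len(clusters) > 1:
        best = min(
            dist.items(),
            key=lambda kv: (kv[1], key_rank[kv[0][0]], key_rank[kv[0][1]]),
        )
        (a, b), h = best
        node = (clusters[a][0], clusters[b][0])
        members = clusters[a][1] + clusters[b][1]
        heights[id(node)] = h
        na, nb = len(clusters[a][1]), len(clusters[b][1])
        del clusters[a], clusters[b]
        newd = {}
        for c in clusters:
            da = dist[tuple(sorted((a, c)))]
            db = dist[tuple(sorted((b, c)))]
            if linkage == "average":
                d = (na * da + nb * db) / (na + nb)
            elif linkage == "complete":
                d = max(da, db)
            elif linkage == "single":
                d = min(da, db)
            else:
                raise ValueError(f"unknown linkage {linkage!r}")
            newd[(c, next_key)] = d
        dist = {
            k: v for k, v in dist.items() if a not in k and b not in k
        }
        dist.update(newd)
        clusters[next_key] = (node, members)
        key_rank[next_key] = (min(names[m] for m in members),)
        next_key += 1

    root = next(iter(clusters.values()))[0]
    return _newick(root, names, heights) + ";"
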