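"""Synthetic genomes, copy-number truth sets and GC-biased read sets.

This module emulates the design of the four-silkworm resequencing study at
desk scale: a multi-scaffold diploid reference with smoothly varying GC and a
sprinkling of segmental duplications, four individuals split into a
"domesticated" and a "wild" group, per-individual implanted gains and losses
(integer copy number 0–20) with controlled sharing structure, and single-end
reads sampled per base pair from a Poisson process whose rate is proportional
to local copy number and modulated by a smooth GC bias.

Everything is deterministic for a fixed seed; no global RNG state is used.
Coordinates are 0-based half-open throughout, matching BED.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "SyntheticGenome",
    "SyntheticTruth",
    "ReadSet",
    "CnvSpec",
    "RandomCnvParams",
    "DEFAULT_SAMPLES",
    "simulate_genome",
    "implant_cnvs",
    "simulate_reads",
    "sin_bump_bias",
    "write_truth_bed",
    "read_truth_bed",
]

#: The study design: two domesticated and two wild individuals.
DEFAULT_SAMPLES: tuple[tuple[str, str], ...] = (
    ("dom1", "domesticated"),
    ("dom2", "domesticated"),
    ("wild1", "wild"),
    ("wild2", "wild"),
)

_BASES = np.frombuffer(b"GCAT", dtype="S1")


@dataclass
class SyntheticGenome:
    """A synthetic multi-scaffold reference.

    ``scaffolds`` maps name -> sequence (upper-case ACGT). ``gc_profile``
    holds the per-window *target* GC fraction used during simulation;
    downstream GC corrections always recompute GC from the sequence itself.
    ``sd_intervals`` are segmental-duplication annotations, 0-based half-open.
    """

    scaffolds: dict[str, str]
    gc_window: int = 1000
    gc_profile: dict[str, np.ndarray] = field(default_factory=dict)
    sd_intervals: list[tuple[str, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for name, seq in self.scaffolds.items():
            if len(seq) <= 0:
                raise ValueError(f"scaffold {name!r} has non-positive length")
        lengths = self.lengths()
        for scaf, start, end in self.sd_intervals:
            if scaf not in lengths:
                raise ValueError(f"SD interval on unknown scaffold {scaf!r}")
            if not (0 <= start < end <= lengths[scaf]):
                raise ValueError(
                    f"SD interval {scaf}:{start}-{end} outside scaffold bounds"
                )

    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.scaffolds.items()}

    @property
    def total_length(self) -> int:
        return sum(self.lengths().values())

    def write_fasta(self, path: str | Path, width: int = 60) -> None:
        with open(path, "w") as fh:
            for name, seq in self.scaffolds.items():
                fh.write(f">{name}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")

    def write_sd_bed(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for scaf, start, end in self.sd_intervals:
                fh.write(f"{scaf}\t{start}\t{end}\n")


@dataclass
class SyntheticTruth:
    """Implanted copy-number intervals for one individual.

    Background ploidy is 2 everywhere not covered by ``cnv_intervals``; each
    interval carries an absolute integer copy number != 2. Intervals are
    non-overlapping within a sample.
    """

    sample_id: str
    group_label: str
    cnv_intervals: list[tuple[str, int, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for scaf, start, end, cn in self.cnv_intervals:
            if end <= start:
                raise ValueError(f"empty truth interval {scaf}:{start}-{end}")
            if not (0 <= cn <= 20) or int(cn) != cn:
                raise ValueError(f"copy number must be an integer in [0, 20], got {cn}")
            if cn == 2:
                raise ValueError("truth intervals must have copy number != 2")
        by_scaf: dict[str, list[tuple[int, int]]] = {}
        for scaf, start, end, _ in self.cnv_intervals:
            by_scaf.setdefault(scaf, []).append((start, end))
        for scaf, ivs in by_scaf.items():
            ivs.sort()
            for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
                if s2 < e1:
                    raise ValueError(
                        f"overlapping truth intervals on {scaf} in {self.sample_id}"
                    )

    def copy_number_track(self, scaffold: str, length: int) -> np.ndarray:
        """Per-bp absolute copy number along one scaffold."""
        cn = np.full(length, 2, dtype=np.int16)
        for scaf, start, end, c in self.cnv_intervals:
            if scaf == scaffold:
                cn[start:end] = c
        return cn


@dataclass
class ReadSet:
    """Single-end read start positions per scaffold (sorted, 0-based)."""

    sample_id: str
    read_starts: dict[str, np.ndarray]
    read_length: int

    @property
    def total_reads(self) -> int:
        return int(sum(len(v) for v in self.read_starts.values()))

    def coverage(self, genome_length: int) -> float:
        return self.total_reads * self.read_length / genome_length

    def write_sam(self, genome: SyntheticGenome, path: str | Path) -> None:
        """Write a sorted, unpaired SAM file (MAPQ 60, full-match CIGAR)."""
        import pysam

        lengths = genome.lengths()
        header = {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [{"SN": n, "LN": ln} for n, ln in lengths.items()],
        }
        rl = self.read_length
        with pysam.AlignmentFile(str(path), "w", header=header) as out:
            for tid, (name, _) in enumerate(lengths.items()):
                seq = genome.scaffolds[name]
                for k, pos in enumerate(self.read_starts.get(name, ())):
                    a = pysam.AlignedSegment(out.header)
                    a.query_name = f"{self.sample_id}_{name}_{k}"
                    a.query_sequence = seq[pos : pos + rl]
                    a.flag = 0
                    a.reference_id = tid
                    a.reference_start = int(pos)
                    a.mapping_quality = 60
                    a.cigarstring = f"{rl}M"
                    a.query_qualities = pysam.qualitystring_to_array("I" * rl)
                    out.write(a)


def _bresenham_gc_window(n: int, gc: float, phase: int) -> np.ndarray:
    """Deterministic window with an evenly spread, exact-count GC pattern.

    Used for constant-GC genomes so that *any* aligned sub-window has GC equal
    to the target to within one base; makes flat-GC identities exact
    downstream.
    """
    idx = np.arange(phase, phase + n)
    is_gc = np.floor((idx + 1) * gc) > np.floor(idx * gc)
    # alternate G/C and A/T so the sequence is not a two-letter string
    alt = idx % 2 == 0
    out = np.where(is_gc, np.where(alt, b"G", b"C"), np.where(alt, b"A", b"T"))
    return out.astype("S1")


def simulate_genome(
    n_scaffolds: int,
    length_range: tuple[int, int],
    gc_params: float | tuple[float, float] = (0.3, 0.6),
    sd_density: float = 0.014,
    seed: int | None = None,
    gc_window: int = 1000,
) -> SyntheticGenome:
    """Generate a synthetic reference with smooth GC and SD annotations.

    Parameters
    ----------
    n_scaffolds : number of scaffolds (>= 1).
    length_range : (lo, hi) scaffold length bounds in bp, inclusive.
    gc_params : a single float for a flat GC genome, or (low, high) bounds of
        a smooth sinusoidal GC landscape sampled per ``gc_window``.
    sd_density : target fraction of the genome covered by segmental
        duplications (the silkworm reference carries ~1.4%).
    """
    if n_scaffolds < 1:
        raise ValueError("n_scaffolds must be >= 1")
    lo, hi = int(length_range[0]), int(length_range[1])
    if lo <= 0 or hi < lo:
        raise ValueError(f"invalid length_range {length_range!r}")
    if not 0.0 <= sd_density < 1.0:
        raise ValueError("sd_density must be in [0, 1)")
    rng = np.random.default_rng(seed)

    flat = isinstance(gc_params, (int, float))
    scaffolds: dict[str, str] = {}
    gc_profile: dict[str, np.ndarray] = {}
    for s in range(n_scaffolds):
        name = f"scaffold{s + 1}"
        length = int(rng.integers(lo, hi + 1)) if hi > lo else lo
        n_win = (length + gc_window - 1) // gc_window
        if flat:
            gc_target = np.full(n_win, float(gc_params))
        else:
            low, high = float(gc_params[0]), float(gc_params[1])
            if not (0.0 <= low <= high <= 1.0):
                raise ValueError("gc bounds must satisfy 0 <= low <= high <= 1")
            # smooth sinusoid with random phase and ~50-window period, plus a
            # slow random drift; clipped to [low, high]
            period = float(rng.uniform(30, 70))
            phase = float(rng.uniform(0, 2 * np.pi))
            t = np.arange(n_win)
            mid, amp = (low + high) / 2, (high - low) / 2
            drift = np.cumsum(rng.normal(0, amp / 60, n_win))
            gc_target = np.clip(
                mid + amp * np.sin(2 * np.pi * t / period + phase) + drift, low, high
            )
        gc_profile[name] = gc_target

        parts = []
        for w in range(n_win):
            n = min(gc_window, length - w * gc_window)
            gct = gc_target[w]
            if flat:
                parts.append(_bresenham_gc_window(n, gct, phase=w * gc_window))
            else:
                u = rng.random(n)
                code = np.digitize(u, [gct / 2, gct, gct + (1 - gct) / 2])
                parts.append(_BASES[code])
        scaffolds[name] = np.concatenate(parts).tobytes().decode()

    sd_intervals: list[tuple[str, int, int]] = []
    if sd_density > 0:
        names = list(scaffolds)
        lengths = {n: len(scaffolds[n]) for n in names}
        total = sum(lengths.values())
        target_bp = sd_density * total
        placed_bp = 0
        occupied: dict[str, list[tuple[int, int]]] = {n: [] for n in names}
        for _ in range(10000):
            if placed_bp >= target_bp:
                break
            scaf = names[int(rng.integers(len(names)))]
            # cap by the remaining budget so small genomes do not overshoot
            budget = int(1.2 * target_bp - placed_bp)
            hi = min(50_000, max(6_000, budget))
            lo = min(5_000, max(2_000, budget // 2))
            sd_len = int(rng.integers(lo, hi + 1))
            if sd_len >= lengths[scaf]:
                continue
            start = int(rng.integers(0, lengths[scaf] - sd_len))
            end = start + sd_len
            if any(start < e and s < end for s, e in occupied[scaf]):
                continue
            occupied[scaf].append((start, end))
            sd_intervals.append((scaf, start, end))
            placed_bp += sd_len
        sd_intervals.sort()

    return SyntheticGenome(
        scaffolds=scaffolds,
        gc_window=gc_window,
        gc_profile=gc_profile,
        sd_intervals=sd_intervals,
    )


@dataclass
class CnvSpec:
    """One requested CNV: an interval, a copy number and a sharing class.

    ``sharing`` is ``"all"``, a group label (e.g. ``"domesticated"``), or a
    sample id for an individual-specific variant.
    """

    scaffold: str
    start: int
    end: int
    copy_number: int
    sharing: str = "all"


@dataclass
class RandomCnvParams:
    """Randomised CNV layout mirroring the study's sharing classes.

    Each sample receives ``n_all + n_group + n_individual`` CNVs. Copy
    numbers are drawn from ``cn_choices`` with ``cn_weights``; the default mix
    is loss-biased (deletion-favouring, as expected under NAHR). Lengths are
    uniform in ``length_range`` (the study's calls span ~9.8-34.5 kb).
    """

    n_individual: int = 10
    n_group: int = 5
    n_all: int = 5
    cn_choices: tuple[int, ...] = (0, 1, 3, 4, 6)
    cn_weights: tuple[float, ...] = (0.25, 0.30, 0.20, 0.15, 0.10)
    length_range: tuple[int, int] = (10_000, 35_000)
    min_gap: int = 5_000


def implant_cnvs(
    genome: SyntheticGenome,
    specs: Sequence[CnvSpec] | None = None,
    random_params: RandomCnvParams | None = None,
    samples: Sequence[tuple[str, str]] = DEFAULT_SAMPLES,
    seed: int | None = None,
) -> list[SyntheticTruth]:
    """Assign CNVs to samples, honouring the requested sharing classes.

    Either ``specs`` (explicit intervals) or ``random_params`` (randomised
    layout) must be given. A group-specific CNV appears at the identical
    interval in every member of that group and in no other sample; an
    "all"-shared CNV appears in all samples.
    """
    if (specs is None) == (random_params is None):
        raise ValueError("give exactly one of specs or random_params")
    sample_ids = [s for s, _ in samples]
    groups = dict(samples)
    lengths = genome.lengths()

    def recipients(sharing: str) -> list[str]:
        if sharing == "all":
            return sample_ids
        if sharing in set(groups.values()):
            return [s for s in sample_ids if groups[s] == sharing]
        if sharing in groups:
            return [sharing]
        raise ValueError(f"unknown sharing class {sharing!r}")

    per_sample: dict[str, list[tuple[str, int, int, int]]] = {
        s: [] for s in sample_ids
    }

    if specs is not None:
        for spec in specs:
            if spec.end - spec.start < 5_000:
                raise ValueError("CNV length must be >= 5 kb")
            if spec.scaffold not in lengths:
                raise ValueError(f"unknown scaffold {spec.scaffold!r}")
            if not (0 <= spec.start < spec.end <= lengths[spec.scaffold]):
                raise ValueError("CNV outside scaffold bounds")
            for sid in recipients(spec.sharing):
                for scaf, s0, e0, _ in per_sample[sid]:
                    if scaf == spec.scaffold and spec.start < e0 and s0 < spec.end:
                        raise ValueError(
                            f"overlapping requested intervals in sample {sid} "
                            f"on {scaf}"
                        )
                per_sample[sid].append(
                    (spec.scaffold, spec.start, spec.end, spec.copy_number)
                )
    else:
        p = random_params
        rng = np.random.default_rng(seed)
        scaf_names = list(lengths)
        scaf_p = np.array([lengths[n] for n in scaf_names], dtype=float)
        scaf_p /= scaf_p.sum()
        weights = np.asarray(p.cn_weights, dtype=float)
        weights = weights / weights.sum()

        units: list[str] = (
            ["all"] * p.n_all
            + [g for g in sorted(set(groups.values())) for _ in range(p.n_group)]
            + [s for s in sample_ids for _ in range(p.n_individual)]
        )
        for sharing in units:
            rec = recipients(sharing)
            for _ in range(5000):
                scaf = scaf_names[int(rng.choice(len(scaf_names), p=scaf_p))]
                ln = int(rng.integers(p.length_range[0], p.length_range[1] + 1))
                if ln + 2 * p.min_gap >= lengths[scaf]:
                    continue
                start = int(rng.integers(p.min_gap, lengths[scaf] - ln - p.min_gap))
                end = start + ln
                clash = any(
                    scaf == s_scaf and start - p.min_gap < e0 and s0 < end + p.min_gap
                    for sid in rec
                    for s_scaf, s0, e0, _ in per_sample[sid]
                )
                if clash:
                    continue
                cn = int(rng.choice(p.cn_choices, p=weights))
                for sid in rec:
                    per_sample[sid].append((scaf, start, end, cn))
                break
            else:
                raise RuntimeError(
                    "could not place a CNV without overlap; genome too small "
                    "for the requested layout"
                )

    return [
        SyntheticTruth(
            sample_id=sid,
            group_label=groups[sid],
            cnv_intervals=sorted(per_sample[sid]),
        )
        for sid in sample_ids
    ]


def sin_bump_bias(
    amplitude: float = 0.3, center: float = 0.45, width: float = 0.15
) -> Callable[[np.ndarray], np.ndarray]:
    """Unimodal GC-bias multiplier: 1 + amplitude * sin-bump around ``center``.

    The bump is ``sin(pi * t)`` for GC within ``center +/- width`` and zero
    outside; `simulate_reads` renormalises the multiplier to mean 1 over the
    genome, so total coverage is unchanged.
    """

    def bias(gc: np.ndarray) -> np.ndarray:
        gc = np.asarray(gc, dtype=float)
        t = (gc - (center - width)) / (2 * width)
        bump = np.where((t >= 0) & (t <= 1), np.sin(np.pi * np.clip(t, 0, 1)), 0.0)
        return 1.0 + amplitude * bump

    return bias


def simulate_reads(
    genome: SyntheticGenome,
    truth: SyntheticTruth,
    coverage: float,
    read_length: int = 100,
    gc_bias_fn: Callable[[np.ndarray], np.ndarray] | None = None,
    seed: int | None = None,
) -> ReadSet:
    """Sample single-end read starts along the genome.

    The expected number of read starts per bp at a locus is
    ``(coverage / read_length) * (copy_number / 2) * gc_bias(local GC)``,
    with the bias renormalised to mean 1 over the genome; actual counts are
    Poisson. Scaffolds shorter than ``read_length`` are skipped with a
    warning.
    """
    if coverage <= 0:
        raise ValueError("coverage must be > 0")
    rng = np.random.default_rng(seed)
    w = genome.gc_window

    if gc_bias_fn is not None:
        # normalise the multiplier to mean 1 over genome windows (bp-weighted)
        vals, weights = [], []
        for name, gc in genome.gc_profile.items():
            vals.append(gc_bias_fn(gc))
            weights.append(np.minimum(w, len(genome.scaffolds[name]) - np.arange(len(gc)) * w))
        norm = float(
            np.sum(np.concatenate(vals) * np.concatenate(weights))
            / np.sum(np.concatenate(weights))
        )
    else:
        norm = 1.0

    base_rate = coverage / read_length
    read_starts: dict[str, np.ndarray] = {}
    for name, seq in genome.scaffolds.items():
        length = len(seq)
        if read_length > length:
            warnings.warn(
                f"scaffold {name} shorter than read length; skipped", stacklevel=2
            )
            continue
        cn = truth.copy_number_track(name, length).astype(float)
        rate = base_rate * cn / 2.0
        if gc_bias_fn is not None:
            gc_bp = np.repeat(genome.gc_profile[name], w)[:length]
            rate = rate * (gc_bias_fn(gc_bp) / norm)
        n_pos = length - read_length + 1
        counts = rng.poisson(rate[:n_pos])
        read_starts[name] = np.repeat(
            np.arange(n_pos, dtype=np.int64), counts
        )
    return ReadSet(
        sample_id=truth.sample_id, read_starts=read_starts, read_length=read_length
    )


def write_truth_bed(truths: Sequence[SyntheticTruth], path: str | Path) -> None:
    """BED6 truth export: name = ``sample:group``, score = copy number."""
    with open(path, "w") as fh:
        for t in truths:
            for scaf, start, end, cn in t.cnv_intervals:
                fh.write(
                    f"{scaf}\t{start}\t{end}\t{t.sample_id}:{t.group_label}\t{cn}\t.\n"
                )


def read_truth_bed(path: str | Path) -> list[SyntheticTruth]:
    by_sample: dict[str, tuple[str, list[tuple[str, int, int, int]]]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            scaf, start, end, name, score, _ = line.rstrip("\n").split("\t")[:6]
            sid, group = name.split(":", 1)
            by_sample.setdefault(sid, (group, []))[1].append(
                (scaf, int(start), int(end), int(score))
            )
    return [
        SyntheticTruth(sample_id=sid, group_label=group, cnv_intervals=sorted(ivs))
        for sid, (group, ivs) in by_sample.items()
    ]
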