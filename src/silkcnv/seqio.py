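"""Format I/O and read cleaning.

Readers/writers for the standard formats the pipeline touches (FASTQ, SAM/BAM
via pysam, BED, GFF3) plus the quality-trimming rule used before alignment:
slide a 5 bp window along the read and truncate at the start of the first
window whose mean Phred quality drops below 20.

Coordinates: BED is kept 0-based half-open verbatim; GFF3 (1-based inclusive)
is converted to 0-based half-open on load.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "trim_read",
    "trim_fastq",
    "read_alignments",
    "load_intervals",
    "load_genes",
    "write_intervals",
    "write_calls_bed",
]

MIN_KEPT_LENGTH = 30  # reads trimmed below this are dropped (alignability floor)


def trim_read(
    qualities: Sequence[int], q_threshold: float = 20, window: int = 5
) -> int:
    """Return the kept length after 3'-end quality trimming.

    Windows of ``window`` bases are scanned left to right; at the first window
    whose mean quality is below ``q_threshold`` the read is truncated at that
    window's start. Reads shorter than the window are kept whole iff their
    overall mean quality reaches the threshold, else dropped entirely.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    q = np.asarray(qualities, dtype=np.int64)
    if q.size == 0:
        raise ValueError("qualities must be non-empty")
    n = q.size
    if n < window:
        return n if q.sum() >= q_threshold * n else 0
    # integer window sums keep the threshold comparison exact
    cs = np.concatenate(([0], np.cumsum(q)))
    sums = cs[window:] - cs[:-window]
    bad = np.nonzero(sums < q_threshold * window)[0]
    return n if bad.size == 0 else int(bad[0])


def trim_fastq(
    in_path: str | Path,
    out_path: str | Path,
    q_threshold: float = 20,
    window: int = 5,
    min_length: int = MIN_KEPT_LENGTH,
) -> tuple[int, int]:
    """Trim a FASTQ file; returns (reads kept, reads dropped)."""
    from Bio import SeqIO

    kept = dropped = 0
    with open(out_path, "w") as out:
        for rec in SeqIO.parse(str(in_path), "fastq"):
            quals = rec.letter_annotations["phred_quality"]
            klen = trim_read(quals, q_threshold=q_threshold, window=window)
            if klen < min_length:
                dropped += 1
                continue
            SeqIO.write(rec[:klen], out, "fastq")
            kept += 1
    return kept, dropped


def read_alignments(
    path: str | Path, reference_names: Iterable[str] | None = None
) -> dict[str, np.ndarray]:
    """Load per-scaffold sorted read-start positions (0-based).

    Accepts SAM/BAM (unmapped, secondary, supplementary and duplicate records
    are excluded) or a plain BED of read starts. If ``reference_names`` is
    given, alignments to scaffolds outside that set raise an error.
    """
    path = Path(path)
    starts: dict[str, list[int]] = {}
    if path.suffix.lower() in {".bed", ".txt"}:
        for scaf, s, _e in load_intervals(path):
            starts.setdefault(scaf, []).append(s)
    else:
        import pysam

        save = pysam.set_verbosity(0)  # silence missing-index warning
        with pysam.AlignmentFile(str(path), check_sq=False) as fh:
            for rec in fh:
                if (
                    rec.is_unmapped
                    or rec.is_secondary
                    or rec.is_supplementary
                    or rec.is_duplicate
                ):
                    continue
                starts.setdefault(rec.reference_name, []).append(
                    rec.reference_start
                )
        pysam.set_verbosity(save)
    if reference_names is not None:
        offenders = sorted(set(starts) - set(reference_names))
        if offenders:
            raise ValueError(
                f"alignments on scaffolds absent from the reference: {offenders}"
            )
    if not starts:
        warnings.warn(f"no usable alignments in {path}", stacklevel=2)
    return {
        scaf: np.sort(np.asarray(v, dtype=np.int64)) for scaf, v in starts.items()
    }


def load_intervals(path: str | Path) -> list[tuple[str, int, int]]:
    """Load a BED3+ file as (scaffold, start, end), 0-based half-open.

    Overlapping records are preserved verbatim (no merging). Records with
    ``end <= start`` are rejected with their line number.
    """
    out: list[tuple[str, int, int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: fewer than 3 BED columns")
            scaf, start, end = fields[0], int(fields[1]), int(fields[2])
            if end <= start:
                raise ValueError(f"{path}:{lineno}: end <= start ({start}, {end})")
            out.append((scaf, start, end))
    return out


def load_genes(path: str | Path) -> list[tuple[str, int, int, str, str]]:
    """Load gene models as (scaffold, start, end, gene_id, strand).

    GFF3 ``gene`` features (1-based inclusive) are converted to 0-based
    half-open; BED6 is passed through with its convention preserved. The gene
    id is taken from ``ID=`` (falling back to ``Name=`` or ``gene_id``).
    """
    path = Path(path)
    genes: list[tuple[str, int, int, str, str]] = []
    if path.suffix.lower() in {".gff", ".gff3"}:
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                f = line.split("\t")
                if len(f) < 9:
                    raise ValueError(f"{path}:{lineno}: fewer than 9 GFF3 columns")
                if f[2] != "gene":
                    continue
                start1, end1 = int(f[3]), int(f[4])
                if end1 < start1:
                    raise ValueError(f"{path}:{lineno}: end < start")
                attrs = dict(
                    kv.split("=", 1) for kv in f[8].split(";") if "=" in kv
                )
                gid = attrs.get("ID") or attrs.get("Name") or attrs.get("gene_id")
                if gid is None:
                    gid = f"gene_{lineno}"
                genes.append((f[0], start1 - 1, end1, gid, f[6]))
    else:
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track")):
                    continue
                f = line.split("\t")
                start, end = int(f[1]), int(f[2])
                if end <= start:
                    raise ValueError(f"{path}:{lineno}: end <= start")
                gid = f[3] if len(f) > 3 else f"gene_{lineno}"
                strand = f[5] if len(f) > 5 else "."
                genes.append((f[0], start, end, gid, strand))
    return genes


def write_intervals(
    intervals: Iterable[tuple[str, int, int]], path: str | Path
) -> None:
    with open(path, "w") as fh:
        for scaf, start, end in intervals:
            fh.write(f"{scaf}\t{start}\t{end}\n")


def write_calls_bed(calls, path: str | Path) -> None:
    """Write CNV calls as BED6: name = ``sample:state``, score = copy number."""
    with open(path, "w") as fh:
        for c in calls:
            fh.write(
                f"{c.scaffold}\t{c.start}\t{c.end}\t"
                f"{c.sample_id}:{c.state}\t{c.copy_number}\t.\n"
            )
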