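"""Bespoke Illumina read filtering: trim, clip, length filter, deduplicate.

The pipeline applies four stages, in this order:

1. **Quality-run trimming** — keep only the longest contiguous run of bases
   whose Phred quality is at or above a threshold (default 12); ties go to
   the leftmost run.
2. **Adaptor clipping** — if at least ``adaptor_min_match`` bases (default
   15) of the adaptor's 3' end occur anywhere in the read as an exact
   match, truncate the read at the leftmost such occurrence.
3. **Length filter** — discard reads shorter than ``min_length`` (default
   64 bp).
4. **Prefix deduplication** — among reads whose first ``dedup_prefix``
   (default 64) bases are identical, keep only the first; shorter reads are
   compared by their full sequence.

The stages mirror the homemade qseq-era scripts used to prepare
sequencing-by-synthesis reads for haploid genome mapping, where PCR
amplification bias produces exact-prefix duplicates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO

__all__ = [
    "Read",
    "QCParams",
    "QCReport",
    "trim_quality",
    "clip_adaptor",
    "dedup",
    "qc_pipeline",
    "read_fastq",
    "write_fastq",
]


@dataclass(frozen=True)
class Read:
    """A sequencing read: id, bases and per-base Phred qualities."""

    id: str
    sequence: str
    qualities: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.qualities):
            raise ValueError(f"{self.id}: sequence/quality length mismatch")
        if any(q < 0 for q in self.qualities):
            raise ValueError(f"{self.id}: negative quality score")

    def __len__(self) -> int:
        return len(self.sequence)

    def slice(self, start: int, end: int) -> "Read":
        return Read(self.id, self.sequence[start:end], self.qualities[start:end])


@dataclass(frozen=True)
class QCParams:
    min_quality: int = 12
    adaptor: str = ""
    adaptor_min_match: int = 15
    min_length: int = 64
    dedup_prefix: int = 64

    def __post_init__(self) -> None:
        for name in ("min_quality", "adaptor_min_match", "min_length", "dedup_prefix"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class QCReport:
    """Exact per-stage accounting of a QC run."""

    reads_in: int = 0
    bases_in: int = 0
    reads_out: int = 0
    bases_out: int = 0
    trimmed_to_empty: int = 0
    adaptor_clipped: int = 0
    failed_length: int = 0
    duplicates_removed: int = 0

    @property
    def mean_length_in(self) -> float:
        return self.bases_in / self.reads_in if self.reads_in else 0.0

    @property
    def mean_length_out(self) -> float:
        return self.bases_out / self.reads_out if self.reads_out else 0.0

    def to_tsv(self) -> str:
        rows = [
            ("reads_in", self.reads_in),
            ("bases_in", self.bases_in),
            ("reads_out", self.reads_out),
            ("bases_out", self.bases_out),
            ("trimmed_to_empty", self.trimmed_to_empty),
            ("adaptor_clipped", self.adaptor_clipped),
            ("failed_length_filter", self.failed_length),
            ("duplicates_removed", self.duplicates_removed),
            ("mean_length_in", f"{self.mean_length_in:.2f}"),
            ("mean_length_out", f"{self.mean_length_out:.2f}"),
        ]
        return "\n".join(f"{k}\t{v}" for k, v in rows) + "\n"


def trim_quality(read: Read, min_quality: int = 12) -> Read:
    """Keep the longest run of bases all at or above ``min_quality``.

    On ties the leftmost run wins; if no base passes, an empty read is
    returned.
    """
    best_start = best_len = 0
    run_start = None
    for i, q in enumerate(read.qualities):
        if q >= min_quality:
            if run_start is None:
                run_start = i
            run_len = i - run_start + 1
            if run_len > best_len:
                best_start, best_len = run_start, run_len
        else:
            run_start = None
    return read.slice(best_start, best_start + best_len)


def clip_adaptor(read: Read, adaptor: str, min_match: int = 15) -> Read:
    """Truncate the read at the leftmost exact match of the adaptor's 3' end.

    A match is any suffix of the adaptor of length >= ``min_match`` found
    in full inside the read.  Reads without a qualifying match are returned
    unchanged.
    """
    if len(adaptor) < min_match:
        raise ValueError("adaptor shorter than the minimum match length")
    adaptor = adaptor.upper()
    seq = read.sequence.upper()
    n = len(seq)
    for p in range(n - min_match + 1):
        for k in range(min(len(adaptor), n - p), min_match - 1, -1):
            if seq[p : p + k] == adaptor[-k:]:
                return read.slice(0, p)
    return read


def dedup(reads: Iterable[Read], prefix_len: int = 64) -> tuple[list[Read], int]:
    """Remove later reads whose first ``prefix_len`` bases duplicate an
    earlier read; reads shorter than the prefix are compared in full.

    Returns the surviving reads (input order preserved) and the number
    removed.
    """
    seen: set[str] = set()
    kept: list[Read] = []
    removed = 0
    for r in reads:
        key = r.sequence[:prefix_len]
        if key in seen:
            removed += 1
        else:
            seen.add(key)
            kept.append(r)
    return kept, removed


def qc_read(read: Read, params: QCParams) -> tuple[Read | None, bool, bool]:
    """Trim + clip + length-filter one read.

    Returns (surviving read or None, was_clipped, was_emptied_by_trim).
    """
    trimmed = trim_quality(read, params.min_quality)
    emptied = len(trimmed) == 0
    clipped = False
    if params.adaptor and len(trimmed) > 0:
        after = clip_adaptor(trimmed, params.adaptor, params.adaptor_min_match)
        clipped = len(after) < len(trimmed)
        trimmed = after
    if len(trimmed) < params.min_length:
        return None, clipped, emptied
    return trimmed, clipped, emptied


def qc_pipeline(reads: Iterable[Read], params: QCParams) -> tuple[list[Read], QCReport]:
    """Run trim -> clip -> length filter -> dedup over a read stream."""
    report = QCReport()
    survivors: list[Read] = []
    for r in reads:
        report.reads_in += 1
        report.bases_in += len(r)
        kept, clipped, emptied = qc_read(r, params)
        if emptied:
            report.trimmed_to_empty += 1
        if clipped:
            report.adaptor_clipped += 1
        if kept is None:
            report.failed_length += 1
            continue
        survivors.append(kept)
    survivors, removed = dedup(survivors, params.dedup_prefix)
    report.duplicates_removed = removed
    report.reads_out = len(survivors)
    report.bases_out = sum(len(r) for r in survivors)
    return survivors, report


def qc_pipeline_paired(
    reads1: Iterable[Read], reads2: Iterable[Read], params: QCParams
) -> tuple[list[tuple[Read, Read]], list[Read], QCReport]:
    """Paired-end QC: mates are filtered independently; a pair survives only
    if both mates do, otherwise the survivor becomes an orphan.

    Deduplication applies to mate-1 prefixes of surviving pairs (a
    duplicated fragment duplicates both mates) and separately to orphans.
    """
    report = QCReport()
    pairs: list[tuple[Read, Read]] = []
    orphans: list[Read] = []
    for r1, r2 in zip(reads1, reads2):
        report.reads_in += 2
        report.bases_in += len(r1) + len(r2)
        k1, c1, e1 = qc_read(r1, params)
        k2, c2, e2 = qc_read(r2, params)
        report.trimmed_to_empty += int(e1) + int(e2)
        report.adaptor_clipped += int(c1) + int(c2)
        report.failed_length += int(k1 is None) + int(k2 is None)
        if k1 is not None and k2 is not None:
            pairs.append((k1, k2))
        elif k1 is not None:
            orphans.append(k1)
        elif k2 is not None:
            orphans.append(k2)
    seen: set[str] = set()
    kept_pairs: list[tuple[Read, Read]] = []
    removed = 0
    for r1, r2 in pairs:
        key = r1.sequence[: params.dedup_prefix]
        if key in seen:
            removed += 2
        else:
            seen.add(key)
            kept_pairs.append((r1, r2))
    orphans, orphan_removed = dedup(orphans, params.dedup_prefix)
    removed += orphan_removed
    report.duplicates_removed = removed
    report.reads_out = 2 * len(kept_pairs) + len(orphans)
    report.bases_out = sum(len(a) + len(b) for a, b in kept_pairs) + sum(
        len(o) for o in orphans
    )
    return kept_pairs, orphans, report


def read_fastq(path: str | Path, offset64: bool = False) -> Iterator[Read]:
    """Stream reads from a FASTQ file (Phred+33 by default)."""
    fmt = "fastq-illumina" if offset64 else "fastq"
    for rec in SeqIO.parse(str(path), fmt):
        yield Read(
            rec.id, str(rec.seq), tuple(rec.letter_annotations["phred_quality"])
        )


def write_fastq(reads: Iterable[Read], path: str | Path) -> int:
    """Write reads as Phred+33 FASTQ; returns the number written."""
    n = 0
    with open(path, "w") as fh:
        for r in reads:
            quals = "".join(chr(min(q, 93) + 33) for q in r.qualities)
            fh.write(f"@{r.id}\n{r.sequence}\n+\n{quals}\n")
            n += 1
    return n
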