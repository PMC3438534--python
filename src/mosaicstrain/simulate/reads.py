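"""Simulate error-free paired-end reads at a target coverage.

Long-insert paired reads (defaults: 400 bp reads, 2–4 kb inserts, 10x
coverage) are the classical scaffolding input for a draft assembly.  Reads
carry no sequencing errors; mates sit on opposite strands at the two ends
of a uniformly drawn insert.
"""

from __future__ import annotations

import math
from typing import Iterator, Mapping

import numpy as np
from Bio.Seq import Seq

from mosaicstrain.reads_qc import Read

__all__ = ["simulate_paired_reads", "n_pairs_for_coverage"]


def n_pairs_for_coverage(genome_length: int, read_length: int, coverage: float) -> int:
    """Number of pairs so total bases ~= coverage x genome length."""
    if coverage <= 0:
        return 0
    return math.ceil(coverage * genome_length / (2 * read_length))


def simulate_paired_reads(
    genome: Mapping[str, str],
    read_length: int = 400,
    insert_min: int = 2000,
    insert_max: int = 4000,
    coverage: float = 10.0,
    seed: int = 0,
    quality: int = 40,
) -> Iterator[tuple[Read, Read]]:
    """Yield (mate1, mate2) pairs; mate2 is the reverse complement of the
    insert's far end.  Insert sizes are uniform in [insert_min, insert_max],
    clamped into [read_length, chromosome length]; chromosomes are sampled
    proportionally to length."""
    if insert_min > insert_max:
        raise ValueError("insert_min must not exceed insert_max")
    chroms = list(genome)
    for chrom in chroms:
        if read_length > len(genome[chrom]):
            raise ValueError(
                f"read_length {read_length} exceeds chromosome {chrom} "
                f"({len(genome[chrom])} bp)"
            )
    total = sum(len(genome[c]) for c in chroms)
    n_pairs = n_pairs_for_coverage(total, read_length, coverage)
    rng = np.random.default_rng(seed)
    lengths = np.array([len(genome[c]) for c in chroms], dtype=float)
    weights = lengths / lengths.sum()
    quals = (quality,) * read_length
    for i in range(n_pairs):
        chrom = chroms[rng.choice(len(chroms), p=weights)]
        seq = genome[chrom]
        lo = max(read_length, min(insert_min, len(seq)))
        hi = min(insert_max, len(seq))
        insert = int(rng.integers(lo, hi + 1)) if hi > lo else lo
        start = int(rng.integers(0, len(seq) - insert + 1))
        fwd = seq[start : start + read_length]
        rev = str(
            Seq(seq[start + insert - read_length : start + insert]).reverse_complement()
        )
        name = f"pair{i + 1:07d}"
        yield (
            Read(f"{name}/1", fwd, quals),
            Read(f"{name}/2", rev, quals),
        )
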