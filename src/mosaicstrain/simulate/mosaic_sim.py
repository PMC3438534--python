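"""Plant mosaic ancestry blocks of controlled SNV density."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from mosaicstrain.simulate.genome import BASES, apply_variants_to_genome
from mosaicstrain.variants import Callset, Variant

__all__ = ["BlockSpec", "MosaicTruth", "plant_mosaic"]


@dataclass(frozen=True)
class BlockSpec:
    """One planted ancestry block.

    ``density`` is the target SNV density in SNVs per kb; ``label`` tags
    the (fictitious) ancestral origin, e.g. ``"reference-like"`` or
    ``"donorA"``.  Coordinates are 0-based half-open.
    """

    chrom: str
    start: int
    end: int
    density: float
    label: str = ""

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"block {self.chrom}:{self.start}-{self.end} is empty")
        if self.density < 0:
            raise ValueError("density must be non-negative")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def expected_snvs(self) -> float:
        return self.density * self.length / 1000.0


@dataclass
class MosaicTruth:
    """Sample genome + planted truth.

    ``truth`` holds the planted SNVs as a sorted callset (1-based VCF
    coordinates); ``blocks`` keeps the planted block specs for BED output.
    """

    sample_genome: dict[str, str]
    truth: Callset
    blocks: tuple[BlockSpec, ...]

    def blocks_bed(self) -> str:
        lines = [
            f"{b.chrom}\t{b.start}\t{b.end}\t{b.label or 'block'}\t{b.density:g}"
            for b in sorted(self.blocks, key=lambda b: (b.chrom, b.start))
        ]
        return "\n".join(lines) + ("\n" if lines else "")


def _validate_blocks(blocks: Sequence[BlockSpec], reference: Mapping[str, str]) -> None:
    by_chrom: dict[str, list[BlockSpec]] = {}
    for b in blocks:
        if b.chrom not in reference:
            raise ValueError(f"block on unknown chromosome {b.chrom}")
        if b.end > len(reference[b.chrom]):
            raise ValueError(
                f"block {b.chrom}:{b.start}-{b.end} beyond chromosome end"
            )
        by_chrom.setdefault(b.chrom, []).append(b)
    for chrom, bs in by_chrom.items():
        bs.sort(key=lambda b: b.start)
        for a, b in zip(bs, bs[1:]):
            if a.end > b.start:
                raise ValueError(
                    f"overlapping blocks {chrom}:{a.start}-{a.end} and "
                    f"{chrom}:{b.start}-{b.end}"
                )


def plant_mosaic(
    reference: Mapping[str, str],
    blocks: Sequence[BlockSpec],
    seed: int,
    exact: bool = True,
    forbidden: Iterable[tuple[str, int]] = (),
) -> MosaicTruth:
    """Plant SNVs block by block and build the mosaic sample genome.

    Per block the SNV count is ``round(density x length / 1000)`` in exact
    mode or a Poisson draw with that mean otherwise; positions are uniform
    without replacement within the block and the alternate base is drawn
    uniformly from the three non-reference bases.  ``forbidden`` lists
    (chrom, 0-based position) pairs that must stay untouched (e.g. bases
    already edited by planted marker mutations).

    The truth callset applied to the reference reproduces the sample
    genome exactly.
    """
    _validate_blocks(blocks, reference)
    rng = np.random.default_rng(seed)
    forbidden_set = set(forbidden)
    variants: list[Variant] = []
    for block in sorted(blocks, key=lambda b: (b.chrom, b.start)):
        mean = block.expected_snvs
        n = int(round(mean)) if exact else int(rng.poisson(mean))
        candidates = np.arange(block.start, block.end)
        blocked = [p for c, p in forbidden_set if c == block.chrom]
        if blocked:
            candidates = candidates[~np.isin(candidates, blocked)]
        if n > len(candidates):
            raise ValueError(
                f"block {block.chrom}:{block.start}-{block.end}: "
                f"{n} SNVs requested but only {len(candidates)} positions free"
            )
        chosen = rng.choice(len(candidates), size=n, replace=False)
        seq = reference[block.chrom]
        for idx in sorted(chosen):
            p = int(candidates[idx])
            ref_base = seq[p]
            alts = [b for b in BASES if b != ref_base]
            alt = alts[rng.integers(3)]
            variants.append(Variant(block.chrom, p + 1, ref_base, alt))
    truth = Callset("truth", variants=tuple(variants))
    sample = apply_variants_to_genome(reference, truth)
    return MosaicTruth(sample_genome=sample, truth=truth, blocks=tuple(blocks))
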