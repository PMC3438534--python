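"""Simulate per-platform/per-mapper callsets and tiling-array calls."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from mosaicstrain.mosaic import ArrayCall
from mosaicstrain.simulate.genome import BASES
from mosaicstrain.variants import Callset, Variant

__all__ = ["ErrorModel", "simulate_callsets", "simulate_array_calls"]

_MAX_FP_TRIES = 100


@dataclass(frozen=True)
class ErrorModel:
    """Independent contamination of one callset.

    ``fp_rate`` is the expected number of false-positive calls per kb of
    genome (platform-specific artefacts); ``fn_rate`` the probability that
    a true variant is missed.  Each callset must carry its own seed so
    that errors are independent between callsets.
    """

    fp_rate: float = 0.0
    fn_rate: float = 0.0
    seed: int = 0
    poisson_fp: bool = False

    def __post_init__(self) -> None:
        if self.fp_rate < 0:
            raise ValueError("fp_rate must be non-negative")
        if not 0 <= self.fn_rate < 1:
            raise ValueError("fn_rate must be in [0, 1)")


def _draw_false_positives(
    rng: np.random.Generator,
    reference: Mapping[str, str],
    n_fp: int,
    truth_positions: set[tuple[str, int]],
) -> list[Variant]:
    chroms = list(reference)
    lengths = np.array([len(reference[c]) for c in chroms], dtype=float)
    weights = lengths / lengths.sum()
    out: list[Variant] = []
    taken: set[tuple[str, int]] = set()
    for _ in range(n_fp):
        for _attempt in range(_MAX_FP_TRIES):
            chrom = chroms[rng.choice(len(chroms), p=weights)]
            pos = int(rng.integers(1, len(reference[chrom]) + 1))
            key = (chrom, pos)
            if key in truth_positions or key in taken:
                continue
            ref_base = reference[chrom][pos - 1]
            alts = [b for b in BASES if b != ref_base]
            out.append(Variant(chrom, pos, ref_base, alts[rng.integers(3)]))
            taken.add(key)
            break
        else:
            raise RuntimeError(
                "could not place a false positive off the truth set; "
                "fp_rate too high for this genome"
            )
    return out


def simulate_callsets(
    truth: Callset,
    reference: Mapping[str, str],
    platforms: Sequence[str],
    mappers: Sequence[str],
    error_models: Mapping[tuple[str, str], ErrorModel],
) -> dict[tuple[str, str], Callset]:
    """One contaminated callset per (platform, mapper) combination.

    Each callset is (truth minus its own false-negative draws) union (its
    own false positives at random non-truth positions).  Draws are
    independent between callsets — the property that makes the consensus
    intersection eliminate platform-specific errors.
    """
    truth_positions = {(v.chrom, v.pos) for v in truth}
    genome_kb = sum(len(s) for s in reference.values()) / 1000.0
    out: dict[tuple[str, str], Callset] = {}
    for platform in platforms:
        for mapper in mappers:
            em = error_models[(platform, mapper)]
            rng = np.random.default_rng(em.seed)
            kept = [v for v in truth if rng.random() >= em.fn_rate]
            mean_fp = em.fp_rate * genome_kb
            n_fp = int(rng.poisson(mean_fp)) if em.poisson_fp else int(round(mean_fp))
            fps = _draw_false_positives(rng, reference, n_fp, truth_positions)
            out[(platform, mapper)] = Callset(
                name=f"{platform}:{mapper}",
                platform=platform,
                mapper=mapper,
                variants=tuple(kept + fps),
            )
    return out


def simulate_array_calls(
    truth: Callset,
    chrom_lengths: Mapping[str, int],
    jitter_max_bp: int = 2,
    sensitivity: float = 1.0,
    noise_calls: int = 0,
    seed: int = 0,
    strain: str = "sample",
) -> list[ArrayCall]:
    """Tiling-array-like calls: each truth SNV is detected with probability
    ``sensitivity`` and reported with a uniform positional jitter in
    [-jitter_max_bp, +jitter_max_bp]; ``noise_calls`` extra calls land at
    uniform random positions."""
    if not 0 <= sensitivity <= 1:
        raise ValueError("sensitivity must be in [0, 1]")
    if jitter_max_bp < 0:
        raise ValueError("jitter_max_bp must be non-negative")
    rng = np.random.default_rng(seed)
    calls: list[ArrayCall] = []
    for v in truth.snvs():
        if rng.random() >= sensitivity:
            continue
        jitter = int(rng.integers(-jitter_max_bp, jitter_max_bp + 1))
        pos = min(max(1, v.pos + jitter), chrom_lengths[v.chrom])
        calls.append(ArrayCall(v.chrom, pos, strain))
    chroms = list(chrom_lengths)
    lengths = np.array([chrom_lengths[c] for c in chroms], dtype=float)
    weights = lengths / lengths.sum()
    for _ in range(noise_calls):
        chrom = chroms[rng.choice(len(chroms), p=weights)]
        pos = int(rng.integers(1, chrom_lengths[chrom] + 1))
        calls.append(ArrayCall(chrom, pos, strain))
    calls.sort(key=lambda c: (c.chrom, c.pos))
    return calls
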