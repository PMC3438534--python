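"""N-way consensus variant calling with elimination accounting.

Variants called independently by several sequencing platforms and/or
mapping algorithms are intersected so that only calls confirmed by every
source survive.  Platform-specific false positives are, to a very good
approximation, independent between callsets, so the intersection removes
them while true variants — present in every callset — survive.

The module supports grouping: with ``groupby="mapper"`` each mapper's
callsets are first intersected across platforms, then the per-mapper
consensuses are intersected into the final set (the symmetric order with
``groupby="platform"``).  Under strict allele-aware matching both
orders give the same final consensus.

The :class:`ConsensusReport` accounts exactly for every eliminated call:
``eliminated per callset = |callset| - |matched subset|`` and the total is
their sum, so e.g. intersecting callsets of 11 324 and 10 130 variants down
to a 9 073-variant consensus eliminates (11 324 - 9 073) + (10 130 - 9 073)
= 3 308 calls.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from mosaicstrain.variants import Callset, Variant, classify, union_keys

__all__ = [
    "ConsensusReport",
    "CrossConfirmation",
    "match",
    "intersect",
    "accounting",
    "cross_confirm",
    "round_half_up",
]

_CLASS_ROWS = ("SNP", "INDEL", "MNV", "sum")


def round_half_up(x: float) -> int:
    """Round to nearest integer with .5 going up (report convention)."""
    return int(math.floor(x + 0.5))


def match(a: Variant, b: Variant, mode: str = "strict") -> bool:
    """Decide whether two normalized variants are the same call.

    ``strict``
        equal (chrom, pos, ref, alt) — the default everywhere.
    ``loose``
        for MNVs only: overlapping reference spans with identical alt;
        non-MNV pairs still match strictly.
    """
    if mode == "strict":
        return a.key() == b.key()
    if mode == "loose":
        if classify(a) == "MNV" and classify(b) == "MNV":
            return (
                a.chrom == b.chrom
                and a.pos <= b.end
                and b.pos <= a.end
                and a.alt == b.alt
            )
        return a.key() == b.key()
    raise ValueError(f"unknown match mode {mode!r}")


def _intersect_pairwise(callsets: Sequence[Callset], name: str) -> Callset:
    keys = None
    for cs in callsets:
        keys = cs.keys() if keys is None else keys & cs.keys()
    keys = keys or frozenset()
    variants = tuple(Variant(*k) for k in keys)
    platforms = sorted({cs.platform for cs in callsets if cs.platform})
    mappers = sorted({cs.mapper for cs in callsets if cs.mapper})
    return Callset(
        name,
        platform="+".join(platforms),
        mapper="+".join(mappers),
        variants=variants,
    )


def intersect(
    callsets: Sequence[Callset], groupby: str = "none"
) -> tuple[dict[str, Callset], Callset]:
    """Intersect callsets, optionally grouped by mapper or platform.

    Returns ``(per_group_consensus, final_consensus)``.  With
    ``groupby="mapper"`` each group holds one mapper's callsets across all
    platforms; the final consensus intersects the per-group results.  A
    group containing a single callset passes through unchanged.
    """
    if len(callsets) < 2:
        raise ValueError("need at least two callsets to build a consensus")
    if groupby not in ("mapper", "platform", "none"):
        raise ValueError(f"groupby must be mapper, platform or none, not {groupby!r}")

    if groupby == "none":
        final = _intersect_pairwise(callsets, "consensus")
        return {}, final

    groups: dict[str, list[Callset]] = {}
    for cs in callsets:
        key = cs.mapper if groupby == "mapper" else cs.platform
        groups.setdefault(key, []).append(cs)
    per_group = {
        key: _intersect_pairwise(members, f"consensus[{key}]")
        for key, members in groups.items()
    }
    final = _intersect_pairwise(list(per_group.values()), "consensus")
    return per_group, final


@dataclass
class ConsensusReport:
    """Full accounting of a consensus run.

    ``class_table`` has one column per input callset, per group consensus
    and the final consensus; rows are SNP, INDEL (single-base), MNV and
    their sum.
    """

    input_sizes: dict[str, int]
    group_sizes: dict[str, int]
    final_size: int
    eliminated: dict[str, int]
    eliminated_total: int
    union_size: int
    fraction_eliminated: float
    class_table: dict[str, dict[str, int]]

    @property
    def percent_eliminated(self) -> int:
        return round_half_up(100.0 * self.fraction_eliminated)

    def to_tsv(self) -> str:
        cols = list(self.class_table)
        lines = ["class\t" + "\t".join(cols)]
        for row in _CLASS_ROWS:
            lines.append(
                row + "\t" + "\t".join(str(self.class_table[c][row]) for c in cols)
            )
        lines.append("")
        lines.append(f"eliminated_total\t{self.eliminated_total}")
        lines.append(f"union_size\t{self.union_size}")
        lines.append(
            f"fraction_eliminated\t{self.fraction_eliminated:.4f}"
            f"\t({self.percent_eliminated}%)"
        )
        return "\n".join(lines) + "\n"


def _class_counts(cs: Callset) -> dict[str, int]:
    by = cs.by_class()
    return {
        "SNP": by["SNP"],
        "INDEL": by["INS"] + by["DEL"],
        "MNV": by["MNV"],
        "sum": len(cs),
    }


def accounting(
    callsets: Sequence[Callset],
    per_group: dict[str, Callset],
    final: Callset,
) -> ConsensusReport:
    """Build the elimination accounting for a consensus run.

    Identities guaranteed by construction (and asserted in the test suite):
    eliminated per callset = |callset| - |callset matched by the final
    consensus|; eliminated_total is their sum; class counts per column sum
    to the column total.
    """
    final_keys = final.keys()
    input_sizes = {cs.name: len(cs) for cs in callsets}
    eliminated = {
        cs.name: len(cs) - len(cs.keys() & final_keys) for cs in callsets
    }
    eliminated_total = sum(eliminated.values())
    union = union_keys(callsets)
    table: dict[str, dict[str, int]] = {}
    for cs in callsets:
        table[cs.name] = _class_counts(cs)
    for key, cs in per_group.items():
        table[cs.name] = _class_counts(cs)
    table[final.name] = _class_counts(final)
    return ConsensusReport(
        input_sizes=input_sizes,
        group_sizes={k: len(cs) for k, cs in per_group.items()},
        final_size=len(final),
        eliminated=eliminated,
        eliminated_total=eliminated_total,
        union_size=len(union),
        fraction_eliminated=eliminated_total / len(union) if union else 0.0,
        class_table=table,
    )


@dataclass(frozen=True)
class CrossConfirmation:
    """Agreement between two consensuses for one variant class."""

    confirmed: int
    a_only: int
    b_only: int

    @property
    def percent_of_a(self) -> int:
        total_a = self.confirmed + self.a_only
        return round_half_up(100.0 * self.confirmed / total_a) if total_a else 100

    @property
    def percent_of_b(self) -> int:
        total_b = self.confirmed + self.b_only
        return round_half_up(100.0 * self.confirmed / total_b) if total_b else 100


def cross_confirm(
    consensus_a: Callset, consensus_b: Callset, vclass: str | None = None
) -> CrossConfirmation:
    """Compare two (typically per-mapper) consensuses for one variant class.

    ``confirmed`` counts calls present in both, ``a_only``/``b_only`` the
    calls each consensus makes that the other does not.  Percentages are
    rounded half-up to the nearest integer.
    """
    a = consensus_a.restrict(vclass).keys()
    b = consensus_b.restrict(vclass).keys()
    return CrossConfirmation(
        confirmed=len(a & b), a_only=len(a - b), b_only=len(b - a)
    )
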