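"""Variant data model, normalization, classification and VCF I/O.

A :class:`Variant` is one normalized difference against a haploid reference
genome.  Variants are classified into three classes:

``SNP``
    both alleles a single base;
``INS`` / ``DEL``
    a single-base net length change (one inserted or one deleted base),
    the "single insertion/deletion" class;
``MNV``
    everything else — multi-base substitutions, longer indels and complex
    replacements ("multiple number variations").

All variants are left-aligned and trimmed before comparison so that
equivalent representations emitted by different variant callers compare
equal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pysam

__all__ = [
    "Variant",
    "Callset",
    "ReferenceMismatchError",
    "VcfParseError",
    "normalize",
    "classify",
    "read_vcf",
    "write_vcf",
]

_CLASSES = ("SNP", "INS", "DEL", "MNV")


class ReferenceMismatchError(ValueError):
    """The REF allele of a variant disagrees with the reference genome."""


class VcfParseError(ValueError):
    """A VCF record could not be parsed; carries the 1-based line number."""


@dataclass(frozen=True, order=True)
class Variant:
    """One normalized difference versus the reference.

    Attributes
    ----------
    chrom : str
        Chromosome identifier.
    pos : int
        1-based position of the first reference base of the event.
    ref, alt : str
        Reference and alternate alleles (non-empty, upper-case).
    """

    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if not self.ref or not self.alt:
            raise ValueError(f"empty allele at {self.chrom}:{self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt at {self.chrom}:{self.pos}")

    @property
    def vclass(self) -> str:
        return classify(self)

    @property
    def end(self) -> int:
        """1-based inclusive end of the reference span."""
        return self.pos + len(self.ref) - 1

    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


def classify(variant: Variant) -> str:
    """Assign one of SNP / INS / DEL / MNV to a normalized variant.

    The partition is total and exclusive: single-base substitutions are
    SNPs; events inserting or deleting exactly one base are INS/DEL; every
    other event (multi-base substitution, longer or complex indel) is MNV.
    """
    nref, nalt = len(variant.ref), len(variant.alt)
    if nref == 1 and nalt == 1:
        return "SNP"
    if nref == 1 and nalt == 2 and variant.alt[0] == variant.ref:
        return "INS"
    if nref == 2 and nalt == 1 and variant.ref[0] == variant.alt:
        return "DEL"
    return "MNV"


def normalize(variant: Variant, reference: Mapping[str, str]) -> Variant:
    """Left-align and trim a variant against the reference genome.

    The canonical left-alignment used before comparing callsets: while the
    alleles share their last base, strip it (prepending the previous
    reference base whenever an allele would become empty, which walks
    indels leftward through repeat runs); then strip shared leading bases
    beyond the single anchor base VCF requires for indels.  Equivalent
    representations of the same event always normalize to the same
    (chrom, pos, ref, alt).

    Parameters
    ----------
    reference : mapping of chromosome id to sequence string
        Any mapping with string values works (a dict, a ``pyfaidx.Fasta``
        wrapped as strings, ...).

    Raises
    ------
    ReferenceMismatchError
        If the REF allele does not match the reference at ``pos``.
    """
    seq = str(reference[variant.chrom])
    start0 = variant.pos - 1
    if seq[start0 : start0 + len(variant.ref)].upper() != variant.ref.upper():
        raise ReferenceMismatchError(
            f"REF allele {variant.ref!r} does not match reference at "
            f"{variant.chrom}:{variant.pos}"
        )
    pos, ref, alt = variant.pos, variant.ref.upper(), variant.alt.upper()
    while True:
        if ref and alt and ref[-1] == alt[-1] and (len(ref) > 1 or len(alt) > 1):
            ref, alt = ref[:-1], alt[:-1]
            if ref and alt:
                continue
        if not ref or not alt:
            if pos == 1:  # cannot extend left past the chromosome start
                prev = None
            else:
                prev = seq[pos - 2].upper()
            if prev is None:
                raise ValueError(
                    f"cannot left-align {variant.chrom}:{variant.pos} past "
                    "chromosome start"
                )
            ref, alt = prev + ref, prev + alt
            pos -= 1
            continue
        break
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return Variant(variant.chrom, pos, ref, alt)


@dataclass
class Callset:
    """A named, sorted, duplicate-free set of variants from one source.

    ``platform`` and ``mapper`` record provenance, e.g. which sequencing
    technology and which mapping algorithm produced the calls.
    """

    name: str
    platform: str = ""
    mapper: str = ""
    variants: tuple[Variant, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        self.variants = tuple(sorted(set(self.variants)))

    def __len__(self) -> int:
        return len(self.variants)

    def __iter__(self):
        return iter(self.variants)

    def __contains__(self, v: Variant) -> bool:
        return v in set(self.variants)

    def keys(self) -> frozenset[tuple[str, int, str, str]]:
        return frozenset(v.key() for v in self.variants)

    def snvs(self) -> tuple[Variant, ...]:
        return tuple(v for v in self.variants if classify(v) == "SNP")

    def by_class(self) -> dict[str, int]:
        counts = {c: 0 for c in _CLASSES}
        for v in self.variants:
            counts[classify(v)] += 1
        return counts

    def restrict(self, vclass: str | None) -> "Callset":
        if vclass is None:
            return self
        if vclass == "INDEL":
            keep = {"INS", "DEL"}
        else:
            keep = {vclass}
        return Callset(
            self.name,
            self.platform,
            self.mapper,
            tuple(v for v in self.variants if classify(v) in keep),
        )


def read_vcf(
    path: str | Path,
    name: str | None = None,
    platform: str = "",
    mapper: str = "",
    reference: Mapping[str, str] | None = None,
) -> Callset:
    """Read a VCF (v4.x, plain or bgzipped) into a :class:`Callset`.

    Multi-allelic records are split into one variant per ALT allele.  If a
    reference is supplied every variant is normalized on the way in; the
    output is always sorted and duplicate-free.
    """
    variants: list[Variant] = []
    try:
        vf = pysam.VariantFile(str(path))
    except (OSError, ValueError) as exc:
        raise VcfParseError(f"{path}: cannot open as VCF: {exc}") from exc
    with vf:
        for recno, rec in enumerate(vf, start=1):
            if rec.ref is None:
                raise VcfParseError(f"{path}: record {recno} lacks a REF allele")
            for alt in rec.alts or ():
                if alt in (".", "*", "<NON_REF>") or alt == rec.ref:
                    continue
                try:
                    v = Variant(rec.chrom, rec.pos, rec.ref.upper(), alt.upper())
                except ValueError as exc:
                    raise VcfParseError(f"{path}: record {recno}: {exc}") from exc
                if reference is not None:
                    v = normalize(v, reference)
                variants.append(v)
    return Callset(name or Path(path).stem, platform, mapper, tuple(variants))


def write_vcf(
    callset: Callset,
    path: str | Path,
    contig_lengths: Mapping[str, int] | None = None,
) -> None:
    """Write a callset as a sorted, uncompressed VCF v4.2 with class in INFO."""
    header = pysam.VariantHeader()
    header.add_line(f"##source=mosaicstrain callset={callset.name}")
    header.add_line(
        '##INFO=<ID=VCLASS,Number=1,Type=String,'
        'Description="Variant class: SNP, INS, DEL or MNV">'
    )
    if contig_lengths:
        contigs = dict(contig_lengths)
    else:
        # unknown true lengths: bound by the last reference base touched
        contigs = {}
        for v in callset:
            contigs[v.chrom] = max(contigs.get(v.chrom, 0), v.end)
    for chrom in sorted(contigs):
        header.contigs.add(chrom, length=contigs[chrom])
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for v in callset:
            rec = out.new_record(
                contig=v.chrom,
                start=v.pos - 1,
                stop=v.end,
                alleles=(v.ref, v.alt),
                filter="PASS",
            )
            rec.info["VCLASS"] = classify(v)
            out.write(rec)


def union_keys(callsets: Sequence[Callset]) -> frozenset[tuple[str, int, str, str]]:
    out: set[tuple[str, int, str, str]] = set()
    for cs in callsets:
        out |= cs.keys()
    return frozenset(out)
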