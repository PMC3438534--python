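"""Plant marker mutations (nonsense, frameshift, neutralizing pairs, ...)
into genes of a synthetic reference.

Edits are designed in CDS space at requested codon indices, converted to
genome-space VCF entries (strand-aware), and are constructed so that the
downstream effect annotation reproduces the intended kind and codon index:
a nonsense planted at a glutamate codon 64 annotates as ``glu64STOP``, a
1 bp deletion in codon 47 as a frameshift at codon 47, and a +1/−1 pair
as two frameshifts with the reading frame restored.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from Bio.Seq import Seq

from mosaicstrain.effects import extract_cds, translate
from mosaicstrain.genes import GeneModel
from mosaicstrain.simulate.genome import BASES, STOP_CODONS
from mosaicstrain.variants import Variant, normalize

__all__ = ["MarkerSpec", "MarkerPlantingError", "plant_marker_mutations"]

KINDS = ("nonsense", "frameshift", "neutralizing_pair", "missense_n", "inframe_indel")


class MarkerPlantingError(ValueError):
    """The requested marker cannot be planted at the given codon(s)."""


@dataclass(frozen=True)
class MarkerSpec:
    """One marker mutation to plant.

    ``codons`` are 1-based codon indices: one for nonsense / frameshift /
    inframe_indel, two (insertion site, deletion site) for
    neutralizing_pair, and ``n`` sites for missense_n (n = len(codons)).
    """

    gene_id: str
    kind: str
    codons: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown marker kind {self.kind!r}")
        if self.kind == "neutralizing_pair" and len(self.codons) != 2:
            raise ValueError("neutralizing_pair needs exactly two codon indices")
        if self.kind in ("nonsense", "frameshift", "inframe_indel") and len(
            self.codons
        ) != 1:
            raise ValueError(f"{self.kind} needs exactly one codon index")


def _cds_to_genome(gene: GeneModel) -> list[int]:
    """0-based genome position of each CDS base, in CDS orientation."""
    fwd = [p for s, e in gene.cds for p in range(s, e)]
    return fwd[::-1] if gene.strand == "-" else fwd


def _genome_variant(
    gene: GeneModel,
    genome: Mapping[str, str],
    cds_map: Sequence[int],
    off: int,
    ref_c: str,
    alt_c: str,
) -> Variant:
    """Convert a CDS-space edit (offset, ref, alt in CDS orientation) into
    a genome-space variant.  The edited CDS span must be contiguous in the
    genome (single-exon span)."""
    span = [cds_map[off + i] for i in range(len(ref_c))]
    lo, hi = min(span), max(span)
    if hi - lo + 1 != len(ref_c):
        raise MarkerPlantingError(
            f"{gene.gene_id}: edit at CDS offset {off} crosses an intron"
        )
    if gene.strand == "+":
        g_ref, g_alt = ref_c, alt_c
    else:
        g_ref = str(Seq(ref_c).reverse_complement())
        g_alt = str(Seq(alt_c).reverse_complement())
    found = genome[gene.chrom][lo : hi + 1]
    if found != g_ref:
        raise MarkerPlantingError(
            f"{gene.gene_id}: genome disagrees with CDS at {gene.chrom}:{lo + 1} "
            f"({found!r} != {g_ref!r})"
        )
    return Variant(gene.chrom, lo + 1, g_ref, g_alt)


def _codon_span(idx: int) -> tuple[int, int]:
    return 3 * (idx - 1), 3 * idx


def _nonsense_edit(cds: str, idx: int, n_codons: int) -> tuple[int, str, str]:
    if idx >= n_codons:
        raise MarkerPlantingError(
            f"cannot plant a nonsense at or beyond the natural stop (codon {idx})"
        )
    s, e = _codon_span(idx)
    codon = cds[s:e]
    for stop in STOP_CODONS:
        diff = [i for i in range(3) if codon[i] != stop[i]]
        if len(diff) == 1:
            i = diff[0]
            return s + i, codon[i], stop[i]
    raise MarkerPlantingError(
        f"codon {idx} ({codon}) cannot become a stop by one substitution"
    )


def _deletion_edit(cds: str, idx: int) -> tuple[int, str, str]:
    """Delete one base of codon ``idx``.

    The base is chosen so that both neighbours differ from it, which makes
    the single-base deletion representation unique under left-alignment on
    either strand — the frameshift therefore always annotates at codon
    ``idx``.
    """
    s, e = _codon_span(idx)
    for o in range(s, e):
        if o == 0:
            continue  # no left anchor available
        left_ok = cds[o - 1] != cds[o]
        right_ok = o + 1 >= len(cds) or cds[o + 1] != cds[o]
        if left_ok and right_ok:
            a = o - 1
            return a, cds[a : a + 2], cds[a]
    raise MarkerPlantingError(
        f"no base of codon {idx} can be deleted unambiguously "
        "(homopolymer context)"
    )


def _insertion_edit(cds: str, idx: int, rng: np.random.Generator) -> tuple[int, str, str]:
    """Insert one base at the start of codon ``idx`` (left-align stable)."""
    s, _ = _codon_span(idx)
    if s == 0:
        raise MarkerPlantingError("cannot insert before the start codon")
    a = s - 1
    choices = [b for b in BASES if b != cds[a] and b != cds[s]]
    # prefer a non-T base: T could seed a stop codon in the shifted frame
    non_t = [b for b in choices if b != "T"]
    choices = non_t or choices
    ins = choices[int(rng.integers(len(choices)))]
    return a, cds[a], cds[a] + ins


def _missense_edit(
    cds: str, idx: int, n_codons: int, rng: np.random.Generator
) -> tuple[int, str, str]:
    if idx >= n_codons or idx <= 1:
        raise MarkerPlantingError(f"missense codon index {idx} out of range")
    s, e = _codon_span(idx)
    codon = cds[s:e]
    aa = translate(codon)
    options = []
    for i in range(3):
        for b in BASES:
            if b == codon[i]:
                continue
            new = codon[:i] + b + codon[i + 1:]
            if new in STOP_CODONS:
                continue
            if translate(new) != aa:
                options.append((s + i, codon[i], b))
    if not options:
        raise MarkerPlantingError(f"codon {idx} ({codon}) has no missense substitution")
    return options[int(rng.integers(len(options)))]


def plant_marker_mutations(
    reference: Mapping[str, str],
    genes: Sequence[GeneModel],
    specs: Sequence[MarkerSpec],
    seed: int = 0,
) -> list[Variant]:
    """Design genome-space VCF entries realising each marker spec.

    Edits within one gene must not overlap; codon indices must exist.
    Returns the variants sorted by position (coordinates are relative to
    the *reference*, as in any truth VCF).
    """
    rng = np.random.default_rng(seed)
    by_id = {g.gene_id: g for g in genes}
    variants: list[Variant] = []
    for spec in specs:
        gene = by_id.get(spec.gene_id)
        if gene is None:
            raise MarkerPlantingError(f"unknown gene {spec.gene_id!r}")
        cds = extract_cds(gene, reference)
        n_codons = len(cds) // 3
        for idx in spec.codons:
            if not 1 <= idx <= n_codons:
                raise MarkerPlantingError(
                    f"{spec.gene_id}: codon {idx} outside CDS ({n_codons} codons)"
                )
        cds_map = _cds_to_genome(gene)
        edits: list[tuple[int, str, str]] = []
        if spec.kind == "nonsense":
            edits.append(_nonsense_edit(cds, spec.codons[0], n_codons))
        elif spec.kind == "frameshift":
            edits.append(_deletion_edit(cds, spec.codons[0]))
        elif spec.kind == "neutralizing_pair":
            ins_at, del_at = spec.codons
            edits.append(_insertion_edit(cds, ins_at, rng))
            edits.append(_deletion_edit(cds, del_at))
        elif spec.kind == "missense_n":
            for idx in spec.codons:
                edits.append(_missense_edit(cds, idx, n_codons, rng))
        elif spec.kind == "inframe_indel":
            s, e = _codon_span(spec.codons[0])
            if s == 0:
                raise MarkerPlantingError("cannot delete the start codon")
            a = s - 1
            edits.append((a, cds[a:e], cds[a]))
        edits.sort()
        for (o1, r1, _), (o2, _, _) in zip(edits, edits[1:]):
            if o1 + len(r1) > o2:
                raise MarkerPlantingError(
                    f"{spec.gene_id}: planted edits overlap at CDS offsets "
                    f"{o1} and {o2}"
                )
        for off, ref_c, alt_c in edits:
            v = _genome_variant(gene, reference, cds_map, off, ref_c, alt_c)
            variants.append(normalize(v, reference))
    variants.sort()
    for a, b in zip(variants, variants[1:]):
        if a.chrom == b.chrom and a.pos + len(a.ref) > b.pos:
            raise MarkerPlantingError(
                f"planted variants overlap at {a.chrom}:{a.pos} and {b.pos}"
            )
    return variants
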