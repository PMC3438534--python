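"""Random reference genomes with translatable gene models."""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio.Seq import Seq

from mosaicstrain.genes import GeneModel
from mosaicstrain.variants import Variant

__all__ = [
    "STOP_CODONS",
    "generate_reference",
    "synthesize_cds",
    "place_gene",
    "apply_variants_to_genome",
    "GenePlacementError",
]

BASES = "ACGT"
STOP_CODONS = ("TAA", "TAG", "TGA")
SENSE_CODONS = tuple(
    a + b + c
    for a in BASES
    for b in BASES
    for c in BASES
    if a + b + c not in STOP_CODONS
)
# codons without T can never contribute to a stop in any reading frame
T_FREE_CODONS = tuple(c for c in SENSE_CODONS if "T" not in c)


class GenePlacementError(RuntimeError):
    """Genes could not be placed without overlap in the given chromosomes."""


def _random_sequence(rng: np.random.Generator, length: int, gc: float) -> str:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list(BASES), size=length, p=probs))


def synthesize_cds(
    rng: np.random.Generator,
    n_codons: int,
    codon_overrides: Mapping[int, str] | None = None,
    t_free_codon_range: tuple[int, int] | None = None,
) -> str:
    """Build a CDS: ATG start, random sense codons, one terminal stop.

    ``codon_overrides`` maps 1-based codon indices to fixed codons (e.g.
    force codon 64 to GAA so a planted nonsense reads ``glu64STOP``).
    ``t_free_codon_range`` (1-based, inclusive) restricts a codon stretch
    to T-free codons, which guarantees no stop can appear there in *any*
    reading frame — the precondition for planting a neutralizing
    frameshift pair whose shifted segment must translate without stops.

    Overriding codon 1, the terminal codon, or overriding with a stop
    codon raises ``ValueError``.
    """
    if n_codons < 3:
        raise ValueError("a gene needs at least start, one sense and stop codon")
    overrides = dict(codon_overrides or {})
    for idx, codon in overrides.items():
        if idx <= 1 or idx >= n_codons:
            raise ValueError(f"cannot override start/stop codon (index {idx})")
        if codon.upper() in STOP_CODONS:
            raise ValueError(f"override {codon!r} at codon {idx} is a stop codon")
    codons = ["ATG"]
    for i in range(2, n_codons):
        if i in overrides:
            codons.append(overrides[i].upper())
        elif t_free_codon_range and t_free_codon_range[0] <= i <= t_free_codon_range[1]:
            codons.append(T_FREE_CODONS[rng.integers(len(T_FREE_CODONS))])
        else:
            codons.append(SENSE_CODONS[rng.integers(len(SENSE_CODONS))])
    codons.append(STOP_CODONS[rng.integers(len(STOP_CODONS))])
    return "".join(codons)


def place_gene(
    genome: dict[str, str],
    chrom: str,
    start: int,
    cds_seq: str,
    strand: str,
    gene_id: str,
) -> GeneModel:
    """Write a CDS into the genome at ``start`` (0-based) and return its model.

    For minus-strand genes the reverse complement is written so that
    extracting the CDS strand-aware recovers ``cds_seq``.  Mutates
    ``genome`` in place.
    """
    seq = genome[chrom]
    end = start + len(cds_seq)
    if start < 0 or end > len(seq):
        raise GenePlacementError(f"{gene_id}: {chrom}:{start}-{end} out of range")
    insert = cds_seq if strand == "+" else str(Seq(cds_seq).reverse_complement())
    genome[chrom] = seq[:start] + insert + seq[end:]
    return GeneModel(gene_id=gene_id, chrom=chrom, strand=strand, cds=((start, end),))


def generate_reference(
    seed: int,
    chrom_lengths: Mapping[str, int],
    gc_fraction: float = 0.38,
    n_genes: int = 20,
    gene_codons: tuple[int, int] = (150, 400),
    max_tries: int = 200,
) -> tuple[dict[str, str], list[GeneModel]]:
    """Generate a random reference genome plus non-overlapping gene models.

    Every gene starts with ATG, ends with a stop, has length divisible by
    3 and no internal in-frame stop (guaranteed by construction from sense
    codons).  Genes are distributed over chromosomes proportionally to
    length, on alternating strands.  Deterministic for a fixed seed.
    """
    if not 0 < gc_fraction < 1:
        raise ValueError("gc_fraction must be in (0, 1)")
    for chrom, length in chrom_lengths.items():
        if length < 10_000:
            raise ValueError(f"{chrom}: chromosomes must be at least 10 kb")
    rng = np.random.default_rng(seed)
    genome = {
        chrom: _random_sequence(rng, length, gc_fraction)
        for chrom, length in chrom_lengths.items()
    }
    chroms = list(chrom_lengths)
    lengths = np.array([chrom_lengths[c] for c in chroms], dtype=float)
    weights = lengths / lengths.sum()
    genes: list[GeneModel] = []
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    for gi in range(n_genes):
        n_codons = int(rng.integers(gene_codons[0], gene_codons[1] + 1))
        cds_seq = synthesize_cds(rng, n_codons)
        strand = "+" if gi % 2 == 0 else "-"
        placed = False
        for _ in range(max_tries):
            chrom = chroms[rng.choice(len(chroms), p=weights)]
            limit = chrom_lengths[chrom] - len(cds_seq)
            if limit <= 0:
                continue
            start = int(rng.integers(0, limit))
            end = start + len(cds_seq)
            if any(s < end and start < e for s, e in occupied[chrom]):
                continue
            genes.append(
                place_gene(genome, chrom, start, cds_seq, strand, f"gene{gi + 1:04d}")
            )
            occupied[chrom].append((start, end))
            placed = True
            break
        if not placed:
            raise GenePlacementError(
                f"could not place gene {gi + 1} of {n_genes} after {max_tries} tries"
            )
    genes.sort(key=lambda g: (g.chrom, g.start))
    return genome, genes


def apply_variants_to_genome(
    genome: Mapping[str, str], variants: Iterable[Variant]
) -> dict[str, str]:
    """Apply VCF-style variants to a genome, returning the mutated copy.

    Variants on one chromosome must not overlap; REF alleles are checked
    against the genome.  Applied right-to-left so coordinates stay valid.
    """
    out = {c: s for c, s in genome.items()}
    per_chrom: dict[str, list[Variant]] = {}
    for v in variants:
        per_chrom.setdefault(v.chrom, []).append(v)
    for chrom, vs in per_chrom.items():
        vs.sort(key=lambda v: v.pos, reverse=True)
        for later, earlier in zip(vs, vs[1:]):
            if earlier.pos + len(earlier.ref) > later.pos:
                raise ValueError(
                    f"overlapping variants at {chrom}:{earlier.pos} and "
                    f"{chrom}:{later.pos}"
                )
        seq = out[chrom]
        for v in vs:
            i = v.pos - 1
            if seq[i : i + len(v.ref)] != v.ref:
                raise ValueError(
                    f"REF mismatch at {chrom}:{v.pos}: expected {v.ref!r}, "
                    f"found {seq[i:i + len(v.ref)]!r}"
                )
            seq = seq[:i] + v.alt + seq[i + len(v.ref):]
        out[chrom] = seq
    return out
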