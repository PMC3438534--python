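"""A complete, seeded simulation scenario: the default study conditions.

The scenario emulates the comparison of a mosaic laboratory strain against
the reference genome of its major ancestor, at desk scale:

* a 1.2 Mb reference over three chromosomes with random protein-coding
  genes, plus five dedicated marker genes carrying classical auxotrophic
  lesion types (nonsense, frameshift, neutralizing frameshift pair);
* a sample genome that is reference-like over ~85% of its length
  (background 0.2 SNV/kb, well below the 0.5 SNV/kb identity threshold)
  and carries five divergent ancestry blocks — four of moderate density
  (2–5 SNV/kb) and one high (9–12 SNV/kb) — spanning 175 kb, i.e. 14.6%
  of the genome;
* four callsets (two platforms x two mappers), each contaminated with
  independent false positives (0.05/kb, ~60 per callset) and false
  negatives (2%);
* tiling-array-like calls with +/-2 bp jitter, 50% sensitivity and noise;
* a second, related strain sharing one divergent block identically
  (for ancestry-sharing attribution).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from mosaicstrain.genes import GeneModel
from mosaicstrain.mosaic import ArrayCall
from mosaicstrain.simulate.callsim import ErrorModel, simulate_array_calls, simulate_callsets
from mosaicstrain.simulate.genome import generate_reference, place_gene, synthesize_cds
from mosaicstrain.simulate.markers import MarkerSpec, plant_marker_mutations
from mosaicstrain.simulate.mosaic_sim import BlockSpec, MosaicTruth, plant_mosaic
from mosaicstrain.variants import Callset, Variant

__all__ = ["ScenarioConfig", "Scenario", "build_scenario", "DEFAULT_BLOCKS"]

DEFAULT_CHROMS = {"chrI": 500_000, "chrII": 400_000, "chrIII": 300_000}

# Divergent ancestry blocks: 175 kb of 1.2 Mb = 14.6% non-reference.
# Densities fall in the two empirical divergence classes (2-5 and 9-12
# SNV/kb); every block exceeds the 15 kb reporting threshold.
DEFAULT_BLOCKS = (
    BlockSpec("chrI", 100_000, 140_000, 3.0, "donorA"),
    BlockSpec("chrI", 300_000, 330_000, 10.0, "donorB"),
    BlockSpec("chrII", 50_000, 90_000, 4.0, "donorA"),
    BlockSpec("chrII", 200_000, 220_000, 2.5, "donorC"),
    BlockSpec("chrIII", 150_000, 195_000, 3.5, "donorA"),
)

# Marker genes: (gene id, strand, codon overrides, T-free stretch, spec).
# Codon overrides pin the residues named by the classical allele notation:
# GAA = glu, AAG = lys, GGA = gly, GCA = ala.
_MARKER_GENES = (
    ("mkADE", "+", {64: "GAA"}, None, MarkerSpec("mkADE", "nonsense", (64,))),
    ("mkTRP", "-", {83: "GAA"}, None, MarkerSpec("mkTRP", "nonsense", (83,))),
    # the codon after a frameshift site is pinned too, so the single-base
    # deletion has a unique left-aligned representation
    ("mkCAN", "+", {47: "AAG", 48: "CAA"}, None, MarkerSpec("mkCAN", "frameshift", (47,))),
    ("mkLEU", "-", {83: "GGA", 84: "CGT"}, None, MarkerSpec("mkLEU", "frameshift", (83,))),
    (
        "mkHIS",
        "+",
        {70: "GCA", 105: "CCA", 106: "GAA"},
        (69, 107),
        MarkerSpec("mkHIS", "neutralizing_pair", (70, 106)),
    ),
)
_MARKER_CODONS = 150
_MARKER_SPACING = 2_000
_MARKER_REGION_START = 450_000  # gene-free zone reserved on chrI


@dataclass(frozen=True)
class ScenarioConfig:
    seed: int = 0
    chrom_lengths: Mapping[str, int] = field(default_factory=lambda: dict(DEFAULT_CHROMS))
    n_background_genes: int = 30
    gc_fraction: float = 0.38
    background_density: float = 0.2
    blocks: tuple[BlockSpec, ...] = DEFAULT_BLOCKS
    platforms: tuple[str, ...] = ("pyro", "illumina")
    mappers: tuple[str, ...] = ("mapperA", "mapperB")
    fp_rate: float = 0.05
    fn_rate: float = 0.02
    array_jitter: int = 2
    array_sensitivity: float = 0.5
    array_noise_calls: int = 50
    exact_counts: bool = True


@dataclass
class Scenario:
    config: ScenarioConfig
    reference: dict[str, str]
    genes: list[GeneModel]
    marker_variants: list[Variant]
    mosaic: MosaicTruth
    truth: Callset  # mosaic SNVs + marker mutations
    callsets: dict[tuple[str, str], Callset]
    array_calls: list[ArrayCall]
    other_truth: Callset  # related strain vs the same reference
    shared_block: BlockSpec

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return dict(self.config.chrom_lengths)


def _background_blocks(
    config: ScenarioConfig,
) -> list[BlockSpec]:
    """Reference-like background: everything outside the divergent blocks."""
    out: list[BlockSpec] = []
    for chrom, length in config.chrom_lengths.items():
        cursor = 0
        for b in sorted(
            (b for b in config.blocks if b.chrom == chrom), key=lambda b: b.start
        ):
            if b.start > cursor:
                out.append(
                    BlockSpec(chrom, cursor, b.start, config.background_density,
                              "reference-like")
                )
            cursor = b.end
        if cursor < length:
            out.append(
                BlockSpec(chrom, cursor, length, config.background_density,
                          "reference-like")
            )
    return out


def build_scenario(config: ScenarioConfig | None = None) -> Scenario:
    """Deterministically build the full scenario for a config/seed."""
    config = config or ScenarioConfig()
    seed = config.seed
    rng = np.random.default_rng(seed + 1)

    # Reference: background genes kept off the reserved marker zone by
    # generating first, then dropping collisions (rare) before placing the
    # marker genes at fixed positions.
    reference, genes = generate_reference(
        seed=seed,
        chrom_lengths=config.chrom_lengths,
        gc_fraction=config.gc_fraction,
        n_genes=config.n_background_genes,
    )
    zone_end = _MARKER_REGION_START + len(_MARKER_GENES) * _MARKER_SPACING
    genes = [
        g
        for g in genes
        if not (
            g.chrom == "chrI"
            and g.start < zone_end
            and g.end > _MARKER_REGION_START
        )
    ]
    specs: list[MarkerSpec] = []
    for i, (gene_id, strand, overrides, t_free, spec) in enumerate(_MARKER_GENES):
        cds_seq = synthesize_cds(
            rng, _MARKER_CODONS, codon_overrides=overrides, t_free_codon_range=t_free
        )
        start = _MARKER_REGION_START + i * _MARKER_SPACING
        genes.append(place_gene(reference, "chrI", start, cds_seq, strand, gene_id))
        specs.append(spec)
    genes.sort(key=lambda g: (g.chrom, g.start))

    marker_variants = plant_marker_mutations(reference, genes, specs, seed=seed + 2)
    forbidden = {
        (v.chrom, p)
        for v in marker_variants
        for p in range(v.pos - 1, v.pos - 1 + len(v.ref))
    }

    blocks = list(config.blocks) + _background_blocks(config)
    mosaic = plant_mosaic(
        reference,
        blocks,
        seed=seed + 3,
        exact=config.exact_counts,
        forbidden=forbidden,
    )
    truth = Callset(
        "truth", variants=tuple(list(mosaic.truth) + marker_variants)
    )

    error_models = {
        (p, m): ErrorModel(
            fp_rate=config.fp_rate,
            fn_rate=config.fn_rate,
            seed=seed + 10 + 7 * i,
        )
        for i, (p, m) in enumerate(
            (p, m) for p in config.platforms for m in config.mappers
        )
    }
    callsets = simulate_callsets(
        truth, reference, config.platforms, config.mappers, error_models
    )

    array_calls = simulate_array_calls(
        truth,
        config.chrom_lengths,
        jitter_max_bp=config.array_jitter,
        sensitivity=config.array_sensitivity,
        noise_calls=config.array_noise_calls,
        seed=seed + 4,
        strain="sample",
    )

    # Related strain: identical haplotype inside the first divergent block
    # (shared ancestry), private divergence elsewhere.
    shared_block = config.blocks[0]
    shared = [
        v
        for v in mosaic.truth
        if v.chrom == shared_block.chrom
        and shared_block.start < v.pos <= shared_block.end
    ]
    private_block = BlockSpec("chrIII", 30_000, 60_000, 3.0, "other-private")
    other_private = plant_mosaic(
        reference, [private_block], seed=seed + 5, exact=config.exact_counts
    )
    other_truth = Callset(
        "relative", variants=tuple(shared + list(other_private.truth))
    )

    return Scenario(
        config=config,
        reference=reference,
        genes=genes,
        marker_variants=marker_variants,
        mosaic=mosaic,
        truth=truth,
        callsets=callsets,
        array_calls=array_calls,
        other_truth=other_truth,
        shared_block=shared_block,
    )
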