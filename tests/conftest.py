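"""Shared fixtures: small genomes, toy marker genes, the default scenario."""

from __future__ import annotations

import numpy as np
import pytest

from mosaicstrain.genes import GeneModel
from mosaicstrain.simulate import (
    ScenarioConfig,
    build_scenario,
    place_gene,
    synthesize_cds,
)


@pytest.fixture(scope="session")
def scenario():
    """The default synthetic scenario at seed 0 (built once per session)."""
    return build_scenario(ScenarioConfig(seed=0))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_toy_genome(
    rng: np.random.Generator,
    chrom_len: int = 20_000,
    chrom: str = "chrT",
) -> dict[str, str]:
    bases = "ACGT"
    return {chrom: "".join(bases[i] for i in rng.integers(0, 4, size=chrom_len))}


def make_toy_gene(
    rng: np.random.Generator,
    genome: dict[str, str],
    n_codons: int = 150,
    strand: str = "+",
    start: int = 1_000,
    codon_overrides: dict[int, str] | None = None,
    t_free_codon_range: tuple[int, int] | None = None,
    gene_id: str = "toy",
    chrom: str = "chrT",
) -> GeneModel:
    cds = synthesize_cds(
        rng, n_codons, codon_overrides=codon_overrides,
        t_free_codon_range=t_free_codon_range,
    )
    return place_gene(genome, chrom, start, cds, strand, gene_id)
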