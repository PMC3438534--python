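"""Effect annotation: CDS extraction, variant application, classification.

The independent oracle applies variants at the *genome* level (plain string
splicing), re-extracts the (length-adjusted) gene region and translates —
a different code path from the CDS-space application with its base-level
alignment map.
"""

from __future__ import annotations

import numpy as np
import pytest
from Bio.Seq import Seq

from mosaicstrain.effects import (
    EffectRecord,
    aggregate,
    apply_variants,
    classify_effects,
    extract_cds,
    translate,
)
from mosaicstrain.genes import GeneModel
from mosaicstrain.simulate import MarkerSpec, plant_marker_mutations, synthesize_cds
from mosaicstrain.variants import Variant, normalize
from tests.conftest import make_toy_gene, make_toy_genome


def oracle_mutant_protein(
    genome: dict[str, str], gene: GeneModel, variants: list[Variant]
) -> str:
    """Apply variants by genome-level splicing, then re-extract and translate."""
    (s, e), = gene.cds  # single-exon oracle
    seq = genome[gene.chrom]
    delta = 0
    for v in sorted(variants, key=lambda v: v.pos, reverse=True):
        i = v.pos - 1
        assert seq[i : i + len(v.ref)] == v.ref
        seq = seq[:i] + v.alt + seq[i + len(v.ref):]
        if s <= i < e:
            delta += len(v.alt) - len(v.ref)
    region = seq[s : e + delta]
    if gene.strand == "-":
        region = str(Seq(region).reverse_complement())
    return translate(region)


class TestExtractCds:
    def test_plus_strand_is_substring(self, rng):
        genome = make_toy_genome(rng)
        gene = make_toy_gene(rng, genome, strand="+")
        (s, e), = gene.cds
        assert extract_cds(gene, genome) == genome["chrT"][s:e]

    def test_minus_strand_is_reverse_complement(self, rng):
        genome = make_toy_genome(rng)
        gene = make_toy_gene(rng, genome, strand="-")
        (s, e), = gene.cds
        expected = str(Seq(genome["chrT"][s:e]).reverse_complement())
        assert extract_cds(gene, genome) == expected

    def test_two_exon_gene_splices(self, rng):
        genome = make_toy_genome(rng)
        gene = GeneModel("g2", "chrT", "+", ((100, 160), (300, 345)))
        expected = genome["chrT"][100:160] + genome["chrT"][300:345]
        assert extract_cds(gene, genome) == expected

    def test_out_of_range_raises(self, rng):
        genome = make_toy_genome(rng, chrom_len=10_000)
        gene = GeneModel("g", "chrT", "+", ((9_990, 10_050),))
        with pytest.raises(IndexError):
            extract_cds(gene, genome)


class TestApplyVariants:
    def test_empty_list_is_identity(self, rng):
        genome = make_toy_genome(rng)
        gene = make_toy_gene(rng, genome)
        cds = extract_cds(gene, genome)
        assert apply_variants(cds, gene, []) == cds

    def test_single_snp_changes_one_base(self, rng):
        genome = make_toy_genome(rng)
        gene = make_toy_gene(rng, genome, strand="+", start=1000)
        cds = extract_cds(gene, genome)
        pos = 1000 + 30 + 1  # 1-based, inside CDS
        ref_base = genome["chrT"][pos - 1]
        alt = "A" if ref_base != "A" else "C"
        out = apply_variants(cds, gene, [Variant("chrT", pos, ref_base, alt)])
        diffs = [i for i, (a, b) in enumerate(zip(cds, out)) if a != b]
        assert diffs == [30]

    def test_net_length_change(self, rng):
        genome = make_toy_genome(rng)
        gene = make_toy_gene(rng, genome, strand="+", start=1000)
        cds = extract_cds(gene, genome)
        ins = Variant("chrT", 1010, genome["chrT"][1009], genome["chrT"][1009] + "A")
        dele = Variant("chrT", 1100, genome["chrT"][1099:1101], genome["chrT"][1099])
        out = apply_variants(cds, gene, [ins, dele])
        assert len(out) == len(cds)  # +1 -1

    def test_overlapping_variants_raise(self, rng):
        genome = make_toy_genome(rng)
        gene = make_toy_gene(rng, genome, strand="+", start=1000)
        cds = extract_cds(gene, genome)
        seq = genome["chrT"]
        a = Variant("chrT", 1010, seq[1009:1012], seq[1009])
        b = Variant("chrT", 1011, seq[1010], "A" if seq[1010] != "A" else "C")
        with pytest.raises(ValueError, match="overlap"):
            apply_variants(cds, gene, [a, b])


class TestMarkerAlleles:
    """The classical auxotrophic lesion notations round-trip through
    planting + annotation, on both strands."""

    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_nonsense_glu64stop(self, rng, strand):
        genome = make_toy_genome(rng)
        gene = make_toy_gene(
            rng, genome, strand=strand, codon_overrides={64: "GAA"}, gene_id="ade"
        )
        variants = plant_marker_mutations(
            genome, [gene], [MarkerSpec("ade", "nonsense", (64,))], seed=1
        )
        rec = classify_effects(gene, genome, variants)
        assert rec.nonsense_label == "glu64STOP"
        assert rec.altered

    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_nonsense_glu83stop(self, rng, strand):
        genome = make_toy_genome(rng)
        gene = make_toy_gene(
            rng, genome, strand=strand, codon_overrides={83: "GAA"}, gene_id="trp"
        )
        variants = plant_marker_mutations(
            genome, [gene], [MarkerSpec("trp", "nonsense", (83,))], seed=1
        )
        rec = classify_effects(gene, genome, variants)
        assert rec.nonsense_label == "glu83STOP"

    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_frameshift_lys47(self, rng, strand):
        genome = make_toy_genome(rng)
        gene = make_toy_gene(
            rng, genome, strand=strand,
            codon_overrides={47: "AAG", 48: "CAA"}, gene_id="can",
        )
        variants = plant_marker_mutations(
            genome, [gene], [MarkerSpec("can", "frameshift", (47,))], seed=1
        )
        rec = classify_effects(gene, genome, variants)
        assert rec.frameshift_labels == ["lys47"]
        assert not rec.frame_restored

    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_frameshift_gly83(self, rng, strand):
        genome = make_toy_genome(rng)
        gene = make_toy_gene(
            rng, genome, strand=strand,
            codon_overrides={83: "GGA", 84: "CGT"}, gene_id="leu",
        )
        variants = plant_marker_mutations(
            genome, [gene], [MarkerSpec("leu", "frameshift", (83,))], seed=1
        )
        rec = classify_effects(gene, genome, variants)
        assert rec.frameshift_labels == ["gly83"]

    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_neutralizing_pair_ala70_glu106(self, rng, strand):
        genome = make_toy_genome(rng)
        gene = make_toy_gene(
            rng, genome, strand=strand,
            codon_overrides={70: "GCA", 105: "CCA", 106: "GAA"},
            t_free_codon_range=(69, 107), gene_id="his",
        )
        variants = plant_marker_mutations(
            genome, [gene],
            [MarkerSpec("his", "neutralizing_pair", (70, 106))], seed=1,
        )
        rec = classify_effects(gene, genome, variants)
        assert sorted(rec.frameshift_labels) == ["ala70", "glu106"]
        assert rec.frame_restored
        # frame restored without new stops: equal protein lengths,
        # identical outside the shifted segment
        assert len(rec.mut_protein) == len(rec.ref_protein)
        assert rec.ref_protein[:68] == rec.mut_protein[:68]
        assert rec.ref_protein[107:] == rec.mut_protein[107:]

    def test_missense_zero_plants_nothing(self, rng):
        genome = make_toy_genome(rng)
        gene = make_toy_gene(rng, genome, gene_id="g")
        assert plant_marker_mutations(
            genome, [gene], [MarkerSpec("g", "missense_n", ())], seed=1
        ) == []

    def test_nonsense_at_natural_stop_rejected(self, rng):
        from mosaicstrain.simulate.markers import MarkerPlantingError

        genome = make_toy_genome(rng)
        gene = make_toy_gene(rng, genome, n_codons=100, gene_id="g")
        with pytest.raises(MarkerPlantingError):
            plant_marker_mutations(
                genome, [gene], [MarkerSpec("g", "nonsense", (100,))], seed=1
            )


class TestAgainstOracle:
    def test_random_genes_match_brute_force(self):
        """Mutant protein from the alignment-map path equals the oracle's
        genome-splice-and-retranslate on hundreds of random genes with
        random substitution/indel cocktails."""
        rng = np.random.default_rng(2024)
        n_checked = 0
        for trial in range(300):
            genome = make_toy_genome(rng, chrom_len=3000)
            n_codons = int(rng.integers(50, 150))
            strand = "+" if rng.random() < 0.5 else "-"
            gene = make_toy_gene(
                rng, genome, n_codons=n_codons, strand=strand, start=500,
                gene_id=f"g{trial}",
            )
            (s, e), = gene.cds
            variants = []
            taken: set[int] = set()
            for _ in range(int(rng.integers(1, 4))):
                p0 = int(rng.integers(s + 3, e - 6))
                if any(abs(p0 - t) < 4 for t in taken):
                    continue
                taken.add(p0)
                seq = genome["chrT"]
                kind = rng.random()
                if kind < 0.5:  # SNV
                    ref_b = seq[p0]
                    alt_b = "ACGT"[int(rng.integers(4))]
                    if alt_b == ref_b:
                        continue
                    v = Variant("chrT", p0 + 1, ref_b, alt_b)
                elif kind < 0.75:  # 1 bp deletion
                    v = Variant("chrT", p0 + 1, seq[p0 : p0 + 2], seq[p0])
                else:  # 1 bp insertion
                    ins = "ACGT"[int(rng.integers(4))]
                    v = Variant("chrT", p0 + 1, seq[p0], seq[p0] + ins)
                variants.append(v)
            if not variants:
                continue
            rec = classify_effects(gene, genome, variants)
            expected = oracle_mutant_protein(genome, gene, variants)
            assert rec.mut_protein == expected, (trial, variants)
            n_checked += 1
        assert n_checked > 250


class TestAggregate:
    def test_zero_variants_all_zero(self, rng):
        genome = make_toy_genome(rng)
        genes = [make_toy_gene(rng, genome, start=1000 + 600 * i, gene_id=f"g{i}")
                 for i in range(3)]
        records = [classify_effects(g, genome, []) for g in genes]
        summary = aggregate(records)
        assert summary.n_proteins_altered == 0
        assert summary.n_with_1_2_residues == summary.n_with_3plus_residues == 0

    def test_synonymous_only_not_altered(self, rng):
        genome = make_toy_genome(rng)
        # CTT -> CTC is leu -> leu
        gene = make_toy_gene(rng, genome, codon_overrides={10: "CTT"}, gene_id="syn")
        (s, _), = gene.cds
        pos0 = s + 29 if gene.strand == "+" else None
        assert gene.strand == "+"
        v = Variant("chrT", pos0 + 1, "T", "C")
        assert genome["chrT"][pos0] == "T"
        rec = classify_effects(gene, genome, [v])
        assert rec.n_changed_residues == 0
        assert not rec.altered
        assert aggregate([rec]).n_proteins_altered == 0

    def test_planted_plan_recovered(self, rng):
        """10 nonsense + 5 neutralizing pairs + 20 single-substitution genes
        aggregate exactly to plan."""
        genome = make_toy_genome(rng, chrom_len=40_000)
        genes, specs = [], []
        pos = 200
        for i in range(10):
            gid = f"non{i}"
            genes.append(make_toy_gene(rng, genome, n_codons=120, start=pos,
                                       codon_overrides={30: "GAA"}, gene_id=gid))
            specs.append(MarkerSpec(gid, "nonsense", (30,)))
            pos += 500
        for i in range(5):
            gid = f"neu{i}"
            genes.append(make_toy_gene(
                rng, genome, n_codons=120, start=pos,
                codon_overrides={40: "GCA", 59: "CCA", 60: "GAA"},
                t_free_codon_range=(39, 61), gene_id=gid,
            ))
            specs.append(MarkerSpec(gid, "neutralizing_pair", (40, 60)))
            pos += 500
        for i in range(20):
            gid = f"mis{i}"
            genes.append(make_toy_gene(rng, genome, n_codons=120, start=pos,
                                       gene_id=gid))
            specs.append(MarkerSpec(gid, "missense_n", (50,)))
            pos += 500
        variants = plant_marker_mutations(genome, genes, specs, seed=5)
        records = [classify_effects(g, genome, variants) for g in genes]
        summary = aggregate(records)
        assert summary.n_nonsense == 10
        assert summary.genes_with_neutralizing_pairs == sorted(
            f"neu{i}" for i in range(5)
        )
        assert summary.n_with_1_2_residues == 20
        assert summary.n_with_3plus_residues == 0
        assert summary.n_proteins_altered == 35
        assert summary.n_genes_with_small_indels == 5  # the neutralizing pairs

    def test_two_substitutions_counted_in_1_2_class(self, rng):
        genome = make_toy_genome(rng)
        gene = make_toy_gene(rng, genome, gene_id="g")
        variants = plant_marker_mutations(
            genome, [gene], [MarkerSpec("g", "missense_n", (20, 40))], seed=2
        )
        rec = classify_effects(gene, genome, variants)
        assert rec.n_changed_residues == 2
        summary = aggregate([rec])
        assert summary.n_with_1_2_residues == 1
        assert summary.n_with_3plus_residues == 0
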