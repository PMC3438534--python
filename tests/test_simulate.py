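"""Synthetic-data generator: determinism, truth round-trips, error models."""

from __future__ import annotations

import hashlib

import numpy as np
import pytest

from mosaicstrain.effects import extract_cds, translate
from mosaicstrain.genes import read_fasta, read_gff3, write_fasta, write_gff3
from mosaicstrain.mosaic import window_density
from mosaicstrain.simulate import (
    BlockSpec,
    ErrorModel,
    apply_variants_to_genome,
    build_scenario,
    generate_reference,
    plant_mosaic,
    simulate_array_calls,
    simulate_callsets,
    simulate_paired_reads,
)
from mosaicstrain.simulate.genome import GenePlacementError
from mosaicstrain.variants import Callset, Variant


def digest(genome: dict[str, str]) -> str:
    h = hashlib.sha256()
    for chrom in sorted(genome):
        h.update(chrom.encode())
        h.update(genome[chrom].encode())
    return h.hexdigest()


class TestGenerateReference:
    def test_genes_translatable_without_internal_stops(self):
        genome, genes = generate_reference(1, {"chr1": 100_000}, n_genes=10)
        assert len(genes) == 10
        for g in genes:
            cds = extract_cds(g, genome)
            assert len(cds) % 3 == 0
            assert cds.startswith("ATG")
            protein = translate(cds)
            assert protein.endswith("*")
            assert "*" not in protein[:-1]

    def test_same_seed_byte_identical(self, tmp_path):
        outputs = []
        for run in ("a", "b"):
            genome, genes = generate_reference(7, {"chr1": 50_000}, n_genes=5)
            fa, gff = tmp_path / f"{run}.fa", tmp_path / f"{run}.gff3"
            write_fasta(genome, fa)
            write_gff3(genes, gff)
            outputs.append((fa.read_bytes(), gff.read_bytes()))
        assert outputs[0] == outputs[1]

    def test_different_seeds_differ(self):
        g1, _ = generate_reference(1, {"chr1": 50_000}, n_genes=2)
        g2, _ = generate_reference(2, {"chr1": 50_000}, n_genes=2)
        assert digest(g1) != digest(g2)

    def test_gff_fasta_round_trip(self, tmp_path):
        genome, genes = generate_reference(3, {"chr1": 60_000}, n_genes=6)
        write_fasta(genome, tmp_path / "r.fa")
        write_gff3(genes, tmp_path / "r.gff3")
        genome2 = read_fasta(tmp_path / "r.fa")
        genes2 = read_gff3(tmp_path / "r.gff3")
        assert genome2 == genome
        assert [(g.gene_id, g.chrom, g.strand, g.cds) for g in genes2] == [
            (g.gene_id, g.chrom, g.strand, g.cds) for g in genes
        ]

    def test_impossible_placement_raises(self):
        with pytest.raises(GenePlacementError):
            generate_reference(1, {"chr1": 10_000}, n_genes=50,
                               gene_codons=(380, 400))

    def test_bad_gc_rejected(self):
        with pytest.raises(ValueError):
            generate_reference(1, {"chr1": 50_000}, gc_fraction=1.2)


class TestPlantMosaic:
    def _genome(self, seed=1, length=100_000):
        genome, _ = generate_reference(seed, {"chr1": length}, n_genes=2)
        return genome

    def test_zero_density_block_empty_truth(self):
        genome = self._genome()
        planted = plant_mosaic(genome, [BlockSpec("chr1", 0, 50_000, 0.0)], seed=1)
        assert len(planted.truth) == 0
        assert planted.sample_genome == genome

    def test_exact_mode_exact_count(self):
        genome = self._genome()
        planted = plant_mosaic(genome, [BlockSpec("chr1", 0, 100_000, 3.0)], seed=1)
        assert len(planted.truth) == 300
        assert all(1 <= v.pos <= 100_000 for v in planted.truth)

    def test_round_trip_reproduces_sample(self):
        genome = self._genome()
        planted = plant_mosaic(
            genome, [BlockSpec("chr1", 10_000, 60_000, 5.0)], seed=2
        )
        rebuilt = apply_variants_to_genome(genome, planted.truth)
        assert rebuilt == planted.sample_genome

    def test_poisson_mode_mean_within_3se(self):
        genome = self._genome()
        counts = [
            len(plant_mosaic(genome, [BlockSpec("chr1", 0, 100_000, 3.0)],
                             seed=s, exact=False).truth)
            for s in range(50)
        ]
        se = np.sqrt(300) / np.sqrt(50)
        assert abs(np.mean(counts) - 300) <= 3 * se

    def test_overlapping_blocks_rejected(self):
        genome = self._genome()
        with pytest.raises(ValueError, match="overlap"):
            plant_mosaic(
                genome,
                [BlockSpec("chr1", 0, 30_000, 1.0), BlockSpec("chr1", 20_000, 50_000, 1.0)],
                seed=1,
            )

    def test_window_density_recovers_planted_density(self):
        genome = self._genome()
        planted = plant_mosaic(genome, [BlockSpec("chr1", 0, 100_000, 3.0)], seed=3)
        track = window_density(planted.truth, {"chr1": 100_000})
        assert track.total_snvs == 300
        mean_density = np.mean([w.density for w in track.windows])
        assert mean_density == pytest.approx(3.0, abs=1 / 5.0)

    def test_determinism(self):
        genome = self._genome()
        a = plant_mosaic(genome, [BlockSpec("chr1", 0, 50_000, 2.0)], seed=4)
        b = plant_mosaic(genome, [BlockSpec("chr1", 0, 50_000, 2.0)], seed=4)
        assert a.truth.variants == b.truth.variants
        assert digest(a.sample_genome) == digest(b.sample_genome)


class TestSimulateCallsets:
    def _truth(self, genome, n=500, seed=6):
        planted = plant_mosaic(
            genome, [BlockSpec("chr1", 0, len(genome["chr1"]), n / (len(genome["chr1"]) / 1000))],
            seed=seed,
        )
        return planted.truth

    def test_no_errors_equals_truth(self):
        genome, _ = generate_reference(1, {"chr1": 200_000}, n_genes=2)
        truth = self._truth(genome)
        models = {("p", "m"): ErrorModel(fp_rate=0.0, fn_rate=0.0, seed=1)}
        out = simulate_callsets(truth, genome, ["p"], ["m"], models)
        assert out[("p", "m")].keys() == truth.keys()

    def test_fn_rate_binomial_expectation(self):
        genome, _ = generate_reference(1, {"chr1": 500_000}, n_genes=2)
        truth = self._truth(genome, n=1000)
        n = len(truth)
        sizes = []
        for rep in range(20):
            models = {("p", "m"): ErrorModel(fp_rate=0.0, fn_rate=0.1, seed=rep)}
            out = simulate_callsets(truth, genome, ["p"], ["m"], models)
            sizes.append(len(out[("p", "m")]))
        se = np.sqrt(n * 0.1 * 0.9) / np.sqrt(20)
        assert abs(np.mean(sizes) - 0.9 * n) <= 3 * se

    def test_independent_fp_rarely_shared(self):
        genome, _ = generate_reference(2, {"chr1": 1_000_000}, n_genes=2)
        truth = Callset("empty")
        models = {
            ("a", "m"): ErrorModel(fp_rate=0.05, fn_rate=0.0, seed=21),
            ("b", "m"): ErrorModel(fp_rate=0.05, fn_rate=0.0, seed=22),
        }
        out = simulate_callsets(truth, genome, ["a", "b"], ["m"], models)
        shared = out[("a", "m")].keys() & out[("b", "m")].keys()
        # expectation ~ 50*50/1e6 * 1/3 << 1
        assert len(shared) <= 1

    def test_fp_never_on_truth_positions(self):
        genome, _ = generate_reference(3, {"chr1": 100_000}, n_genes=2)
        truth = self._truth(genome, n=200)
        models = {("p", "m"): ErrorModel(fp_rate=0.5, fn_rate=0.0, seed=5)}
        out = simulate_callsets(truth, genome, ["p"], ["m"], models)
        cs = out[("p", "m")]
        truth_pos = {(v.chrom, v.pos) for v in truth}
        fps = [v for v in cs if v.key() not in truth.keys()]
        assert all((v.chrom, v.pos) not in truth_pos for v in fps)


class TestSimulateReads:
    def test_pair_count_from_coverage(self):
        genome, _ = generate_reference(1, {"chr1": 100_000}, n_genes=2)
        pairs = list(simulate_paired_reads(genome, 400, 2000, 4000, 10.0, seed=1))
        assert len(pairs) == 1250  # ceil(10 * 100000 / 800)

    def test_zero_coverage_zero_reads(self):
        genome, _ = generate_reference(1, {"chr1": 50_000}, n_genes=2)
        assert list(simulate_paired_reads(genome, coverage=0.0, seed=1)) == []

    def test_reads_map_exactly(self):
        from Bio.Seq import Seq

        genome, _ = generate_reference(4, {"chr1": 60_000}, n_genes=2)
        seq = genome["chr1"]
        pairs = list(simulate_paired_reads(genome, 100, 1000, 2000, 0.5, seed=2))
        assert pairs
        for r1, r2 in pairs:
            assert r1.sequence in seq
            assert str(Seq(r2.sequence).reverse_complement()) in seq

    def test_read_longer_than_chromosome_rejected(self):
        genome = {"chr1": "ACGT" * 100}
        with pytest.raises(ValueError, match="read_length"):
            list(simulate_paired_reads(genome, read_length=2000, coverage=1.0, seed=1))


class TestSimulateArrayCalls:
    def _truth(self, n=1000, length=1_000_000, seed=30):
        genome, _ = generate_reference(seed, {"chr1": length}, n_genes=2)
        return plant_mosaic(
            genome, [BlockSpec("chr1", 0, length, n / (length / 1000))], seed=seed
        ).truth

    def test_perfect_array_equals_truth_positions(self):
        truth = self._truth(n=200, length=200_000)
        calls = simulate_array_calls(truth, {"chr1": 200_000}, 0, 1.0, 0, seed=1)
        assert [c.pos for c in calls] == [v.pos for v in truth]

    def test_jitter_bounded(self):
        truth = self._truth(n=200, length=200_000)
        calls = simulate_array_calls(truth, {"chr1": 200_000}, 2, 1.0, 0, seed=2)
        truth_pos = np.array([v.pos for v in truth])
        for c in calls:
            assert np.min(np.abs(truth_pos - c.pos)) <= 2

    def test_sensitivity_mean_within_3se(self):
        truth = self._truth(n=1000)
        n = len(truth)
        detected = []
        for rep in range(20):
            calls = simulate_array_calls(
                truth, {"chr1": 1_000_000}, 2, 0.5, 0, seed=rep
            )
            detected.append(len(calls))
        se = np.sqrt(n * 0.25) / np.sqrt(20)
        assert abs(np.mean(detected) - 0.5 * n) <= 3 * se


class TestScenario:
    def test_truth_includes_markers_and_blocks(self, scenario):
        marker_keys = {v.key() for v in scenario.marker_variants}
        assert marker_keys <= scenario.truth.keys()
        assert len(scenario.callsets) == 4

    def test_scenario_deterministic(self, scenario):
        again = build_scenario(scenario.config)
        assert again.truth.variants == scenario.truth.variants
        assert digest(again.reference) == digest(scenario.reference)
        for key in scenario.callsets:
            assert again.callsets[key].variants == scenario.callsets[key].variants
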