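"""Self-contained validation experiments.

Each function builds its own synthetic inputs, runs one method end to end
and returns plain numbers.  They back both the acceptance test suite and
``scripts/acceptance.py``; all randomness is seeded.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np

from mosaicstrain import consensus as cons
from mosaicstrain import mosaic as mos
from mosaicstrain.effects import classify_effects, translate
from mosaicstrain.mosaic import array_overlap, segment_clusters, window_density
from mosaicstrain.reads_qc import QCParams, Read, qc_pipeline
from mosaicstrain.simulate import (
    BlockSpec,
    ErrorModel,
    MarkerSpec,
    generate_reference,
    plant_marker_mutations,
    plant_mosaic,
    place_gene,
    simulate_array_calls,
    simulate_callsets,
    simulate_paired_reads,
    synthesize_cds,
)
from mosaicstrain.variants import Callset, Variant

__all__ = [
    "printed_counts_accounting",
    "marker_notation_demo",
    "effects_oracle_agreement",
    "mosaic_recovery_experiment",
    "fp_elimination_experiment",
    "readqc_experiment",
    "array_overlap_experiment",
]


# --------------------------------------------------------------------------
# consensus accounting on published-scale counts
# --------------------------------------------------------------------------

def _snv_set(name: str, n: int, shared_with: Sequence[int],
             unique_start: int, platform: str = "", mapper: str = "") -> Callset:
    """A callset of n distinct synthetic SNVs: the given shared positions
    plus callset-private positions from ``unique_start`` upward."""
    positions = list(shared_with)
    p = unique_start
    while len(positions) < n:
        positions.append(p)
        p += 1
    return Callset(
        name, platform, mapper,
        tuple(Variant("chr1", q, "A", "T") for q in positions[:n]),
    )


def printed_counts_accounting() -> dict:
    """Recompute the published-scale accounting identities through the
    consensus machinery on synthetic callsets with the same set sizes.

    Two platform callsets of 11 324 and 10 130 calls sharing a 9 073-call
    consensus; per-mapper class tables of 8 471/280/322 and
    8 815/397/370; a cross-mapper SNP overlap of 8 049.
    """
    shared = list(range(1, 9_074))  # 9073 shared positions
    pyro = _snv_set("pyro", 11_324, shared, 20_000_000,
                    platform="pyro", mapper="newbler")
    synth = _snv_set("synth", 10_130, shared, 30_000_000,
                     platform="synth", mapper="newbler")
    _, final = cons.intersect([pyro, synth])
    report = cons.accounting([pyro, synth], {}, final)

    snp_shared = list(range(1, 8_050))  # 8049 shared SNPs
    newbler_snps = _snv_set("newbler", 8_471, snp_shared, 40_000_000,
                            mapper="newbler")
    clc_snps = _snv_set("clc", 8_815, snp_shared, 50_000_000, mapper="clc")
    confirm = cons.cross_confirm(newbler_snps, clc_snps, vclass="SNP")

    def classed(name: str, n_snp: int, n_indel: int, n_mnv: int) -> Callset:
        variants = [Variant("chr1", i + 1, "A", "T") for i in range(n_snp)]
        base = 1_000_000
        variants += [
            Variant("chr1", base + 10 * i, "AT", "A") for i in range(n_indel)
        ]
        variants += [
            Variant("chr1", base * 2 + 10 * i, "AT", "CG") for i in range(n_mnv)
        ]
        return Callset(name, variants=tuple(variants))

    final_classes = classed("consensus", 8_049, 25, 59).by_class()
    newbler_classes = classed("newbler", 8_471, 280, 322).by_class()

    return {
        "platform_consensus_size": report.final_size,
        "eliminated_total": report.eliminated_total,
        "percent_eliminated_of_union": report.percent_eliminated,
        "cross_mapper_confirmed_snps": confirm.confirmed,
        "cross_mapper_percent_of_newbler": confirm.percent_of_a,
        "newbler_only_snps": confirm.a_only,
        "clc_only_snps": confirm.b_only,
        "final_class_sum": sum(
            v for k, v in final_classes.items()
        ),
        "newbler_class_sum": sum(v for v in newbler_classes.values()),
    }


# --------------------------------------------------------------------------
# marker-allele notation + translate-and-diff oracle
# --------------------------------------------------------------------------

def _marker_gene(rng, genome, gene_id, strand, overrides, t_free, start):
    cds = synthesize_cds(rng, 150, codon_overrides=overrides,
                         t_free_codon_range=t_free)
    return place_gene(genome, "chrT", start, cds, strand, gene_id)


def marker_notation_demo(seed: int = 0) -> dict:
    """Plant the five classical auxotrophic lesions in toy genes and
    annotate them; returns the allele strings the annotation produces."""
    rng = np.random.default_rng(seed)
    genome = {"chrT": "".join(rng.choice(list("ACGT"), size=30_000))}
    plan = [
        ("ade2", "+", {64: "GAA"}, None, MarkerSpec("ade2", "nonsense", (64,))),
        ("trp1", "-", {83: "GAA"}, None, MarkerSpec("trp1", "nonsense", (83,))),
        ("can1", "+", {47: "AAG", 48: "CAA"}, None,
         MarkerSpec("can1", "frameshift", (47,))),
        ("leu2", "-", {83: "GGA", 84: "CGT"}, None,
         MarkerSpec("leu2", "frameshift", (83,))),
        ("his3", "+", {70: "GCA", 105: "CCA", 106: "GAA"}, (69, 107),
         MarkerSpec("his3", "neutralizing_pair", (70, 106))),
    ]
    genes, specs = [], []
    for i, (gid, strand, over, t_free, spec) in enumerate(plan):
        genes.append(_marker_gene(rng, genome, gid, strand, over, t_free,
                                  1_000 + 2_000 * i))
        specs.append(spec)
    variants = plant_marker_mutations(genome, genes, specs, seed=seed + 1)
    out = {}
    for g in genes:
        rec = classify_effects(g, genome, variants)
        if rec.nonsense:
            out[g.gene_id] = rec.nonsense_label
        elif rec.frameshifts:
            out[g.gene_id] = " and ".join(rec.frameshift_labels)
        if g.gene_id == "his3":
            out["his3_frame_restored"] = rec.frame_restored
    return out


def effects_oracle_agreement(seed: int = 0, n_genes: int = 1000) -> dict:
    """Annotate random genes with random variant cocktails and compare the
    mutant protein with an independent brute-force oracle (apply variants
    by genome splicing, re-extract, translate)."""
    from Bio.Seq import Seq

    rng = np.random.default_rng(seed)
    agree = total = 0
    for trial in range(n_genes):
        genome = {"chrT": "".join(rng.choice(list("ACGT"), size=2_000))}
        n_codons = int(rng.integers(50, 150))
        strand = "+" if rng.random() < 0.5 else "-"
        cds_seq = synthesize_cds(rng, n_codons)
        gene = place_gene(genome, "chrT", 300, cds_seq, strand, f"g{trial}")
        (s, e), = gene.cds
        variants, taken = [], []
        for _ in range(int(rng.integers(1, 4))):
            p0 = int(rng.integers(s + 3, e - 6))
            if any(abs(p0 - t) < 4 for t in taken):
                continue
            taken.append(p0)
            seq = genome["chrT"]
            kind = rng.random()
            if kind < 0.5:
                alt = "ACGT"[int(rng.integers(4))]
                if alt == seq[p0]:
                    continue
                variants.append(Variant("chrT", p0 + 1, seq[p0], alt))
            elif kind < 0.75:
                variants.append(Variant("chrT", p0 + 1, seq[p0:p0 + 2], seq[p0]))
            else:
                ins = "ACGT"[int(rng.integers(4))]
                variants.append(Variant("chrT", p0 + 1, seq[p0], seq[p0] + ins))
        if not variants:
            continue
        rec = classify_effects(gene, genome, variants)
        # oracle: splice the genome, re-extract the (shifted) region
        seq = genome["chrT"]
        delta = 0
        for v in sorted(variants, key=lambda v: v.pos, reverse=True):
            i = v.pos - 1
            seq = seq[:i] + v.alt + seq[i + len(v.ref):]
            delta += len(v.alt) - len(v.ref)
        region = seq[s : e + delta]
        if strand == "-":
            region = str(Seq(region).reverse_complement())
        total += 1
        if rec.mut_protein == translate(region):
            agree += 1
    return {"genes_checked": total, "agreeing": agree,
            "percent_agreement": 100.0 * agree / total}


# --------------------------------------------------------------------------
# mosaic block recovery
# --------------------------------------------------------------------------

_RECOVERY_CHROM_LEN = 600_000
_RECOVERY_BLOCKS = (
    BlockSpec("chr1", 100_000, 140_000, 3.0, "moderate-block"),
    BlockSpec("chr1", 300_000, 325_000, 10.0, "high-block"),
    BlockSpec("chr1", 450_000, 470_000, 3.0, "moderate-block"),
)
_RECOVERY_CLASSES = ("moderate", "high", "moderate")


def mosaic_recovery_experiment(seed: int = 0, n_replicates: int = 50) -> dict:
    """Plant three divergent blocks (>= 20 kb, densities 3 and 10 SNV/kb)
    on a 0.2 SNV/kb background and segment with the default thresholds
    (5 kb windows, 0.5/1.0 SNV/kb, 15 kb minimum cluster).

    A replicate succeeds when every planted block is recovered by a
    cluster of the correct divergence class whose boundaries err by at
    most one window.  Also reports the mean recovered divergent fraction
    (planted: 85 kb / 600 kb = 14.17%).
    """
    genome, _ = generate_reference(seed + 1, {"chr1": _RECOVERY_CHROM_LEN}, n_genes=2)
    background = [
        BlockSpec("chr1", 0, 100_000, 0.2),
        BlockSpec("chr1", 140_000, 300_000, 0.2),
        BlockSpec("chr1", 325_000, 450_000, 0.2),
        BlockSpec("chr1", 470_000, _RECOVERY_CHROM_LEN, 0.2),
    ]
    window = mos.DEFAULT_WINDOW
    planted_fraction = 100.0 * sum(b.length for b in _RECOVERY_BLOCKS) / _RECOVERY_CHROM_LEN
    successes = 0
    fractions = []
    for rep in range(n_replicates):
        planted = plant_mosaic(
            genome, list(_RECOVERY_BLOCKS) + background, seed=seed * 1000 + rep
        )
        track = window_density(planted.truth, {"chr1": _RECOVERY_CHROM_LEN})
        clusters = segment_clusters(track)
        ok = True
        for block, expect_class in zip(_RECOVERY_BLOCKS, _RECOVERY_CLASSES):
            matches = [
                c for c in clusters
                if c.chrom == block.chrom
                and abs(c.start - block.start) <= window
                and abs(c.end - block.end) <= window
            ]
            if len(matches) != 1 or matches[0].divergence_class != expect_class:
                ok = False
        successes += ok
        fractions.append(
            100.0 * sum(c.length for c in clusters) / _RECOVERY_CHROM_LEN
        )
    return {
        "replicates": n_replicates,
        "block_recovery_successes": successes,
        "percent_replicates_recovered": 100.0 * successes / n_replicates,
        "planted_divergent_percent": planted_fraction,
        "mean_recovered_divergent_percent": float(np.mean(fractions)),
        "max_abs_fraction_error": float(
            np.max(np.abs(np.array(fractions) - planted_fraction))
        ),
    }


# --------------------------------------------------------------------------
# false-positive elimination
# --------------------------------------------------------------------------

def fp_elimination_experiment(seed: int = 0, n_seeds: int = 20) -> dict:
    """fn = 0 and ~50 independent FPs per platform on a 1 Mb genome: how
    often does the 2-platform consensus equal the truth exactly?"""
    genome, _ = generate_reference(seed + 2, {"chr1": 1_000_000}, n_genes=2)
    truth = plant_mosaic(
        genome, [BlockSpec("chr1", 0, 1_000_000, 0.5)], seed=seed + 3
    ).truth
    equal = 0
    for rep in range(n_seeds):
        models = {
            ("pA", "m"): ErrorModel(fp_rate=0.05, fn_rate=0.0,
                                    seed=seed * 100 + 2 * rep),
            ("pB", "m"): ErrorModel(fp_rate=0.05, fn_rate=0.0,
                                    seed=seed * 100 + 2 * rep + 1),
        }
        callsets = simulate_callsets(truth, genome, ["pA", "pB"], ["m"], models)
        _, final = cons.intersect(list(callsets.values()))
        equal += final.keys() == truth.keys()
    return {"seeds": n_seeds, "consensus_equals_truth": equal}


# --------------------------------------------------------------------------
# read QC on degraded simulated reads
# --------------------------------------------------------------------------

def readqc_experiment(seed: int = 0) -> dict:
    """Simulate reads, degrade qualities (random low-quality bases and
    3' quality decay), run the QC pipeline and verify the survivor
    invariants (no base < Phred 12, length >= 64)."""
    genome, _ = generate_reference(seed + 4, {"chr1": 100_000}, n_genes=2)
    rng = np.random.default_rng(seed + 5)
    reads = []
    for r1, r2 in simulate_paired_reads(genome, 120, 200, 400, 2.0, seed=seed + 6):
        for r in (r1, r2):
            quals = np.full(len(r), 38)
            decay_from = int(rng.integers(60, len(r) + 1))
            quals[decay_from:] = rng.integers(2, 20, size=len(r) - decay_from)
            n_spikes = int(rng.integers(0, 3))
            for p in rng.integers(0, len(r), size=n_spikes):
                quals[p] = int(rng.integers(0, 12))
            reads.append(Read(r.id, r.sequence, tuple(int(q) for q in quals)))
    params = QCParams(min_quality=12, adaptor="", min_length=64, dedup_prefix=64)
    survivors, report = qc_pipeline(reads, params)
    violations = sum(
        1 for r in survivors if len(r) < 64 or min(r.qualities) < 12
    )
    return {
        "reads_in": report.reads_in,
        "reads_out": report.reads_out,
        "percent_surviving": 100.0 * report.reads_out / report.reads_in,
        "mean_length_out": report.mean_length_out,
        "invariant_violations": violations,
    }


# --------------------------------------------------------------------------
# array-overlap recovery
# --------------------------------------------------------------------------

def array_overlap_experiment(
    seed: int = 0,
    sensitivities: Sequence[float] = (0.1, 0.5, 0.9),
    n_replicates: int = 20,
) -> dict:
    """Simulated tiling-array calls with <=2 bp jitter at several
    sensitivities: the measured overlap percent should recover the
    simulated sensitivity."""
    genome, _ = generate_reference(seed + 7, {"chr1": 1_000_000}, n_genes=2)
    truth = plant_mosaic(
        genome, [BlockSpec("chr1", 0, 1_000_000, 1.0)], seed=seed + 8
    ).truth
    n = len(truth)
    out = {}
    for s in sensitivities:
        rates = []
        for rep in range(n_replicates):
            calls = simulate_array_calls(
                truth, {"chr1": 1_000_000}, jitter_max_bp=2, sensitivity=s,
                noise_calls=0, seed=seed * 100 + rep,
            )
            rates.append(array_overlap(truth, calls, tol_bp=2).percent)
        out[f"overlap_percent_at_sensitivity_{s}"] = float(np.mean(rates))
        out[f"se_at_sensitivity_{s}"] = float(
            100.0 * np.sqrt(s * (1 - s) / n) / np.sqrt(n_replicates)
        )
    out["truth_snvs"] = n
    out["replicates"] = n_replicates
    return out
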