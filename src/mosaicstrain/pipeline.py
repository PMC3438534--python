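"""End-to-end pipeline: simulate -> consensus -> effects -> mosaic.

Chains the analysis stages on a synthetic scenario (or user-supplied
inputs) and writes every stage's outputs plus a combined JSON summary.
Rerunning with the same seed reproduces all outputs byte-identically.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

from mosaicstrain import consensus as cons
from mosaicstrain import effects as eff
from mosaicstrain import mosaic as mos
from mosaicstrain.genes import GeneModel, write_fasta, write_gff3
from mosaicstrain.simulate import Scenario, ScenarioConfig, build_scenario
from mosaicstrain.variants import Callset, write_vcf

__all__ = ["run_pipeline", "analyse_scenario"]


def analyse_scenario(scenario: Scenario) -> dict:
    """Run consensus, effects and mosaic stages on a built scenario and
    return the combined summary (pure computation, no I/O)."""
    callsets = list(scenario.callsets.values())
    per_group, final = cons.intersect(callsets, groupby="mapper")
    report = cons.accounting(callsets, per_group, final)
    groups = list(per_group.values())
    confirm = (
        cons.cross_confirm(groups[0], groups[1], vclass="SNP")
        if len(groups) == 2
        else None
    )

    records = [
        eff.classify_effects(g, scenario.reference, final.variants)
        for g in scenario.genes
    ]
    effect_summary = eff.aggregate(records)
    # annotation of the planted truth, independent of callset errors
    records_truth = [
        eff.classify_effects(g, scenario.reference, scenario.truth.variants)
        for g in scenario.genes
    ]
    truth_summary = eff.aggregate(records_truth)

    track = mos.window_density(final, scenario.chrom_lengths)
    clusters = mos.segment_clusters(track)
    mosaic_report = mos.fractions(track, clusters)
    sharing = mos.share_with_strain(final, scenario.other_truth, clusters)
    overlap = mos.array_overlap(final, scenario.array_calls, tol_bp=2)

    summary = {
        "consensus": {
            "input_sizes": report.input_sizes,
            "group_sizes": report.group_sizes,
            "final_size": report.final_size,
            "eliminated_total": report.eliminated_total,
            "union_size": report.union_size,
            "percent_eliminated": report.percent_eliminated,
            "class_table": report.class_table,
        },
        "effects": {
            "genes_annotated": effect_summary.n_genes,
            "proteins_altered": effect_summary.n_proteins_altered,
            "altered_1_2_residues": effect_summary.n_with_1_2_residues,
            "altered_3plus_residues": effect_summary.n_with_3plus_residues,
            "nonsense_alleles": effect_summary.n_nonsense,
            "genes_with_small_indels": effect_summary.n_genes_with_small_indels,
            "genes_with_complex": effect_summary.n_genes_with_complex,
            "neutralizing_pairs": effect_summary.genes_with_neutralizing_pairs,
        },
        "effects_truth": {
            "proteins_altered": truth_summary.n_proteins_altered,
            "nonsense_alleles": truth_summary.n_nonsense,
            "genes_with_small_indels": truth_summary.n_genes_with_small_indels,
            "neutralizing_pairs": truth_summary.genes_with_neutralizing_pairs,
        },
        "mosaic": {
            "n_clusters": len(clusters),
            "total_divergent_bp": mosaic_report.total_divergent_bp,
            "percent_identical_genome": round(
                mosaic_report.percent_identical_genome, 2
            ),
            "median_percent_divergent": round(
                mosaic_report.median_percent_divergent, 2
            ),
            "percent_identical_by_chrom": {
                c: round(p, 2)
                for c, p in mosaic_report.percent_identical_by_chrom.items()
            },
            "clusters": [
                {
                    "chrom": c.chrom,
                    "start": c.start,
                    "end": c.end,
                    "median_density": round(c.median_density, 3),
                    "class": c.divergence_class,
                }
                for c in clusters
            ],
            "shared_clusters": [
                {
                    "chrom": r.cluster.chrom,
                    "start": r.cluster.start,
                    "end": r.cluster.end,
                    "shared": r.shared,
                    "diff_density": round(r.diff_density, 3),
                }
                for r in sharing
            ],
        },
        "array": {
            "matched": overlap.matched,
            "total_snvs": overlap.total_snvs,
            "percent": round(overlap.percent, 2),
        },
    }
    if confirm is not None:
        summary["consensus"]["cross_mapper_snp"] = {
            "confirmed": confirm.confirmed,
            "a_only": confirm.a_only,
            "b_only": confirm.b_only,
            "percent_of_a": confirm.percent_of_a,
            "percent_of_b": confirm.percent_of_b,
        }
    # keep the analysis artefacts available to callers that want them
    summary["_objects"] = {
        "final": final,
        "per_group": per_group,
        "report": report,
        "records": records,
        "track": track,
        "clusters": clusters,
        "mosaic_report": mosaic_report,
        "sharing": sharing,
    }
    return summary


def run_pipeline(
    outdir: str | Path, config: ScenarioConfig | None = None
) -> dict:
    """Build the scenario, analyse it and write all stage outputs under
    ``outdir``.  Returns the JSON-serialisable summary."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    scenario = build_scenario(config)
    lengths = scenario.chrom_lengths

    write_fasta(scenario.reference, outdir / "reference.fa")
    write_gff3(scenario.genes, outdir / "genes.gff3")
    write_fasta(scenario.mosaic.sample_genome, outdir / "sample.fa")
    write_vcf(scenario.truth, outdir / "truth.vcf", lengths)
    (outdir / "truth_blocks.bed").write_text(scenario.mosaic.blocks_bed())
    for (platform, mapper), cs in scenario.callsets.items():
        write_vcf(cs, outdir / f"calls_{platform}_{mapper}.vcf", lengths)
    mos.write_array_tsv(scenario.array_calls, outdir / "array_calls.tsv")
    write_vcf(scenario.other_truth, outdir / "relative.vcf", lengths)

    summary = analyse_scenario(scenario)
    objects = summary.pop("_objects")
    write_vcf(objects["final"], outdir / "consensus.vcf", lengths)
    (outdir / "consensus_report.tsv").write_text(objects["report"].to_tsv())
    (outdir / "effects.tsv").write_text(eff.records_to_tsv(objects["records"]))
    (outdir / "clusters.bed").write_text(mos.clusters_to_bed(objects["clusters"]))
    (outdir / "mosaic_report.tsv").write_text(objects["mosaic_report"].to_tsv())
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2) + "\n")
    summary["_objects"] = objects
    summary["_scenario"] = scenario
    return summary
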