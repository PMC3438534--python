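"""Consensus variant calling across two platforms and two mappers.

Simulates four callsets (2 platforms x 2 mappers) from one truth set,
each with its own independent false positives and false negatives, then
intersects per mapper and across mappers.  Independent errors almost
never coincide, so the consensus strips them while keeping the truth.
"""

from mosaicstrain import consensus as cons
from mosaicstrain.simulate import (
    BlockSpec,
    ErrorModel,
    generate_reference,
    plant_mosaic,
    simulate_callsets,
)

genome, _ = generate_reference(seed=6, chrom_lengths={"chrI": 1_000_000}, n_genes=2)
truth = plant_mosaic(genome, [BlockSpec("chrI", 0, 1_000_000, 0.8)], seed=7).truth
print(f"truth: {len(truth)} variants")

platforms, mappers = ["pyro", "illumina"], ["mapperA", "mapperB"]
models = {
    (p, m): ErrorModel(fp_rate=0.05, fn_rate=0.01, seed=10 + i)
    for i, (p, m) in enumerate((p, m) for p in platforms for m in mappers)
}
callsets = simulate_callsets(truth, genome, platforms, mappers, models)

per_group, final = cons.intersect(list(callsets.values()), groupby="mapper")
report = cons.accounting(list(callsets.values()), per_group, final)
print(report.to_tsv())

fp_surviving = len(final.keys() - truth.keys())
print(f"false positives surviving the 4-way consensus: {fp_surviving}")
# Each callset carried ~50 independent FPs; the intersection removes them
# because an artefact must recur at the same position with the same allele
# in every callset to survive.  The eliminated counts per callset are the
# FPs plus the truth variants another callset happened to miss.
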