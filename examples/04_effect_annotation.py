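"""Annotate planted marker mutations in the classical allele notation.

Builds toy genes whose codons are pinned so the planted lesions read out
as the textbook auxotrophic alleles: a nonsense at a glutamate codon
("glu64STOP"), single frameshifts ("lys47", "gly83"), and a neutralizing
frameshift pair (+1 then -1) that restores the reading frame.
"""

import numpy as np

from mosaicstrain.effects import classify_effects
from mosaicstrain.simulate import MarkerSpec, place_gene, plant_marker_mutations, synthesize_cds

rng = np.random.default_rng(0)
genome = {"chrT": "".join(rng.choice(list("ACGT"), size=20_000))}

plan = [
    ("ade2", "+", {64: "GAA"}, None, MarkerSpec("ade2", "nonsense", (64,))),
    ("can1", "+", {47: "AAG", 48: "CAA"}, None, MarkerSpec("can1", "frameshift", (47,))),
    ("his3", "+", {70: "GCA", 105: "CCA", 106: "GAA"}, (69, 107),
     MarkerSpec("his3", "neutralizing_pair", (70, 106))),
]
genes, specs = [], []
for i, (gid, strand, overrides, t_free, spec) in enumerate(plan):
    cds = synthesize_cds(rng, 150, codon_overrides=overrides,
                         t_free_codon_range=t_free)
    genes.append(place_gene(genome, "chrT", 1_000 + 2_000 * i, cds, strand, gid))
    specs.append(spec)

variants = plant_marker_mutations(genome, genes, specs, seed=1)
print(f"planted {len(variants)} variants\n")
for gene in genes:
    rec = classify_effects(gene, genome, variants)
    print(f"{gene.gene_id}: {rec.describe()}  (changed residues: "
          f"{rec.n_changed_residues})")
# ade2 truncates at codon 64; can1 shifts frame from codon 47 onward; in
# his3 the second frameshift cancels the first, so the protein keeps its
# length and only the residues between the two indels differ.
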