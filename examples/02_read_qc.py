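"""Quality-trim, adaptor-clip, length-filter and deduplicate reads.

Simulates reads from a small genome, degrades part of their qualities,
duplicates a few (amplification bias), and runs the QC pipeline with the
classical thresholds: Phred 12, 15 bp adaptor match, 64 bp minimum
length, 64 bp dedup prefix.
"""

import numpy as np

from mosaicstrain.reads_qc import QCParams, Read, qc_pipeline
from mosaicstrain.simulate import generate_reference, simulate_paired_reads

genome, _ = generate_reference(seed=3, chrom_lengths={"chrI": 50_000}, n_genes=2)
rng = np.random.default_rng(4)

reads = []
for r1, r2 in simulate_paired_reads(genome, 120, 300, 500, 1.0, seed=5):
    for r in (r1, r2):
        quals = np.full(len(r), 38)
        tail = int(rng.integers(60, len(r) + 1))  # 3' quality decay
        quals[tail:] = rng.integers(2, 20, size=len(r) - tail)
        reads.append(Read(r.id, r.sequence, tuple(int(q) for q in quals)))
reads += reads[:10]  # ten PCR duplicates

params = QCParams(min_quality=12, adaptor="", min_length=64, dedup_prefix=64)
survivors, report = qc_pipeline(reads, params)
print(report.to_tsv())
# reads_out < reads_in: decayed tails were trimmed away (reads whose clean
# run fell under 64 bp died at the length filter) and the 10 planted
# duplicates were removed; every survivor has no base below Phred 12.
assert all(min(r.qualities) >= 12 and len(r) >= 64 for r in survivors)
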