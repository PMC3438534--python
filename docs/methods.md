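# Methods

## Problem setting

A mosaic laboratory strain derives most of its genome from one major
ancestor but carries blocks of chromosome inherited from other parents.
Resequencing such a strain against the major ancestor's reference genome
yields a variant landscape with two signatures: a near-zero background
difference rate in ancestor-derived regions, and contiguous clusters of
much higher SNV density where the material came from elsewhere. The
package's three analysis stages — consensus calling, effect annotation and
density segmentation — exploit these signatures; the synthetic-data
generator creates genomes with exactly this structure so every stage can be
validated against planted truth.

## Variant model and normalization

A variant is `(chrom, pos, ref, alt)` with 1-based VCF coordinates
(intervals elsewhere are 0-based half-open). Before any comparison,
variants are normalized by the canonical left-alignment: shared trailing
bases are stripped (extending leftward through repeat runs whenever an
allele would empty), then shared leading bases are stripped down to the
single anchor base indels require. Every equivalent representation of an
event — including suffix-anchored forms arising from minus-strand
projections — maps to one canonical record; the test suite verifies this
against a brute-force haplotype-equivalence oracle that enumerates padded
representations.

Classes: `SNP` (both alleles one base), `INS`/`DEL` (exactly one base
gained or lost), `MNV` (everything else — multi-base substitutions, longer
or complex events). The partition is total and exclusive, so per-class
counts always sum to the callset size.

## Consensus calling

Callsets are intersected under strict `(chrom, pos, ref, alt)` matching
after normalization. Grouping is two-level: with `groupby="mapper"` the
callsets of each mapper are first intersected across platforms and the
per-mapper consensuses are then intersected; strict matching makes the
final consensus independent of the grouping order (asserted as a property
test). A loose mode that matches MNVs by overlapping reference span plus
identical alt exists but is opt-in.

Accounting: eliminated per callset = |callset| − |callset ∩ consensus|;
the total is their sum, and the eliminated fraction is reported against
the strict-match union of all inputs (both the exact fraction and the
half-up-rounded percent are emitted). Because the consensus is a subset
of every input, the total also equals Σ|inputs| − k·|consensus| for k
inputs. Cross-confirmation between two per-mapper consensuses reports
confirmed / a-only / b-only counts per variant class with percentages
rounded half-up to integers.

The statistical rationale: false positives arise independently per
platform/mapper with ~uniform positions, so the expected number of FPs
surviving a 2-way intersection of callsets with n₁ and n₂ FPs on a genome
of G positions is ≈ n₁·n₂/G · P(same alt) — far below one at realistic
rates (50 FPs each on 1 Mb gives ≈ 0.0008). True variants appear in all
callsets except for false-negative dropouts, so the consensus loses a
true variant with probability 1 − (1 − fn)^k.

## Effect annotation

Per gene the CDS is extracted (concatenated exon intervals,
reverse-complemented for minus-strand genes) and each variant is projected
into CDS coordinates with strand-aware allele complementing; variants not
fully inside one CDS interval are ignored (intron/UTR/intergenic effects
are out of scope). Edits are applied while building a base-level map from
mutant to reference CDS offsets, which drives all downstream calls:

* **substitutions** — mutant codons whose three bases map contiguously and
  in-frame to a reference codon, with a different amino acid;
* **nonsense** — the first premature stop in an in-frame codon, named by
  the *reference* residue: `glu64STOP` means the glutamate at codon 64
  became a stop. Stops inside frameshifted segments are consequences of
  the frameshift, not nonsense calls;
* **frameshifts** — indels with length change ≢ 0 (mod 3), reported at the
  codon containing the first base that changes (the base after the VCF
  anchor), named by the reference residue there (`lys47`);
* **neutralizing pairs** — cumulative indel length change is tracked along
  the CDS; a maximal run of indels returning the cumulative change to
  0 (mod 3) restores the downstream frame. The run is flagged
  `frame_restored` only if the mutant translation of the shifted segment
  contains no stop — otherwise the protein truncates anyway and the gene
  is reported as a plain frameshift.

Changed-residue counts: when reference and mutant CDS have equal length
(pure substitutions, or fully compensated indel pairs) the count is the
positional Hamming distance of the translated proteins up to the first
stop, so residues inside a frame-restored segment count where they differ.
When lengths differ, the count is the number of differing aligned codons
plus the number of mutant codons without an in-frame reference partner.

Genome-wide aggregation assigns each gene its most severe category
(complex variant > single-base indel > nonsense > missense by 1–2 vs 3+
changed residues); genes whose variants are all synonymous are not counted
as altered. The annotation engine is checked against an independent
brute-force oracle — apply the variants by plain genome splicing,
re-extract the (length-adjusted) gene region, translate — on 1000 random
genes per run.

## Mosaic segmentation

Chromosomes are tiled from position 0 into fixed windows (default 5 kb;
the final partial window keeps its true length for density normalization,
and fragments under 1 kb merge into the previous window). Only SNPs enter
the density (indels are excluded by default since block divergence is
measured in SNVs). Windows classify as *identical* (≤ 0.5 SNV/kb),
*divergent* (> 1 SNV/kb) or *ambiguous* in between; the two thresholds
deliberately leave a gap because in practice no region sits between them.
Ambiguous windows directly adjacent to a divergent window are absorbed
into the run in a single pass (longer ambiguous chains revert to
identical — this bounds the boundary error of a recovered block at one
window); maximal divergent runs shorter than 15 kb are discarded.
Cluster density is the median of member-window densities, binned into the
two empirically observed divergence classes (2–5 SNV/kb "moderate",
9–12 SNV/kb "high", else "other"); bins and thresholds are parameters.

Identity fractions are cluster-complement based: percent identical per
chromosome = 100 · (length − Σ cluster lengths)/length, and the median
across chromosomes of the divergent percentage is reported alongside the
genome-wide figure.

**Sharing attribution.** For each cluster, the sample is compared with a
second strain called against the same reference: at every position the
two strains' alleles are compared (absence from a callset means the
reference allele), and the cluster is *shared* when the pairwise
difference density is at most 0.5 SNV/kb while the sample still diverges
from the reference above 1 SNV/kb — i.e. both strains carry the same
non-reference haplotype, implying a common ancestor for the block.
Sharing is evaluated per window first, and a breakpoint is reported at
each window boundary where the state flips inside a cluster (sub-window
refinement is not attempted; breakpoints are window-resolution).

**Array overlap.** Tiling arrays locate a SNV only to within a few bases,
so an array call matches a sequencing SNV when it lies within ±2 bp on
the same chromosome (the ~5 bp detection window read as a symmetric
tolerance). Each array call matches at most one SNV — the nearest,
leftmost on ties — and the overlap is reported as matched SNVs over total
sequencing SNVs.

## Read QC

Four stages in fixed order: (1) keep the longest contiguous run of bases
with quality ≥ Phred 12 (leftmost on ties); (2) truncate at the leftmost
exact occurrence of ≥ 15 bp of the adaptor's 3' end (no mismatches; a
single adaptor strand is searched); (3) drop reads shorter than 64 bp;
(4) remove reads whose first 64 bases duplicate an earlier read's (shorter
reads compare in full; first occurrence wins). Outputs are always
substrings of inputs, survivors satisfy both thresholds, and the pipeline
is idempotent. In paired mode mates are filtered independently; a pair
survives only if both mates do and the survivor of a broken pair is
written to an orphans file, with pair dedup keyed on the mate-1 prefix.

## Synthetic-data generator

* **Reference genomes**: i.i.d. bases at a configurable GC fraction
  (default 0.38, yeast-like), with non-overlapping single-exon genes built
  from sense codons (ATG start, single terminal stop, no internal in-frame
  stop by construction) on alternating strands. All outputs are
  deterministic per seed and byte-identical across runs.
* **Mosaic planting**: per block the SNV count is round(density ·
  length/1000) in exact mode (used throughout the tests, so recovery
  checks are deterministic) or Poisson with that mean; positions are
  uniform without replacement (the placement distribution is the
  generator's own choice); alternate bases are uniform over the three
  non-reference bases. The truth VCF applied to the reference reproduces
  the sample genome exactly (string equality, asserted).
* **Marker mutations** are designed in CDS space at requested codons and
  emitted as normalized genome-space VCF records. Single-base deletions
  pick a base whose neighbours differ so the left-aligned representation
  stays inside the target codon on either strand; the segment between a
  neutralizing pair is built from T-free codons, which cannot form a stop
  in any reading frame, guaranteeing the planted pair annotates as
  frame-restored.
* **Callsets**: per (platform, mapper) an independent seeded error model
  drops each truth variant with probability `fn_rate` and adds
  `fp_rate · genome_kb` false positives at uniform non-truth positions
  (bounded rejection sampling; a Poisson FP count is optional).
* **Reads**: error-free pairs; ⌈coverage·G/(2·read length)⌉ pairs with
  uniform insert sizes (defaults 400 bp reads, 2–4 kb inserts, 10×) —
  mates sit at the insert ends on opposite strands.
* **Array calls**: each truth SNV is detected with probability
  `sensitivity` and jittered by a uniform integer in ±2 bp; noise calls
  land uniformly.

The default scenario (1.2 Mb over three chromosomes, five divergent
blocks spanning 175 kb = 14.6% of the genome with densities in the 2–5
and 9–12 SNV/kb classes, 0.2 SNV/kb background, five marker genes, four
callsets at fp 0.05/kb and fn 2%, array sensitivity 0.5 with ±2 bp jitter
and 50 noise calls) reproduces the qualitative structure of a real
mosaic-strain comparison at desk scale. Problem sizes in the validation
experiments (600 kb × 50 replicates for block recovery, 1 Mb × 20 seeds
for FP elimination, 1000 genes for the translation oracle) were chosen so
the full suite runs in seconds while keeping Monte-Carlo standard errors
small against the tested tolerances.

## What the synthetic data does not emulate

Reads carry no base-calling errors (QC is validated with separately
injected quality degradation); variants are haploid SNVs plus planted
marker indels — no structural variants, no diploid genotypes, no
clustered mutation processes; false positives are uniform rather than
motif- or homopolymer-driven; genes are single-exon (the annotation
handles multi-exon models, exercised by fixtures); array noise is
positionally uniform. Passing tests therefore demonstrate correctness of
the algorithms under the stated error models, not robustness to every
artefact of real sequencing data.

## Numerical and design choices

* Percentages in reports are rounded half-up; exact fractions accompany
  them.
* Window classes use ≤ for the identity threshold and > for the
  divergence threshold; a window exactly at 1 SNV/kb is ambiguous.
* Cluster recovery tolerance is one window per boundary; the single-pass
  ambiguous absorption bounds systematic boundary error at that level.
* Ties in quality-run trimming go leftmost; adaptor search is exact-match
  and single-strand; dedup keeps the first occurrence in input order.
* Degenerate inputs: empty callsets produce empty tracks/reports; a
  zero-density block plants nothing; `coverage=0` yields no reads;
  single-callset groups pass through intersection unchanged.
* Known limitation: genes whose CDS a variant only partially overlaps are
  skipped rather than clipped; overlapping planted edits are rejected
  rather than resolved.
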