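"""CDS-level variant-effect annotation.

For each protein-coding gene the module extracts the coding sequence,
applies the gene's variants in CDS space (strand-aware), translates both
reference and mutant sequences and classifies the consequences:

* **substitutions** — aligned codons whose amino acid changes;
* **nonsense** — an in-frame change converting a sense codon to a stop,
  reported in the classical allele notation ``glu64STOP`` (reference
  glutamate at codon 64 becomes a stop);
* **frameshifts** — indels whose length change is not a multiple of 3,
  reported by the reference residue at the first shifted codon, e.g.
  ``lys47``;
* **neutralizing frameshift pairs** — runs of frameshifting indels whose
  cumulative length change returns to 0 mod 3 restore the downstream
  reading frame; such a run is flagged ``frame_restored`` when the
  translation of the shifted segment introduces no stop codon, because
  only then can the protein remain (partially) functional.

Amino-acid coordinates are 1-based codon indices in the reference protein.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from Bio.Seq import Seq
from Bio.SeqUtils import seq3

from mosaicstrain.genes import GeneModel
from mosaicstrain.variants import Variant, classify

__all__ = [
    "EffectRecord",
    "EffectSummary",
    "extract_cds",
    "apply_variants",
    "classify_effects",
    "aggregate",
    "translate",
]

_STOP = "*"


def translate(cds: str) -> str:
    """Translate a CDS with the standard nuclear code.

    Trailing bases that do not fill a codon (possible after a net
    frameshift) are dropped.  Stops are kept as ``*`` so premature stops
    remain visible.
    """
    usable = len(cds) // 3 * 3
    return str(Seq(cds[:usable]).translate())


def _aa3(aa: str) -> str:
    return seq3(aa).lower()


def extract_cds(gene: GeneModel, genome: Mapping[str, str]) -> str:
    """Concatenate a gene's CDS intervals; reverse-complement for minus strand."""
    chrom_seq = str(genome[gene.chrom])
    for start, end in gene.cds:
        if start < 0 or end > len(chrom_seq):
            raise IndexError(
                f"{gene.gene_id}: CDS interval {start}-{end} outside "
                f"{gene.chrom} (length {len(chrom_seq)})"
            )
    forward = "".join(chrom_seq[s:e] for s, e in gene.cds)
    if gene.strand == "-":
        return str(Seq(forward).reverse_complement())
    return forward


def _cds_offset_forward(gene: GeneModel, pos0: int) -> int | None:
    """Map a 0-based genome position to its offset in the forward-strand
    CDS concatenation, or None when it falls outside every CDS interval."""
    acc = 0
    for s, e in gene.cds:
        if s <= pos0 < e:
            return acc + (pos0 - s)
        acc += e - s
    return None


def project_variant(gene: GeneModel, variant: Variant) -> tuple[int, str, str] | None:
    """Project a genome-space variant into CDS coordinates.

    Returns ``(cds_offset, ref_allele, alt_allele)`` in CDS orientation
    (alleles reverse-complemented for minus-strand genes), or ``None`` when
    the variant's reference span is not fully inside a single CDS interval.
    """
    if variant.chrom != gene.chrom:
        return None
    start0 = variant.pos - 1
    end0 = start0 + len(variant.ref)
    containing = None
    for s, e in gene.cds:
        if s <= start0 and end0 <= e:
            containing = (s, e)
            break
    if containing is None:
        return None
    fwd_off = _cds_offset_forward(gene, start0)
    assert fwd_off is not None
    if gene.strand == "+":
        return fwd_off, variant.ref, variant.alt
    total = gene.cds_length
    cds_off = total - (fwd_off + len(variant.ref))
    ref = str(Seq(variant.ref).reverse_complement())
    alt = str(Seq(variant.alt).reverse_complement())
    return cds_off, ref, alt


def _apply_with_map(
    cds: str, edits: Sequence[tuple[int, str, str]]
) -> tuple[str, list[int]]:
    """Apply (offset, ref, alt) edits and return the mutant CDS together
    with a per-base map mutant offset -> reference CDS offset (-1 for
    bases without a reference counterpart, i.e. insertions)."""
    edits = sorted(edits)
    for (o1, r1, _), (o2, _, _) in zip(edits, edits[1:]):
        if o1 + len(r1) > o2:
            raise ValueError(
                f"overlapping variants at CDS offsets {o1} and {o2}"
            )
    out: list[str] = []
    mut2ref: list[int] = []
    cursor = 0
    for off, ref, alt in edits:
        if cds[off : off + len(ref)] != ref:
            raise ValueError(
                f"projected REF {ref!r} does not match CDS at offset {off}"
            )
        out.append(cds[cursor:off])
        mut2ref.extend(range(cursor, off))
        out.append(alt)
        mut2ref.extend(
            off + i if i < len(ref) else -1 for i in range(len(alt))
        )
        cursor = off + len(ref)
    out.append(cds[cursor:])
    mut2ref.extend(range(cursor, len(cds)))
    return "".join(out), mut2ref


def apply_variants(
    cds: str, gene: GeneModel, variants: Iterable[Variant]
) -> str:
    """Apply a gene's variants to its CDS; variants outside the CDS are
    ignored (intergenic/UTR/intron consequences are out of scope here)."""
    edits = []
    for v in variants:
        proj = project_variant(gene, v)
        if proj is not None:
            edits.append(proj)
    mutant, _ = _apply_with_map(cds, edits)
    return mutant


@dataclass
class EffectRecord:
    """Classified protein-level consequences of one gene's variants."""

    gene_id: str
    substitutions: list[tuple[str, int, str]] = field(default_factory=list)
    nonsense: tuple[str, int] | None = None
    frameshifts: list[tuple[int, int]] = field(default_factory=list)
    frameshift_labels: list[str] = field(default_factory=list)
    inframe_indels: list[tuple[int, int]] = field(default_factory=list)
    frame_restored: bool = False
    n_changed_residues: int = 0
    has_mnv: bool = False
    ref_protein: str = ""
    mut_protein: str = ""

    @property
    def nonsense_label(self) -> str | None:
        if self.nonsense is None:
            return None
        aa, idx = self.nonsense
        return f"{aa}{idx}STOP"

    @property
    def altered(self) -> bool:
        return self.ref_protein != self.mut_protein

    @property
    def substitution_labels(self) -> list[str]:
        return [f"{r}{i}{a}" for r, i, a in self.substitutions]

    def describe(self) -> str:
        """Human-readable allele string, Table-style."""
        parts: list[str] = []
        if self.nonsense:
            parts.append(f"nonsense, {self.nonsense_label}")
        if self.frameshifts:
            n = len(self.frameshifts)
            prefix = f"{n}x frameshift" if n > 1 else "frameshift"
            parts.append(prefix + ", " + " and ".join(self.frameshift_labels))
        if self.inframe_indels:
            parts.append(f"{len(self.inframe_indels)} in-frame indel(s)")
        if self.substitutions:
            parts.append("missense: " + ",".join(self.substitution_labels))
        if self.frame_restored:
            parts.append("frame restored")
        return "; ".join(parts) if parts else "no coding change"


def _effective(protein: str) -> str:
    """Protein sequence up to (excluding) the first stop."""
    i = protein.find(_STOP)
    return protein if i < 0 else protein[:i]


def classify_effects(
    gene: GeneModel, genome: Mapping[str, str], variants: Iterable[Variant]
) -> EffectRecord:
    """Annotate one gene: translate reference and mutant CDS and classify
    every protein-level difference.  See the module docstring for the
    conventions used."""
    cds = extract_cds(gene, genome)
    edits = []
    for v in variants:
        proj = project_variant(gene, v)
        if proj is not None:
            edits.append((proj, v))
    edits.sort(key=lambda pv: pv[0][0])
    mutant, mut2ref = _apply_with_map(cds, [p for p, _ in edits])

    ref_protein = translate(cds)
    mut_protein = translate(mutant)
    rec = EffectRecord(
        gene_id=gene.gene_id, ref_protein=ref_protein, mut_protein=mut_protein
    )
    rec.has_mnv = any(classify(v) == "MNV" for _, v in edits)

    # --- indels: frameshifts, in-frame indels, restoration runs ---------
    indels = [
        (off, ref, alt)
        for (off, ref, alt), _ in edits
        if len(ref) != len(alt)
    ]
    cum_before: list[int] = []
    cum = 0
    for off, ref, alt in indels:
        cum_before.append(cum)
        cum += len(alt) - len(ref)

    runs: list[tuple[int, int]] = []  # (first indel idx, last indel idx)
    run_start = None
    running = 0
    for i, (off, ref, alt) in enumerate(indels):
        delta = len(alt) - len(ref)
        was_zero = running % 3 == 0
        running += delta
        if was_zero and running % 3 != 0:
            run_start = i
        elif not was_zero and running % 3 == 0 and run_start is not None:
            runs.append((run_start, i))
            run_start = None

    for off, ref, alt in indels:
        delta = len(alt) - len(ref)
        # first base whose identity or frame changes: skip the shared
        # prefix (the VCF anchor base for left-anchored representations)
        p = 0
        while p < min(len(ref), len(alt)) and ref[p] == alt[p]:
            p += 1
        first_changed = off + p
        codon_idx = first_changed // 3 + 1
        if delta % 3 != 0:
            rec.frameshifts.append((codon_idx, delta))
            residue = (
                _aa3(ref_protein[codon_idx - 1])
                if codon_idx - 1 < len(ref_protein)
                else "ter"
            )
            rec.frameshift_labels.append(f"{residue}{codon_idx}")
        else:
            rec.inframe_indels.append((codon_idx, delta))

    restored = False
    for a, b in runs:
        # mutant-space span of the shifted segment
        off_a, ref_a, alt_a = indels[a]
        off_b, ref_b, alt_b = indels[b]
        pa = 0
        while pa < min(len(ref_a), len(alt_a)) and ref_a[pa] == alt_a[pa]:
            pa += 1
        m_start = off_a + pa + cum_before[a]
        m_end = off_b + len(alt_b) + cum_before[b]
        c0, c1 = m_start // 3, max(m_start // 3, (m_end - 1) // 3)
        segment = mut_protein[c0 : c1 + 1]
        if _STOP not in segment:
            restored = True
    rec.frame_restored = restored

    # --- aligned codon comparison: substitutions, nonsense, n_changed ---
    n_mut_codons = len(mutant) // 3
    n_ref_codons = len(cds) // 3
    aligned_diffs = 0
    unaligned = 0
    first_premature: tuple[str, int] | None = None
    for mi in range(n_mut_codons):
        offsets = mut2ref[3 * mi : 3 * mi + 3]
        in_frame = (
            len(offsets) == 3
            and offsets[0] >= 0
            and offsets[1] == offsets[0] + 1
            and offsets[2] == offsets[0] + 2
            and offsets[0] % 3 == 0
        )
        mut_aa = mut_protein[mi]
        if in_frame:
            ri = offsets[0] // 3
            ref_aa = ref_protein[ri]
            if mut_aa != ref_aa:
                aligned_diffs += 1
                if mut_aa == _STOP:
                    if first_premature is None and ri < n_ref_codons - 1:
                        first_premature = (_aa3(ref_aa), ri + 1)
                else:
                    rec.substitutions.append((_aa3(ref_aa), ri + 1, _aa3(mut_aa)))
        else:
            unaligned += 1
    rec.nonsense = first_premature

    if len(mutant) == len(cds):
        # net-zero length change: positional comparison is well defined,
        # including inside frame-restored segments
        eff_r, eff_m = _effective(ref_protein), _effective(mut_protein)
        span = max(len(eff_r), len(eff_m))
        rec.n_changed_residues = sum(
            1
            for i in range(span)
            if (eff_r[i] if i < len(eff_r) else None)
            != (eff_m[i] if i < len(eff_m) else None)
        )
    else:
        rec.n_changed_residues = aligned_diffs + unaligned
    return rec


@dataclass
class EffectSummary:
    """Genome-wide aggregation of per-gene effect records."""

    n_genes: int = 0
    n_proteins_altered: int = 0
    n_with_1_2_residues: int = 0
    n_with_3plus_residues: int = 0
    n_nonsense: int = 0
    n_genes_with_small_indels: int = 0
    n_genes_with_complex: int = 0
    genes_with_neutralizing_pairs: list[str] = field(default_factory=list)

    def to_tsv(self) -> str:
        rows = [
            ("genes_annotated", self.n_genes),
            ("proteins_altered", self.n_proteins_altered),
            ("altered_1_2_residues", self.n_with_1_2_residues),
            ("altered_3plus_residues", self.n_with_3plus_residues),
            ("nonsense_alleles", self.n_nonsense),
            ("genes_with_small_indels", self.n_genes_with_small_indels),
            ("genes_with_complex_variants", self.n_genes_with_complex),
            (
                "genes_with_neutralizing_pairs",
                ",".join(self.genes_with_neutralizing_pairs) or "-",
            ),
        ]
        return "\n".join(f"{k}\t{v}" for k, v in rows) + "\n"


def aggregate(records: Iterable[EffectRecord]) -> EffectSummary:
    """Summarise effect records genome-wide.

    Category assignment per gene (highest applicable wins): complex
    (any multi-base/complex variant) > small indel (any single-base indel)
    > nonsense > missense classes by number of changed residues.  Genes
    whose variants are all synonymous are not counted as altered.
    """
    out = EffectSummary()
    for rec in records:
        out.n_genes += 1
        if rec.altered:
            out.n_proteins_altered += 1
        if rec.frame_restored:
            out.genes_with_neutralizing_pairs.append(rec.gene_id)
        if rec.has_mnv:
            out.n_genes_with_complex += 1
        elif rec.frameshifts or rec.inframe_indels:
            out.n_genes_with_small_indels += 1
        elif rec.nonsense is not None:
            out.n_nonsense += 1
        elif rec.altered:
            if rec.n_changed_residues in (1, 2):
                out.n_with_1_2_residues += 1
            elif rec.n_changed_residues >= 3:
                out.n_with_3plus_residues += 1
    out.genes_with_neutralizing_pairs.sort()
    return out


def records_to_tsv(records: Iterable[EffectRecord]) -> str:
    """Per-gene TSV: gene, allele-style description, changed residues, flags."""
    lines = ["gene\teffect\tn_changed_residues\tframe_restored\taltered"]
    for rec in records:
        lines.append(
            f"{rec.gene_id}\t{rec.describe()}\t{rec.n_changed_residues}\t"
            f"{'yes' if rec.frame_restored else 'no'}\t"
            f"{'yes' if rec.altered else 'no'}"
        )
    return "\n".join(lines) + "\n"
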