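"""Gene models (CDS intervals + strand) and FASTA/GFF3 I/O.

A :class:`GeneModel` carries the protein-coding structure of one gene as a
list of CDS intervals in 0-based half-open genome coordinates, plus strand.
Internally every interval is 0-based half-open; GFF3 output uses the format's
1-based inclusive convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = ["GeneModel", "read_fasta", "write_fasta", "read_gff3", "write_gff3"]


@dataclass(frozen=True)
class GeneModel:
    """CDS intervals and strand for one protein-coding gene.

    ``cds`` is a tuple of (start, end) pairs, 0-based half-open, sorted by
    genome coordinate regardless of strand.
    """

    gene_id: str
    chrom: str
    strand: str
    cds: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: strand must be + or -")
        for start, end in self.cds:
            if start >= end:
                raise ValueError(f"{self.gene_id}: empty CDS interval {start}-{end}")
        object.__setattr__(self, "cds", tuple(sorted(self.cds)))

    @property
    def start(self) -> int:
        return self.cds[0][0]

    @property
    def end(self) -> int:
        return self.cds[-1][1]

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds)


def read_fasta(path: str | Path) -> dict[str, str]:
    """Load a FASTA file into a plain {name: sequence} dict (upper-case)."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(genome: Mapping[str, str], path: str | Path, width: int = 60) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in genome.items()
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def read_gff3(path: str | Path) -> list[GeneModel]:
    """Read CDS features from a GFF3 file into gene models.

    CDS features are grouped by their ``Parent`` (or ``ID``) attribute; the
    strand must be consistent within a gene.
    """
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    grouped: dict[str, list] = {}
    for feat in db.features_of_type("CDS"):
        parents = feat.attributes.get("Parent") or feat.attributes.get("ID") or [feat.id]
        grouped.setdefault(parents[0], []).append(feat)
    models = []
    for gene_id, feats in grouped.items():
        strands = {f.strand for f in feats}
        chroms = {f.seqid for f in feats}
        if len(strands) != 1 or len(chroms) != 1:
            raise ValueError(f"{gene_id}: inconsistent strand/chromosome in CDS set")
        models.append(
            GeneModel(
                gene_id=gene_id,
                chrom=chroms.pop(),
                strand=strands.pop(),
                cds=tuple((f.start - 1, f.end) for f in feats),
            )
        )
    return sorted(models, key=lambda g: (g.chrom, g.start, g.gene_id))


def write_gff3(genes: Iterable[GeneModel], path: str | Path) -> None:
    """Write gene models as GFF3 gene + CDS features (phase 0)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda g: (g.chrom, g.start, g.gene_id)):
            fh.write(
                f"{g.chrom}\tmosaicstrain\tgene\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\tID={g.gene_id}\n"
            )
            for i, (s, e) in enumerate(g.cds, start=1):
                fh.write(
                    f"{g.chrom}\tmosaicstrain\tCDS\t{s + 1}\t{e}\t.\t{g.strand}\t0\t"
                    f"ID={g.gene_id}.cds{i};Parent={g.gene_id}\n"
                )
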