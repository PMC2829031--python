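"""Gene/transcript models and file I/O for the synthetic genomes.

Internal coordinates are 0-based half-open throughout the package; GFF3 is
converted to/from its native 1-based closed convention at the boundary, BED
is consumed natively.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

PROTEIN_CODING = "protein_coding"
NCRNA = "ncRNA"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class TranscriptModel:
    """A single-isoform gene model (one transcript per locus)."""

    gene_id: str
    chrom: str
    start: int  # 0-based, half-open span
    end: int
    strand: str
    biotype: str  # PROTEIN_CODING or NCRNA
    exons: list[tuple[int, int]]
    cds: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.exons = sorted(self.exons)
        self.cds = sorted(self.cds)
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: bad strand {self.strand!r}")
        for s, e in self.exons + self.cds:
            if s < self.start or e > self.end:
                raise ValueError(
                    f"malformed gene model {self.gene_id}: exon [{s},{e}) "
                    f"outside span [{self.start},{self.end})"
                )

    @property
    def tss(self) -> int:
        """Transcription start: leftmost base for '+', one past the
        rightmost base (half-open end) for '-'."""
        return self.start if self.strand == "+" else self.end

    def introns(self) -> list[tuple[int, int]]:
        return [
            (self.exons[i][1], self.exons[i + 1][0])
            for i in range(len(self.exons) - 1)
        ]

    def spliced_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    def spliced_sequence(self, chrom_seq: str) -> str:
        seq = "".join(chrom_seq[s:e] for s, e in self.exons)
        return seq if self.strand == "+" else revcomp(seq)


@dataclass
class SyntheticGenome:
    """A chromosome sequence set plus its annotation."""

    sequences: dict[str, str]
    models: list[TranscriptModel]

    def genes(self) -> list[TranscriptModel]:
        return [m for m in self.models if m.biotype == PROTEIN_CODING]

    def ncrnas(self) -> list[TranscriptModel]:
        return [m for m in self.models if m.biotype == NCRNA]

    def by_id(self) -> dict[str, TranscriptModel]:
        return {m.gene_id: m for m in self.models}


# ---------------------------------------------------------------------------
# writers (all emit a provenance header with config hash and seed)
# ---------------------------------------------------------------------------

def _header_lines(comment: str, config_hash: str | None, seed: int | None) -> list[str]:
    lines = []
    if config_hash is not None or seed is not None:
        lines.append(f"{comment} config_hash={config_hash} seed={seed}")
    return lines


def write_gff3(
    models: list[TranscriptModel],
    path: str | Path,
    config_hash: str | None = None,
    seed: int | None = None,
) -> None:
    out = ["##gff-version 3"]
    out += _header_lines("#!", config_hash, seed)
    for m in sorted(models, key=lambda m: (m.chrom, m.start, m.gene_id)):
        s1, e1 = m.start + 1, m.end  # 1-based closed
        gtype = "gene" if m.biotype == PROTEIN_CODING else "ncRNA_gene"
        ttype = "mRNA" if m.biotype == PROTEIN_CODING else "lnc_RNA"
        tid = f"{m.gene_id}.t1"
        out.append(
            f"{m.chrom}\tlncdev\t{gtype}\t{s1}\t{e1}\t.\t{m.strand}\t.\tID={m.gene_id}"
        )
        out.append(
            f"{m.chrom}\tlncdev\t{ttype}\t{s1}\t{e1}\t.\t{m.strand}\t.\t"
            f"ID={tid};Parent={m.gene_id}"
        )
        for i, (s, e) in enumerate(m.exons, 1):
            out.append(
                f"{m.chrom}\tlncdev\texon\t{s + 1}\t{e}\t.\t{m.strand}\t.\t"
                f"ID={tid}.exon{i};Parent={tid}"
            )
        for i, (s, e) in enumerate(m.cds, 1):
            out.append(
                f"{m.chrom}\tlncdev\tCDS\t{s + 1}\t{e}\t.\t{m.strand}\t0\t"
                f"ID={tid}.cds{i};Parent={tid}"
            )
    Path(path).write_text("\n".join(out) + "\n")


def read_gff3(path: str | Path) -> list[TranscriptModel]:
    """Parse a GFF3 annotation back into transcript models via gffutils."""
    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    models = []
    for gene in list(db.features_of_type("gene")) + list(
        db.features_of_type("ncRNA_gene")
    ):
        biotype = PROTEIN_CODING if gene.featuretype == "gene" else NCRNA
        exons, cds = [], []
        for tx in db.children(gene, level=1):
            for child in db.children(tx, level=1):
                iv = (child.start - 1, child.end)  # back to half-open
                if child.featuretype == "exon":
                    exons.append(iv)
                elif child.featuretype == "CDS":
                    cds.append(iv)
        models.append(
            TranscriptModel(
                gene_id=gene.id,
                chrom=gene.seqid,
                start=gene.start - 1,
                end=gene.end,
                strand=gene.strand,
                biotype=biotype,
                exons=exons,
                cds=cds,
            )
        )
    models.sort(key=lambda m: (m.chrom, m.start, m.gene_id))
    return models


def write_fasta(records: dict[str, str], path: str | Path) -> None:
    seqs = [SeqRecord(Seq(s), id=name, description="") for name, s in records.items()]
    with open(path, "w") as fh:
        SeqIO.write(seqs, fh, "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_tsv(
    df: pd.DataFrame,
    path: str | Path,
    config_hash: str | None = None,
    seed: int | None = None,
) -> None:
    buf = io.StringIO()
    for line in _header_lines("#", config_hash, seed):
        buf.write(line + "\n")
    df.to_csv(buf, sep="\t", index=False)
    Path(path).write_text(buf.getvalue())


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


BED_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


def write_bed(
    df: pd.DataFrame,
    path: str | Path,
    config_hash: str | None = None,
    seed: int | None = None,
) -> None:
    """BED6 (+ optional extra numeric columns, e.g. a structure P column)."""
    cols = BED_COLUMNS + [c for c in df.columns if c not in BED_COLUMNS]
    buf = io.StringIO()
    for line in _header_lines("#", config_hash, seed):
        buf.write(line + "\n")
    df[cols].to_csv(buf, sep="\t", index=False, header=False)
    Path(path).write_text(buf.getvalue())


def read_bed(path: str | Path, extra: list[str] | None = None) -> pd.DataFrame:
    names = BED_COLUMNS + (extra or [])
    return pd.read_csv(path, sep="\t", comment="#", header=None, names=names)
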