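"""Readers and writers for the standard formats the pipeline consumes.

FASTA via Biopython, GFF3 via gffutils, narrowPeak/BED12/TSV via pandas.
GFF3 and BED12 gene records are collapsed to one :class:`GeneModel` per gene
(union span, union exons).
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Union

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .models import CountTable, GeneModel, Peak
from .regions import GenomicInterval

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_narrowpeak",
    "write_narrowpeak",
    "read_gene_annotation",
    "write_gff3",
    "read_count_table",
    "read_cluster_labels",
    "read_hit_table",
]

PathLike = Union[str, Path]

NARROWPEAK_COLUMNS = [
    "chrom",
    "chromStart",
    "chromEnd",
    "name",
    "score",
    "strand",
    "signalValue",
    "pValue",
    "qValue",
    "peak",
]


class FormatError(ValueError):
    """Raised on malformed input files."""


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: PathLike) -> Dict[str, str]:
    """Read a (possibly wrapped) multi-record FASTA into ``{id: sequence}``."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Dict[str, str], path: PathLike, width: int = 80) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# narrowPeak (ENCODE BED6+4)


def _format_score(value: float) -> str:
    return f"{value:.6g}"


def read_narrowpeak(path: PathLike) -> List[Peak]:
    """Read an ENCODE narrowPeak (BED6+4) file.

    Column 10 (summit offset relative to chromStart) may be −1, meaning no
    point source; such peaks carry ``summit_offset=None``.
    """
    peaks: List[Peak] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) != 10:
                raise FormatError(
                    f"{path}: line {lineno}: expected 10 narrowPeak columns, got {len(fields)}"
                )
            try:
                start, end = int(fields[1]), int(fields[2])
                strand = fields[5] if fields[5] in ("+", "-") else None
                summit = int(fields[9])
                peak = Peak(
                    interval=GenomicInterval(fields[0], start, end, strand),
                    name=fields[3],
                    score=int(fields[4]),
                    fold_enrichment=float(fields[6]),
                    neg_log10_p=float(fields[7]),
                    neg_log10_q=float(fields[8]),
                    summit_offset=None if summit == -1 else summit,
                )
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: {exc}") from exc
            peaks.append(peak)
    return peaks


def write_narrowpeak(peaks: Iterable[Peak], path: PathLike) -> None:
    with open(path, "w") as fh:
        for p in peaks:
            iv = p.interval
            fh.write(
                "\t".join(
                    [
                        iv.contig,
                        str(iv.start),
                        str(iv.end),
                        p.name,
                        str(p.score),
                        iv.strand or ".",
                        _format_score(p.fold_enrichment),
                        _format_score(p.neg_log10_p),
                        _format_score(p.neg_log10_q),
                        str(-1 if p.summit_offset is None else p.summit_offset),
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Gene annotation: GFF3 and BED12


def _merge_intervals(intervals: Sequence[GenomicInterval]) -> List[GenomicInterval]:
    """Union of possibly-overlapping same-contig intervals."""
    merged: List[GenomicInterval] = []
    for iv in sorted(intervals, key=lambda i: i.start):
        if merged and iv.start <= merged[-1].end:
            prev = merged[-1]
            merged[-1] = GenomicInterval(prev.contig, prev.start, max(prev.end, iv.end), prev.strand)
        else:
            merged.append(iv)
    return merged


_NCRNA_TYPES = {"ncRNA", "lnc_RNA", "lncRNA", "tRNA", "rRNA", "snRNA", "snoRNA"}


def _gff3_gene_models(db: gffutils.FeatureDB) -> List[GeneModel]:
    genes: List[GeneModel] = []
    for gene in db.features_of_type("gene"):
        strand = gene.strand if gene.strand in ("+", "-") else None
        span = GenomicInterval(gene.seqid, gene.start - 1, gene.end, strand)
        exons: List[GenomicInterval] = []
        cds: List[GenomicInterval] = []
        child_types = set()
        for child in db.children(gene.id):
            child_types.add(child.featuretype)
            if child.featuretype == "exon":
                exons.append(GenomicInterval(child.seqid, child.start - 1, child.end, strand))
            elif child.featuretype == "CDS":
                cds.append(GenomicInterval(child.seqid, child.start - 1, child.end, strand))
        exons = _merge_intervals(exons) if exons else [span]
        cds = _merge_intervals(cds)
        for e in exons:
            if e.start < span.start or e.end > span.end:
                raise FormatError(f"gene {gene.id}: exon outside gene span")
        attrs = gene.attributes
        description = (attrs.get("description") or attrs.get("Name") or [""])[0]
        biotype = (attrs.get("gene_biotype") or attrs.get("biotype") or [""])[0]
        if not biotype:
            if "mRNA" in child_types or cds:
                biotype = "protein_coding"
            elif child_types & _NCRNA_TYPES:
                biotype = "ncRNA"
            elif "miRNA" in child_types:
                biotype = "miRNA"
            else:
                biotype = "other"
        genes.append(
            GeneModel(
                gene_id=gene.id,
                span=span,
                exons=tuple(exons),
                cds=tuple(cds),
                description=description,
                biotype=biotype,
            )
        )
    return genes


def _bed12_gene_models(path: PathLike) -> List[GeneModel]:
    genes: List[GeneModel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) != 12:
                raise FormatError(f"{path}: line {lineno}: expected 12 BED12 columns, got {len(f)}")
            chrom, start, end = f[0], int(f[1]), int(f[2])
            strand = f[5] if f[5] in ("+", "-") else None
            span = GenomicInterval(chrom, start, end, strand)
            thick_start, thick_end = int(f[6]), int(f[7])
            n_blocks = int(f[9])
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            offsets = [int(x) for x in f[11].rstrip(",").split(",")]
            if len(sizes) != n_blocks or len(offsets) != n_blocks:
                raise FormatError(f"{path}: line {lineno}: blockCount mismatch")
            exons = [
                GenomicInterval(chrom, start + off, start + off + size, strand)
                for off, size in zip(offsets, sizes)
            ]
            cds: List[GenomicInterval] = []
            if thick_end > thick_start:
                for e in exons:
                    s, t = max(e.start, thick_start), min(e.end, thick_end)
                    if s < t:
                        cds.append(GenomicInterval(chrom, s, t, strand))
            genes.append(
                GeneModel(
                    gene_id=f[3],
                    span=span,
                    exons=tuple(exons),
                    cds=tuple(cds),
                    biotype="protein_coding" if cds else "other",
                )
            )
    return genes


def read_gene_annotation(path: PathLike, dialect: str = "gff3") -> List[GeneModel]:
    """Read gene models from GFF3 (gene/mRNA/exon hierarchy) or BED12.

    Multi-isoform genes collapse to the union span and union exon set; GFF3
    1-based inclusive coordinates are converted to the internal 0-based
    half-open convention here, at the boundary.
    """
    if dialect == "gff3":
        db = gffutils.create_db(
            str(path),
            dbfn=":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
        )
        return _gff3_gene_models(db)
    if dialect == "bed12":
        return _bed12_gene_models(path)
    raise ValueError(f"unknown annotation dialect {dialect!r} (expected 'gff3' or 'bed12')")


def write_gff3(genes: Iterable[GeneModel], path: PathLike) -> None:
    """Write gene models as a minimal gene/mRNA/exon(/CDS) GFF3."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            strand = g.span.strand or "."
            attrs = f"ID={g.gene_id}"
            if g.description:
                attrs += f";description={g.description}"
            attrs += f";gene_biotype={g.biotype}"
            fh.write(
                f"{g.span.contig}\tmbchip\tgene\t{g.span.start + 1}\t{g.span.end}\t.\t{strand}\t.\t{attrs}\n"
            )
            rna_type = "mRNA" if g.biotype == "protein_coding" else "ncRNA"
            rna_id = f"{g.gene_id}.t1"
            fh.write(
                f"{g.span.contig}\tmbchip\t{rna_type}\t{g.span.start + 1}\t{g.span.end}\t.\t{strand}\t.\t"
                f"ID={rna_id};Parent={g.gene_id}\n"
            )
            for i, e in enumerate(g.exons, start=1):
                fh.write(
                    f"{e.contig}\tmbchip\texon\t{e.start + 1}\t{e.end}\t.\t{strand}\t.\t"
                    f"ID={rna_id}.exon{i};Parent={rna_id}\n"
                )
            for i, c in enumerate(g.cds, start=1):
                fh.write(
                    f"{c.contig}\tmbchip\tCDS\t{c.start + 1}\t{c.end}\t.\t{strand}\t0\t"
                    f"ID={rna_id}.cds{i};Parent={rna_id}\n"
                )


# ---------------------------------------------------------------------------
# Tables


def read_count_table(path: PathLike, length_column: Optional[str] = "length") -> CountTable:
    """Read a gene×sample (or cell×gene) TSV count table.

    When ``length_column`` names a column it is split out as per-gene lengths.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    lengths = None
    if length_column is not None and length_column in df.columns:
        lengths = df[length_column].astype(int)
        df = df.drop(columns=[length_column])
    return CountTable(counts=df, lengths=lengths)


def read_cluster_labels(path: PathLike) -> pd.Series:
    """Read a two-column TSV of cell id → cluster label."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.iloc[:, 0]


def read_hit_table(path: PathLike) -> pd.DataFrame:
    """Read a BLAST outfmt-6-like hit table.

    Requires (at least) qseqid, sseqid, bitscore, evalue columns; a headerless
    12-column outfmt 6 file is also accepted.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"qseqid", "sseqid", "bitscore", "evalue"}
    if not required <= set(df.columns):
        outfmt6 = [
            "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
            "qstart", "qend", "sstart", "send", "evalue", "bitscore",
        ]
        df = pd.read_csv(path, sep="\t", header=None)
        if df.shape[1] == 12:
            df.columns = outfmt6
        elif df.shape[1] == 4:
            df.columns = ["qseqid", "sseqid", "bitscore", "evalue"]
        else:
            raise FormatError(
                f"{path}: expected columns {sorted(required)} or 12-column outfmt 6"
            )
    if (df["evalue"] < 0).any():
        raise FormatError(f"{path}: negative e-values")
    return df[["qseqid", "sseqid", "bitscore", "evalue"]].copy()
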