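"""Domain records: ChIP peaks, gene models, count tables, homology hits."""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import pandas as pd

from .regions import GenomicInterval

__all__ = ["Peak", "GeneModel", "CountTable"]


@dataclass(frozen=True)
class Peak:
    """One called ChIP-seq peak (one ENCODE narrowPeak record).

    Scores are stored on the −log10 scale exactly as narrowPeak prints them;
    ``summit_offset`` is ``None`` when the caller reported no point source
    (column 10 = −1).
    """

    interval: GenomicInterval
    name: str
    fold_enrichment: float
    neg_log10_p: float
    neg_log10_q: float
    summit_offset: Optional[int] = None
    score: int = 0

    def __post_init__(self) -> None:
        for label, v in (
            ("fold_enrichment", self.fold_enrichment),
            ("neg_log10_p", self.neg_log10_p),
            ("neg_log10_q", self.neg_log10_q),
        ):
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"peak {self.name}: {label} must be finite and >= 0, got {v}")
        if self.summit_offset is not None:
            if not 0 <= self.summit_offset < self.interval.length:
                raise ValueError(
                    f"peak {self.name}: summit offset {self.summit_offset} outside "
                    f"interval of length {self.interval.length}"
                )

    @property
    def anchor(self) -> int:
        """Best single-base position: summit when present, else the midpoint."""
        if self.summit_offset is not None:
            return self.interval.start + self.summit_offset
        return self.interval.midpoint

    @property
    def q_value(self) -> float:
        return 10.0 ** (-self.neg_log10_q)


@dataclass(frozen=True)
class GeneModel:
    """A gene collapsed to its union span and union exon set.

    Multi-isoform genes are merged because peaks are annotated per gene, not
    per transcript.  The TSS is the 5'-most base of the span given strand.
    """

    gene_id: str
    span: GenomicInterval
    exons: tuple = ()
    cds: tuple = ()
    description: str = ""
    biotype: str = "protein_coding"

    def __post_init__(self) -> None:
        exons = tuple(sorted(self.exons, key=lambda e: e.start))
        object.__setattr__(self, "exons", exons)
        object.__setattr__(self, "cds", tuple(sorted(self.cds, key=lambda e: e.start)))
        prev_end = None
        for e in exons:
            if e.contig != self.span.contig or e.start < self.span.start or e.end > self.span.end:
                raise ValueError(f"gene {self.gene_id}: exon {e} outside span {self.span}")
            if prev_end is not None and e.start < prev_end:
                raise ValueError(f"gene {self.gene_id}: overlapping exons")
            prev_end = e.end

    @property
    def strand(self) -> Optional[str]:
        return self.span.strand

    @property
    def tss(self) -> int:
        """Transcription start site (0-based position of the 5'-most base)."""
        if self.span.strand == "-":
            return self.span.end - 1
        return self.span.start

    def utr_intervals(self) -> tuple:
        """(five_prime_utrs, three_prime_utrs) derived from exons minus CDS.

        Empty when no CDS is annotated — UTR labels are only meaningful for
        genes with coding annotation.
        """
        if not self.cds or not self.exons:
            return (), ()
        cds_start = min(c.start for c in self.cds)
        cds_end = max(c.end for c in self.cds)
        left: List[GenomicInterval] = []
        right: List[GenomicInterval] = []
        for e in self.exons:
            if e.start < cds_start:
                left.append(
                    GenomicInterval(e.contig, e.start, min(e.end, cds_start), e.strand)
                )
            if e.end > cds_end:
                right.append(
                    GenomicInterval(e.contig, max(e.start, cds_end), e.end, e.strand)
                )
        if self.span.strand == "-":
            return tuple(right), tuple(left)
        return tuple(left), tuple(right)


@dataclass
class CountTable:
    """A nonnegative integer count matrix with optional per-gene lengths.

    ``counts`` rows are genes (bulk) or cells (single-cell); ``lengths`` is
    indexed by gene id where present.
    """

    counts: pd.DataFrame
    lengths: Optional[pd.Series] = None

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("count table contains negative entries")
        if self.lengths is not None and (self.lengths <= 0).any():
            bad = self.lengths[self.lengths <= 0].index.tolist()
            raise ValueError(f"non-positive gene lengths for {bad[:5]}")
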