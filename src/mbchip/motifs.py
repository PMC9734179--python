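"""Motif counting and TSS-upstream window extraction.

The counting rule matches how GA-rich binding sites are tallied in promoter
scans of this kind: every start position is counted, overlaps allowed, so
``GAGAG`` contains one GAGA and two GAGs.  Motif specs may use IUPAC
degenerate codes and at most one parenthesized optional base, e.g.
``AT(C)TTTGTA`` expands to ATTTTGTA and ATCTTTGTA.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import pandas as pd

from .models import GeneModel
from .regions import GenomicInterval

__all__ = [
    "MotifSpec",
    "UpstreamRecord",
    "count_overlapping",
    "extract_upstream",
    "scan_motif",
    "species_motif_table",
    "GAGA_MOTIFS",
    "UPSTREAM_WINDOWS",
]

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC", "B": "CGT", "D": "AGT",
    "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

GAGA_MOTIFS = (("GAGA", "GAGA"), ("GAG", "GAG"))
UPSTREAM_WINDOWS = (2000, 10000)


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def count_overlapping(sequence: str, motif: str) -> int:
    """Count motif occurrences allowing overlap (exact match, N never matches).

    Implemented with a zero-width regex lookahead so every start position is
    examined; ``count_overlapping("GAGAG", "GAG") == 2``.
    """
    if not motif:
        raise ValueError("motif must be non-empty")
    if not sequence:
        return 0
    return len(re.findall(f"(?={re.escape(motif.upper())})", sequence.upper()))


@dataclass(frozen=True)
class MotifSpec:
    """A named motif pattern over IUPAC codes with ≤1 optional base.

    ``AT(C)TTTGTA`` expands to the two plain patterns ATTTTGTA / ATCTTTGTA.
    """

    name: str
    pattern: str

    def expansions(self) -> List[str]:
        pats = [self.pattern.upper()]
        m = re.search(r"\(([A-Z])\)", pats[0])
        if m:
            with_base = pats[0][: m.start()] + m.group(1) + pats[0][m.end():]
            without = pats[0][: m.start()] + pats[0][m.end():]
            pats = [without, with_base]
        if any("(" in p or ")" in p for p in pats):
            raise ValueError(f"motif {self.name}: at most one parenthesized optional base")
        for p in pats:
            if len(p) < 2:
                raise ValueError(f"motif {self.name}: expanded pattern {p!r} too short")
            for ch in p:
                if ch not in IUPAC:
                    raise ValueError(f"motif {self.name}: invalid IUPAC code {ch!r}")
        return pats

    def regexes(self) -> List[str]:
        return ["".join(f"[{IUPAC[c]}]" if len(IUPAC[c]) > 1 else IUPAC[c] for c in p)
                for p in self.expansions()]


def scan_motif(
    sequence: str,
    spec: MotifSpec,
    count_both_strands: bool = False,
) -> Tuple[List[Tuple[int, str]], int]:
    """Find all overlap-allowed matches of a motif spec.

    Returns ``(positions, count)`` where positions are ``(start, strand)``
    on forward-strand coordinates, deduplicated per (position, strand).
    By default only the given (gene-sense) strand is scanned.
    """
    seq = sequence.upper()
    hits = set()
    for rx in spec.regexes():
        for m in re.finditer(f"(?=({rx}))", seq):
            hits.add((m.start(), "+"))
    if count_both_strands:
        for p in spec.expansions():
            rc = reverse_complement(p)
            rx = "".join(f"[{IUPAC[c]}]" if len(IUPAC[c]) > 1 else IUPAC[c] for c in rc)
            for m in re.finditer(f"(?=({rx}))", seq):
                hits.add((m.start(), "-"))
    positions = sorted(hits)
    return positions, len(positions)


def reverse_complement_pattern(pattern: str) -> str:
    return reverse_complement(pattern)


@dataclass(frozen=True)
class UpstreamRecord:
    """A TSS-upstream window, oriented 5'→3' with respect to the gene."""

    subject: str
    window_length: int
    sequence: str
    interval: GenomicInterval
    clipped: bool

    @property
    def effective_length(self) -> int:
        """Non-N bases actually available for motif counting."""
        return len(self.sequence) - self.sequence.count("N")


def extract_upstream(
    gene: GeneModel,
    genome: Dict[str, str],
    length: int,
    subject: Optional[str] = None,
) -> UpstreamRecord:
    """Extract the ``length`` bases immediately 5' of the gene's TSS.

    For '−' strand genes the window lies at higher genomic coordinates and
    is reverse-complemented so the returned sequence reads 5'→3' in gene
    orientation.  Windows are clipped at contig ends and flagged.
    """
    contig = gene.span.contig
    if contig not in genome:
        raise KeyError(f"contig {contig!r} not present in the genome")
    if gene.span.strand not in ("+", "-"):
        raise ValueError(f"gene {gene.gene_id} has no strand; TSS-upstream window undefined")
    seq = genome[contig]
    tss = gene.tss
    if gene.span.strand == "+":
        lo, hi = tss - length, tss
        clipped = lo < 0
        lo = max(0, lo)
        window = seq[lo:hi].upper()
    else:
        lo, hi = tss + 1, tss + 1 + length
        clipped = hi > len(seq)
        hi = min(len(seq), hi)
        window = reverse_complement(seq[lo:hi].upper())
    return UpstreamRecord(
        subject=subject or gene.gene_id,
        window_length=length,
        sequence=window,
        interval=GenomicInterval(contig, lo, hi, gene.span.strand),
        clipped=clipped,
    )


def species_motif_table(
    upstream_records: Sequence[UpstreamRecord],
    motifs: Sequence[Tuple[str, str]] = GAGA_MOTIFS,
    window_lengths: Sequence[int] = UPSTREAM_WINDOWS,
) -> pd.DataFrame:
    """Per-subject overlap-allowed motif counts over the window cross-product.

    Rows cover every subject × motif × window length; a subject with no
    upstream record for a window is reported with a missing count (absent),
    never silently as zero.  Row order is deterministic.
    """
    by_key: Dict[Tuple[str, int], UpstreamRecord] = {}
    subjects: List[str] = []
    for rec in upstream_records:
        key = (rec.subject, rec.window_length)
        if key in by_key:
            raise ValueError(f"duplicate upstream record for {key}")
        by_key[key] = rec
        if rec.subject not in subjects:
            subjects.append(rec.subject)
    rows = []
    for subject in subjects:
        for window in window_lengths:
            rec = by_key.get((subject, window))
            for motif_name, pattern in motifs:
                rows.append(
                    {
                        "subject": subject,
                        "window_length": window,
                        "motif": motif_name,
                        "count": count_overlapping(rec.sequence, pattern)
                        if rec is not None
                        else pd.NA,
                        "effective_length": rec.effective_length if rec is not None else pd.NA,
                    }
                )
    return pd.DataFrame(rows, columns=["subject", "window_length", "motif", "count", "effective_length"])
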