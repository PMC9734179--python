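"""Genomic coordinate primitives.

All coordinates inside the package are 0-based half-open; the 1-based
inclusive convention used by GFF3 and ``contig:first-last`` region strings
is converted exactly once, at the I/O boundary.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Optional

__all__ = [
    "GenomicInterval",
    "parse_region_string",
    "format_region_string",
    "overlap",
    "gap_distance",
    "intersection",
]

_REGION_RE = re.compile(r"^(?P<contig>[^:\s]+):(?P<first>\d+)-(?P<last>\d+)$")


class RegionParseError(ValueError):
    """Raised when a region string does not parse."""


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval ``[start, end)`` on ``contig``.

    ``strand`` is ``"+"``, ``"-"`` or ``None`` (unstranded).
    """

    contig: str
    start: int
    end: int
    strand: Optional[str] = None

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start {self.start} on {self.contig}")
        if self.start >= self.end:
            raise ValueError(
                f"empty or inverted interval {self.contig}:[{self.start}, {self.end})"
            )
        if self.strand not in (None, "+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def contains(self, position: int) -> bool:
        return self.start <= position < self.end

    def shifted(self, offset: int) -> "GenomicInterval":
        return GenomicInterval(self.contig, self.start + offset, self.end + offset, self.strand)


def parse_region_string(text: str) -> GenomicInterval:
    """Parse a 1-based inclusive ``contig:first-last`` region string.

    ``"NC_037652.1:7063408-7063595"`` denotes a 188-bp region and becomes
    the 0-based half-open interval ``[7063407, 7063595)``.
    """
    m = _REGION_RE.match(text.strip())
    if m is None:
        raise RegionParseError(f"malformed region string: {text!r}")
    first = int(m.group("first"))
    last = int(m.group("last"))
    if first < 1:
        raise RegionParseError(f"1-based coordinate must be >= 1, got {first} in {text!r}")
    if first > last:
        raise RegionParseError(f"region start {first} exceeds end {last} in {text!r}")
    return GenomicInterval(m.group("contig"), first - 1, last)


def format_region_string(interval: GenomicInterval) -> str:
    """Inverse of :func:`parse_region_string` (1-based inclusive output)."""
    return f"{interval.contig}:{interval.start + 1}-{interval.end}"


def overlap(a: GenomicInterval, b: GenomicInterval) -> int:
    """Number of bases shared by two intervals (0 across contigs)."""
    if a.contig != b.contig:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def gap_distance(a: GenomicInterval, b: GenomicInterval) -> int:
    """Bases strictly between two same-contig intervals; 0 when they touch or overlap."""
    if a.contig != b.contig:
        raise ValueError(f"gap_distance undefined across contigs {a.contig} / {b.contig}")
    return max(0, max(a.start, b.start) - min(a.end, b.end))


def intersection(a: GenomicInterval, b: GenomicInterval) -> Optional[GenomicInterval]:
    """The shared interval, or ``None`` when the two do not overlap."""
    if overlap(a, b) == 0:
        return None
    return GenomicInterval(a.contig, max(a.start, b.start), min(a.end, b.end))
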