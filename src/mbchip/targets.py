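"""Peak-to-gene target assignment and condition comparison.

A gene is a target candidate of a reconciled signal when the signal's
representative interval overlaps the gene span extended by the window
(default ±10 kb) — i.e. the signal lies within 10 kb upstream or downstream
of the gene.  Position labels (5'UTR/3'UTR/Exon/Intron/Upstream/Downstream)
are decided at the signal center only, so each (signal, gene) pair gets
exactly one label.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Dict, FrozenSet, Iterable, List, Optional, Sequence, Set, Tuple

import pandas as pd
from intervaltree import IntervalTree

from .models import GeneModel
from .reconcile import ReconciledPeak
from .regions import GenomicInterval, overlap

__all__ = [
    "TargetAssignment",
    "TargetSetComparison",
    "assign_targets",
    "classify_position",
    "rank_signal_report",
    "compare_target_sets",
    "round_half_up_percent",
    "target_gene_ids",
]

DEFAULT_WINDOW = 10_000

POSITION_LABELS = ("5'UTR", "3'UTR", "Exon", "Intron", "Upstream", "Downstream")


@dataclass(frozen=True)
class TargetAssignment:
    """One (signal, gene) annotation row; gene fields are None for orphan signals."""

    signal: ReconciledPeak
    gene_id: Optional[str]
    position_label: Optional[str]
    signed_distance: Optional[int]
    gene: Optional[GeneModel] = None


def classify_position(signal: ReconciledPeak, gene: GeneModel) -> str:
    """Label the signal's position relative to one gene.

    Inside the span the priority is UTR > Exon > Intron, evaluated at the
    signal center.  Outside, Upstream/Downstream follow gene orientation;
    strandless genes default to '+' with a warning.
    """
    center = signal.center
    strand = gene.span.strand
    if strand is None:
        warnings.warn(
            f"gene {gene.gene_id} has no strand; assuming '+' for Upstream/Downstream"
        )
        strand = "+"
    if gene.span.contains(center):
        utr5, utr3 = gene.utr_intervals()
        if any(u.contains(center) for u in utr5):
            return "5'UTR"
        if any(u.contains(center) for u in utr3):
            return "3'UTR"
        if any(e.contains(center) for e in gene.exons):
            return "Exon"
        return "Intron"
    if center < gene.span.start:
        return "Upstream" if strand == "+" else "Downstream"
    return "Downstream" if strand == "+" else "Upstream"


def _signed_distance(signal: ReconciledPeak, gene: GeneModel, label: str) -> int:
    """Edge-to-edge gap, signed negative on the upstream side (0 inside)."""
    iv = signal.representative.interval
    if overlap(iv, gene.span) > 0 or gene.span.contains(signal.center):
        return 0
    gap = max(gene.span.start - iv.end, iv.start - gene.span.end, 0)
    return -gap if label == "Upstream" else gap


def assign_targets(
    signals: Sequence[ReconciledPeak],
    genes: Sequence[GeneModel],
    window: int = DEFAULT_WINDOW,
) -> List[TargetAssignment]:
    """Assign every reconciled signal to all genes within ±``window`` bp.

    Every qualifying gene is emitted (one signal can have several side-
    numbered genes); a signal with no gene in range yields an explicit
    orphan record with ``gene_id=None``.
    """
    if window < 0:
        raise ValueError(f"window must be >= 0, got {window}")
    trees: Dict[str, IntervalTree] = {}
    for idx, g in enumerate(genes):
        tree = trees.setdefault(g.span.contig, IntervalTree())
        tree.addi(g.span.start - window, g.span.end + window, idx)

    out: List[TargetAssignment] = []
    for sig in signals:
        iv = sig.representative.interval
        hits = trees.get(sig.contig, IntervalTree()).overlap(iv.start, iv.end)
        gene_hits = sorted(hits, key=lambda h: (genes[h.data].span.start, genes[h.data].gene_id))
        if not gene_hits:
            out.append(TargetAssignment(sig, None, None, None))
            continue
        for h in gene_hits:
            gene = genes[h.data]
            label = classify_position(sig, gene)
            out.append(
                TargetAssignment(
                    signal=sig,
                    gene_id=gene.gene_id,
                    position_label=label,
                    signed_distance=_signed_distance(sig, gene, label),
                    gene=gene,
                )
            )
    return out


def rank_signal_report(
    assignments: Sequence[TargetAssignment], top_n: int = 20
) -> pd.DataFrame:
    """Rank signals by −log10(q) descending and expand multi-gene signals.

    Mirrors the top-N signal table layout: fold enrichment and −log10(q) are
    shown on the first row of each signal; additional genes within the window
    get side-numbered rows (e.g. 2-1, 2-2).  Ties break by fold enrichment
    descending, then contig/coordinate.
    """
    if top_n < 1:
        raise ValueError(f"top_n must be >= 1, got {top_n}")
    by_signal: Dict[int, List[TargetAssignment]] = {}
    order: List[ReconciledPeak] = []
    for a in assignments:
        key = id(a.signal)
        if key not in by_signal:
            by_signal[key] = []
            order.append(a.signal)
        by_signal[key].append(a)

    ranked = sorted(
        order,
        key=lambda s: (
            -s.representative.neg_log10_q,
            -s.representative.fold_enrichment,
            s.contig,
            s.representative.interval.start,
        ),
    )[:top_n]

    rows = []
    for rank, sig in enumerate(ranked, start=1):
        assigns = by_signal[id(sig)]
        multi = len(assigns) > 1
        for side, a in enumerate(assigns, start=1):
            rows.append(
                {
                    "gene_no": f"{rank}-{side}" if multi else str(rank),
                    "gene_id": a.gene_id if a.gene_id is not None else "-",
                    "description": (a.gene.description if a.gene is not None else "-"),
                    "fold_enrichment": sig.representative.fold_enrichment if side == 1 else None,
                    "neg_log10_q": sig.representative.neg_log10_q if side == 1 else None,
                    "position": a.position_label if a.position_label is not None else "-",
                    "contig": sig.contig,
                    "center": sig.center,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "gene_no", "gene_id", "description", "fold_enrichment",
            "neg_log10_q", "position", "contig", "center",
        ],
    )


def round_half_up_percent(fraction: float) -> int:
    """Percentage rounded half-up to the nearest integer (138/263 → 52)."""
    return int(Decimal(fraction * 100).quantize(Decimal("1"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class TargetSetComparison:
    """Set algebra between two condition-level target-gene catalogs."""

    set_a: FrozenSet[str]
    set_b: FrozenSet[str]
    common: FrozenSet[str]
    a_specific: FrozenSet[str]
    b_specific: FrozenSet[str]

    @property
    def frac_a_specific(self) -> float:
        return len(self.a_specific) / len(self.set_a) if self.set_a else 0.0

    @property
    def frac_b_specific(self) -> float:
        return len(self.b_specific) / len(self.set_b) if self.set_b else 0.0

    @property
    def percent_a_specific(self) -> int:
        return round_half_up_percent(self.frac_a_specific)

    @property
    def percent_b_specific(self) -> int:
        return round_half_up_percent(self.frac_b_specific)


def compare_target_sets(a: Iterable[str], b: Iterable[str]) -> TargetSetComparison:
    """Exact set algebra between two target-gene id sets."""
    sa, sb = frozenset(a), frozenset(b)
    return TargetSetComparison(
        set_a=sa,
        set_b=sb,
        common=sa & sb,
        a_specific=sa - sb,
        b_specific=sb - sa,
    )


def target_gene_ids(assignments: Iterable[TargetAssignment]) -> Set[str]:
    """The condition-level unique target-gene set from an assignment list."""
    return {a.gene_id for a in assignments if a.gene_id is not None}
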