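"""Replicate peak reconciliation.

Two biological ChIP replicates are reconciled under the rule that peaks are
reproducible when their anchors (summit when called, else midpoint) lie
within 1 kb on the same contig.  Matching is globally optimal: among all
maximum-cardinality one-to-one matchings of eligible pairs, the one with
minimal total anchor distance is returned, so results do not depend on input
order the way greedy nearest-neighbour matching does.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .models import Peak
from .regions import GenomicInterval

__all__ = [
    "ReconciledPeak",
    "filter_peaks_by_q",
    "reconcile_replicates",
    "extract_peak_window",
    "PeakWindow",
    "reconciled_to_frame",
    "write_reconciled_tsv",
    "read_reconciled_tsv",
]

DEFAULT_MAX_DISTANCE = 1000
DEFAULT_FLANK = 150


@dataclass(frozen=True)
class ReconciledPeak:
    """A reproducible signal: one peak from each replicate within the bound.

    ``representative`` is the member with the larger −log10(q) (i.e. the more
    significant call); ``center`` is the midpoint of the two anchors and is
    the point from which motif-discovery windows are cut.
    """

    peak_a: Peak
    peak_b: Peak
    anchor_distance: int
    representative: Peak
    center: int

    @property
    def contig(self) -> str:
        return self.peak_a.interval.contig


def filter_peaks_by_q(peaks: Sequence[Peak], q_max: float) -> List[Peak]:
    """Keep peaks more significant than ``q_max`` (order preserved).

    The threshold is converted to the −log10 scale once; a peak passes when
    its stored ``neg_log10_q`` strictly exceeds −log10(q_max).
    """
    if not 0 < q_max <= 1:
        raise ValueError(f"q_max must be in (0, 1], got {q_max}")
    threshold = -math.log10(q_max)
    return [p for p in peaks if p.neg_log10_q > threshold]


def _match_one_contig(
    anchors_a: np.ndarray, anchors_b: np.ndarray, max_distance: int
) -> List[Tuple[int, int]]:
    """Max-cardinality min-total-distance matching on one contig.

    Ineligible pairs (distance > max_distance) get a big-M cost so the
    assignment first maximizes the number of eligible pairs, then minimizes
    their summed distance.
    """
    na, nb = len(anchors_a), len(anchors_b)
    if na == 0 or nb == 0:
        return []
    dist = np.abs(anchors_a[:, None].astype(np.int64) - anchors_b[None, :].astype(np.int64))
    eligible = dist <= max_distance
    big_m = int(dist[eligible].sum()) + max_distance + 1 if eligible.any() else 1
    cost = np.where(eligible, dist, big_m)
    rows, cols = linear_sum_assignment(cost)
    return [(i, j) for i, j in zip(rows, cols) if eligible[i, j]]


def reconcile_replicates(
    rep_a: Sequence[Peak],
    rep_b: Sequence[Peak],
    max_distance: int = DEFAULT_MAX_DISTANCE,
) -> Tuple[List[ReconciledPeak], List[Peak], List[Peak]]:
    """Reconcile two replicate peak lists.

    Returns ``(reconciled, unmatched_a, unmatched_b)``.  A pair is eligible
    iff both peaks share a contig and their anchors are within
    ``max_distance`` bp (inclusive).  Output is sorted by (contig, lower
    anchor) for determinism.
    """
    if max_distance < 0:
        raise ValueError(f"max_distance must be >= 0, got {max_distance}")
    by_contig_a: Dict[str, List[int]] = {}
    by_contig_b: Dict[str, List[int]] = {}
    for i, p in enumerate(rep_a):
        by_contig_a.setdefault(p.interval.contig, []).append(i)
    for j, p in enumerate(rep_b):
        by_contig_b.setdefault(p.interval.contig, []).append(j)

    reconciled: List[ReconciledPeak] = []
    matched_a: set = set()
    matched_b: set = set()
    for contig in sorted(set(by_contig_a) & set(by_contig_b)):
        ia = by_contig_a[contig]
        ib = by_contig_b[contig]
        anchors_a = np.array([rep_a[i].anchor for i in ia])
        anchors_b = np.array([rep_b[j].anchor for j in ib])
        for li, lj in _match_one_contig(anchors_a, anchors_b, max_distance):
            i, j = ia[li], ib[lj]
            pa, pb = rep_a[i], rep_b[j]
            rep = pa if pa.neg_log10_q >= pb.neg_log10_q else pb
            reconciled.append(
                ReconciledPeak(
                    peak_a=pa,
                    peak_b=pb,
                    anchor_distance=abs(pa.anchor - pb.anchor),
                    representative=rep,
                    center=(pa.anchor + pb.anchor) // 2,
                )
            )
            matched_a.add(i)
            matched_b.add(j)
    reconciled.sort(key=lambda r: (r.contig, min(r.peak_a.anchor, r.peak_b.anchor)))
    unmatched_a = [p for i, p in enumerate(rep_a) if i not in matched_a]
    unmatched_b = [p for j, p in enumerate(rep_b) if j not in matched_b]
    return reconciled, unmatched_a, unmatched_b


@dataclass(frozen=True)
class PeakWindow:
    """A fixed-width forward-strand window around a reconciled-signal center."""

    name: str
    interval: GenomicInterval
    sequence: str
    clipped: bool


def extract_peak_window(
    genome: Dict[str, str],
    signal: ReconciledPeak,
    flank: int = DEFAULT_FLANK,
    name: Optional[str] = None,
) -> PeakWindow:
    """Extract the ``[center − flank, center + flank)`` window (forward strand).

    Windows running past a contig edge are clipped and flagged; the returned
    sequence is upper-cased.
    """
    contig = signal.contig
    if contig not in genome:
        raise KeyError(f"contig {contig!r} not present in the genome")
    seq = genome[contig]
    lo = signal.center - flank
    hi = signal.center + flank
    clipped = lo < 0 or hi > len(seq)
    lo_c, hi_c = max(0, lo), min(len(seq), hi)
    window_name = name or f"{contig}:{lo_c}-{hi_c}"
    return PeakWindow(
        name=window_name,
        interval=GenomicInterval(contig, lo_c, hi_c),
        sequence=seq[lo_c:hi_c].upper(),
        clipped=clipped,
    )


# ---------------------------------------------------------------------------
# Tabular round-trip for the CLI


def reconciled_to_frame(signals: Iterable[ReconciledPeak]) -> pd.DataFrame:
    rows = []
    for s in signals:
        rep = s.representative
        rows.append(
            {
                "contig": s.contig,
                "center": s.center,
                "anchor_distance": s.anchor_distance,
                "rep_start": rep.interval.start,
                "rep_end": rep.interval.end,
                "rep_name": rep.name,
                "fold_enrichment": rep.fold_enrichment,
                "neg_log10_p": rep.neg_log10_p,
                "neg_log10_q": rep.neg_log10_q,
                "rep_summit": -1 if rep.summit_offset is None else rep.summit_offset,
                "name_a": s.peak_a.name,
                "name_b": s.peak_b.name,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "contig", "center", "anchor_distance", "rep_start", "rep_end", "rep_name",
            "fold_enrichment", "neg_log10_p", "neg_log10_q", "rep_summit",
            "name_a", "name_b",
        ],
    )


def write_reconciled_tsv(signals: Iterable[ReconciledPeak], path: Union[str, Path]) -> None:
    reconciled_to_frame(signals).to_csv(path, sep="\t", index=False)


def read_reconciled_tsv(path: Union[str, Path]) -> List[ReconciledPeak]:
    """Rehydrate reconciled signals from the TSV written by the reconcile stage.

    Both replicate slots are filled with the representative peak; center and
    anchor distance are taken from the file, so downstream target assignment
    and window extraction behave identically.
    """
    df = pd.read_csv(path, sep="\t")
    out: List[ReconciledPeak] = []
    for row in df.itertuples(index=False):
        rep = Peak(
            interval=GenomicInterval(row.contig, int(row.rep_start), int(row.rep_end)),
            name=str(row.rep_name),
            fold_enrichment=float(row.fold_enrichment),
            neg_log10_p=float(row.neg_log10_p),
            neg_log10_q=float(row.neg_log10_q),
            summit_offset=None if int(row.rep_summit) < 0 else int(row.rep_summit),
        )
        out.append(
            ReconciledPeak(
                peak_a=rep,
                peak_b=rep,
                anchor_distance=int(row.anchor_distance),
                representative=rep,
                center=int(row.center),
            )
        )
    return out
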