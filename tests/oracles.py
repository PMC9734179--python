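"""Independent brute-force oracles used by the test suite.

These deliberately avoid the implementation's code paths: per-base set
membership for interval arithmetic, every-start-position enumeration for
motif counting, a bitmask dynamic program for replicate matching, all-pairs
scans for target assignment, and the literal mutual-best definition for RBH.
"""

from functools import lru_cache
from typing import Dict, List, Sequence, Tuple

import pandas as pd


def bases_covered(start: int, end: int) -> set:
    return set(range(start, end))


def overlap_by_membership(a, b) -> int:
    if a.contig != b.contig:
        return 0
    return len(bases_covered(a.start, a.end) & bases_covered(b.start, b.end))


def gap_by_membership(a, b) -> int:
    """Bases strictly between two same-contig intervals, counted one by one."""
    if overlap_by_membership(a, b) > 0:
        return 0
    lo = min(a.end, b.end)
    hi = max(a.start, b.start)
    return sum(
        1
        for pos in range(lo, hi)
        if pos not in bases_covered(a.start, a.end)
        and pos not in bases_covered(b.start, b.end)
    )


def count_every_start(sequence: str, motif: str) -> int:
    sequence, motif = sequence.upper(), motif.upper()
    return sum(
        1
        for i in range(len(sequence) - len(motif) + 1)
        if sequence[i : i + len(motif)] == motif
    )


def optimal_matching(anchors_a: Sequence[int], anchors_b: Sequence[int], max_distance: int):
    """Exhaustive optimum over all one-to-one assignments via bitmask DP.

    Returns (cardinality, total_distance) of the maximum-cardinality,
    minimum-total-distance matching of eligible pairs (|d| <= max_distance).
    """
    m = len(anchors_b)

    @lru_cache(maxsize=None)
    def best(i: int, mask: int) -> Tuple[int, int]:
        if i == len(anchors_a):
            return (0, 0)
        res = best(i + 1, mask)  # leave a_i unmatched
        for j in range(m):
            if mask >> j & 1:
                continue
            d = abs(anchors_a[i] - anchors_b[j])
            if d > max_distance:
                continue
            c, t = best(i + 1, mask | (1 << j))
            cand = (c + 1, t + d)
            if cand[0] > res[0] or (cand[0] == res[0] and cand[1] < res[1]):
                res = cand
        return res

    out = best(0, 0)
    best.cache_clear()
    return out


def all_pairs_targets(signals, genes, window: int):
    """Qualifying (signal index, gene_id) pairs by scanning every pair."""
    pairs = set()
    for si, sig in enumerate(signals):
        iv = sig.representative.interval
        for g in genes:
            if g.span.contig != iv.contig:
                continue
            ext_start = g.span.start - window
            ext_end = g.span.end + window
            if min(iv.end, ext_end) > max(iv.start, ext_start):
                pairs.add((si, g.gene_id))
    return pairs


def rbh_by_definition(a2b: pd.DataFrame, b2a: pd.DataFrame):
    """Reciprocal best hits straight from the definition."""

    def best_map(df: pd.DataFrame) -> Dict[str, str]:
        out: Dict[str, str] = {}
        for q in df["qseqid"].unique():
            sub = df[df["qseqid"] == q]
            sub = sub.sort_values(
                by=["bitscore", "evalue", "sseqid"], ascending=[False, True, True]
            )
            out[q] = sub.iloc[0]["sseqid"]
        return out

    fwd, rev = best_map(a2b), best_map(b2a)
    return {(a, b) for a, b in fwd.items() if rev.get(b) == a}
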