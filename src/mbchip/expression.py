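"""Expression integration: ranking, cluster markers, target intersection, RBH.

Marker detection follows the conventional single-cell one-vs-rest recipe:
per-cell counts are normalized to counts-per-10k and log1p-transformed, the
effect size is the log2 fold change of cluster mean vs rest mean (pseudocount
1 on the CP10K scale), genes passing the expressed-fraction and effect
filters are tested with a two-sided Wilcoxon rank-sum test, and p-values are
Bonferroni-adjusted over all genes in the matrix (Benjamini–Hochberg is
available as an alternative).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, FrozenSet, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .models import CountTable, GeneModel

__all__ = [
    "rank_by_length_normalized",
    "find_markers",
    "intersect_targets_with_markers",
    "reciprocal_best_hits",
    "CandidateBreakdown",
    "gene_lengths_from_models",
]

DEFAULT_LKC_CLUSTERS = frozenset({1, 2, 6, 7})


def gene_lengths_from_models(genes: Sequence[GeneModel]) -> pd.Series:
    """Gene length = union-exon length when exons exist, else the genomic span."""
    lengths = {}
    for g in genes:
        if g.exons:
            lengths[g.gene_id] = sum(e.length for e in g.exons)
        else:
            lengths[g.gene_id] = g.span.length
    return pd.Series(lengths, name="length")


def rank_by_length_normalized(
    counts: CountTable,
    top_n: int = 40,
    sample: Optional[str] = None,
) -> pd.DataFrame:
    """Rank genes by count divided by gene length, descending.

    Ties break by raw count descending then gene id lexicographic, so the
    ranking is invariant to input row order.  Genes without a length are
    excluded with a warning.
    """
    if top_n < 1:
        raise ValueError(f"top_n must be >= 1, got {top_n}")
    if counts.lengths is None:
        raise ValueError("count table has no gene lengths")
    col = sample if sample is not None else counts.counts.columns[0]
    raw = counts.counts[col]
    have_length = raw.index.intersection(counts.lengths.index)
    n_excluded = len(raw.index) - len(have_length)
    if n_excluded:
        warnings.warn(f"{n_excluded} genes excluded from ranking (missing length)")
    df = pd.DataFrame(
        {
            "gene_id": have_length,
            "raw_count": raw.loc[have_length].to_numpy(),
            "length": counts.lengths.loc[have_length].to_numpy(),
        }
    )
    df["normalized_value"] = df["raw_count"] / df["length"]
    df = df.sort_values(
        by=["normalized_value", "raw_count", "gene_id"],
        ascending=[False, False, True],
        kind="mergesort",
    ).head(top_n)
    df["rank"] = np.arange(1, len(df) + 1)
    return df.reset_index(drop=True)[["rank", "gene_id", "raw_count", "length", "normalized_value"]]


def _adjust(p: np.ndarray, n_tests: int, method: str) -> np.ndarray:
    if method == "bonferroni":
        return np.minimum(p * n_tests, 1.0)
    if method == "bh":
        # BH over the actually-tested p-values
        order = np.argsort(p)
        ranked = p[order] * len(p) / (np.arange(len(p)) + 1)
        ranked = np.minimum.accumulate(ranked[::-1])[::-1]
        out = np.empty_like(p)
        out[order] = np.minimum(ranked, 1.0)
        return out
    raise ValueError(f"unknown correction {method!r} (expected 'bonferroni' or 'bh')")


def find_markers(
    matrix: CountTable,
    labels: pd.Series,
    min_frac: float = 0.1,
    min_effect: float = 0.25,
    alpha: float = 0.05,
    correction: str = "bonferroni",
    min_cells: int = 3,
) -> pd.DataFrame:
    """One-vs-rest cluster marker detection on a cells×genes count matrix.

    Returns one row per (cluster, tested gene) with effect size (log2 fold
    change), Wilcoxon rank-sum p, adjusted p, expressed fractions and an
    ``is_marker`` flag (p_adj < alpha and positive effect direction is NOT
    required: the flag follows the adjusted p-value and the effect filter,
    which is two-sided).
    """
    X = matrix.counts
    labels = labels.reindex(X.index)
    if labels.isna().any():
        raise ValueError("cluster labels missing for some cells")
    clusters = sorted(labels.unique())
    sizes = labels.value_counts()
    usable = [c for c in clusters if sizes[c] >= min_cells]
    dropped = [c for c in clusters if sizes[c] < min_cells]
    if dropped:
        warnings.warn(f"clusters {dropped} excluded (fewer than {min_cells} cells)")
    if len(usable) < 2:
        raise ValueError("marker detection requires at least 2 clusters with enough cells")

    raw = X.to_numpy(dtype=float)
    libsize = raw.sum(axis=1, keepdims=True)
    libsize[libsize == 0] = 1.0
    cp10k = raw / libsize * 1e4
    log_expr = np.log1p(cp10k)
    n_genes = raw.shape[1]
    genes = X.columns.to_numpy()

    rows: List[pd.DataFrame] = []
    for cluster in usable:
        in_mask = (labels == cluster).to_numpy()
        n_in = int(in_mask.sum())
        n_out = int((~in_mask).sum())
        frac_in = (raw[in_mask] > 0).mean(axis=0)
        frac_out = (raw[~in_mask] > 0).mean(axis=0)
        mean_in = cp10k[in_mask].mean(axis=0)
        mean_out = cp10k[~in_mask].mean(axis=0)
        effect = np.log2((mean_in + 1.0) / (mean_out + 1.0))
        tested = (frac_in >= min_frac) & (np.abs(effect) >= min_effect)
        if not tested.any():
            continue
        x = log_expr[np.ix_(in_mask, tested)]
        y = log_expr[np.ix_(~in_mask, tested)]
        res = stats.mannwhitneyu(x, y, alternative="two-sided", axis=0)
        p = np.asarray(res.pvalue, dtype=float)
        p_adj = _adjust(p, n_genes, correction)
        rows.append(
            pd.DataFrame(
                {
                    "gene_id": genes[tested],
                    "cluster": cluster,
                    "effect": effect[tested],
                    "p": p,
                    "p_adj": np.maximum(p_adj, p),
                    "frac_in": frac_in[tested],
                    "frac_out": frac_out[tested],
                    "n_in": n_in,
                    "n_out": n_out,
                }
            )
        )
    if not rows:
        return pd.DataFrame(
            columns=["gene_id", "cluster", "effect", "p", "p_adj",
                     "frac_in", "frac_out", "n_in", "n_out", "is_marker"]
        )
    out = pd.concat(rows, ignore_index=True)
    out["is_marker"] = out["p_adj"] < alpha
    return out


@dataclass(frozen=True)
class CandidateBreakdown:
    """Target genes that are markers in ≥1 configured cluster, bucketed by
    how many of those clusters they mark (3+, 2, or 1)."""

    candidates: FrozenSet[str]
    cluster_counts: Dict[str, int]
    bucket_3plus: FrozenSet[str]
    bucket_2: FrozenSet[str]
    bucket_1: FrozenSet[str]

    @property
    def bucket_sizes(self) -> Dict[str, int]:
        return {"3+": len(self.bucket_3plus), "2": len(self.bucket_2), "1": len(self.bucket_1)}


def intersect_targets_with_markers(
    target_gene_ids: Iterable[str],
    markers: pd.DataFrame,
    lkc_clusters: Iterable[int] = DEFAULT_LKC_CLUSTERS,
    positive_only: bool = True,
) -> CandidateBreakdown:
    """Intersect ChIP target candidates with cluster markers.

    Candidates are targets flagged as markers — by default with a positive
    effect, i.e. *higher* expression — in at least one of the configured
    (large-Kenyon-cell) clusters; each candidate is bucketed by the number
    of those clusters in which it is a marker.
    """
    lkc = set(lkc_clusters)
    observed = set(markers["cluster"].unique())
    if not lkc <= observed:
        raise ValueError(f"clusters {sorted(lkc - observed)} not present in the marker table")
    flagged = markers[(markers["is_marker"]) & (markers["cluster"].isin(lkc))]
    if positive_only and "effect" in flagged.columns:
        flagged = flagged[flagged["effect"] > 0]
    counts = flagged.groupby("gene_id")["cluster"].nunique()
    targets = set(target_gene_ids)
    candidate_counts = {g: int(c) for g, c in counts.items() if g in targets}
    b3 = frozenset(g for g, c in candidate_counts.items() if c >= 3)
    b2 = frozenset(g for g, c in candidate_counts.items() if c == 2)
    b1 = frozenset(g for g, c in candidate_counts.items() if c == 1)
    return CandidateBreakdown(
        candidates=frozenset(candidate_counts),
        cluster_counts=candidate_counts,
        bucket_3plus=b3,
        bucket_2=b2,
        bucket_1=b1,
    )


def _best_hits(table: pd.DataFrame) -> pd.Series:
    """Best subject per query: max bitscore, then min e-value, then subject id."""
    df = table.copy()
    dup = df.duplicated(subset=["qseqid", "sseqid"], keep=False)
    if dup.any():
        warnings.warn("duplicate (query, subject) hit rows; keeping the best-scoring one")
        df = (
            df.sort_values(["bitscore", "evalue"], ascending=[False, True], kind="mergesort")
            .drop_duplicates(subset=["qseqid", "sseqid"], keep="first")
        )
    df = df.sort_values(
        by=["qseqid", "bitscore", "evalue", "sseqid"],
        ascending=[True, False, True, True],
        kind="mergesort",
    )
    best = df.drop_duplicates(subset="qseqid", keep="first")
    return best.set_index("qseqid")[["sseqid", "bitscore"]]


def reciprocal_best_hits(a2b: pd.DataFrame, b2a: pd.DataFrame) -> pd.DataFrame:
    """Reciprocal-best-hit ortholog pairs from two directed hit tables.

    A pair (a, b) is emitted iff b is a's best hit in ``a2b`` and a is b's
    best hit in ``b2a``.  Queries with no hit are dropped.
    """
    best_ab = _best_hits(a2b)
    best_ba = _best_hits(b2a)
    rows = []
    for a, rec in best_ab.iterrows():
        b = rec["sseqid"]
        if b in best_ba.index and best_ba.loc[b, "sseqid"] == a:
            rows.append(
                {
                    "id_a": a,
                    "id_b": b,
                    "score_a2b": float(rec["bitscore"]),
                    "score_b2a": float(best_ba.loc[b, "bitscore"]),
                }
            )
    return (
        pd.DataFrame(rows, columns=["id_a", "id_b", "score_a2b", "score_b2a"])
        .sort_values("id_a", kind="mergesort")
        .reset_index(drop=True)
    )
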