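"""Seeded generators for every input the pipeline consumes.

Each generator is a pure function of its seed and parameters (same seed,
same bytes) and returns the planted ground truth alongside the artifact, so
parameter-recovery tests can check the pipeline end to end without any
external download.  The defaults emulate the study conditions the pipeline
was built for: two jittered ChIP replicates sharing true peaks plus
replicate-specific noise, an insect-like low-GC genome with multi-exon genes
on both strands, TSS-upstream windows with planted GA-rich motif densities,
negative-binomial single-cell counts with planted per-cluster markers, and
homology hit tables with planted mutual-best pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .models import CountTable, GeneModel, Peak
from .motifs import count_overlapping
from .regions import GenomicInterval

__all__ = [
    "generate_genome",
    "plant_upstream_motifs",
    "generate_gene_models",
    "generate_replicate_peaks",
    "generate_sc_counts",
    "generate_hit_tables",
    "generate_chip_study",
    "ChipStudyTruth",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")


def generate_genome(
    seed: int, contigs: Dict[str, int], gc: float = 0.35
) -> Dict[str, str]:
    """Random genome with the given contig lengths and GC content.

    The default GC of 0.35 is typical of hymenopteran assemblies.
    """
    if not 0 < gc < 1:
        raise ValueError(f"gc must be in (0, 1), got {gc}")
    rng = np.random.default_rng(seed)
    at = (1 - gc) / 2
    p = [at, gc / 2, gc / 2, at]
    genome = {}
    for name, length in contigs.items():
        if length <= 0:
            raise ValueError(f"contig {name}: length must be positive")
        genome[name] = rng.choice(_BASES, size=length, p=p).tobytes().decode()
    return genome


def plant_upstream_motifs(
    genome: Dict[str, str],
    window: GenomicInterval,
    gaga_n: int,
    gag_n: int,
    seed: int,
) -> Tuple[Dict[str, str], Dict[str, int]]:
    """Plant GAGA/GAG occurrences into a window and record realized counts.

    Motifs are written at random non-adjacent positions (≥1 background base
    between placements).  Because the background can contain additional
    occurrences, and every GAGA contains a GAG, the returned truth records
    the *realized* overlap-allowed counts recomputed with the same counter
    the pipeline uses — not the requested numbers.
    """
    if window.contig not in genome:
        raise KeyError(f"contig {window.contig!r} not in genome")
    items = ["GAGA"] * gaga_n + ["GAG"] * gag_n
    footprint = sum(len(m) + 1 for m in items)
    if footprint > window.length:
        raise ValueError(
            f"cannot plant {gaga_n} GAGA + {gag_n} GAG in a {window.length}-bp window"
        )
    rng = np.random.default_rng(seed)
    rng.shuffle(items)
    free = window.length - footprint
    gaps = rng.multinomial(free, [1.0 / (len(items) + 1)] * (len(items) + 1)) if items else []
    seq = list(genome[window.contig])
    pos = window.start
    for gap, item in zip(gaps, items):
        pos += int(gap)
        seq[pos : pos + len(item)] = item
        pos += len(item) + 1
    new_genome = dict(genome)
    new_genome[window.contig] = "".join(seq)
    planted_window = new_genome[window.contig][window.start : window.end]
    truth = {
        "requested_gaga": gaga_n,
        "requested_gag": gag_n,
        "realized_gaga": count_overlapping(planted_window, "GAGA"),
        "realized_gag": count_overlapping(planted_window, "GAG"),
    }
    return new_genome, truth


def generate_gene_models(
    seed: int,
    contig_lengths: Dict[str, int],
    n_genes: int = 30,
    min_spacing: int = 30_000,
    gene_length_range: Tuple[int, int] = (2_000, 8_000),
    exon_range: Tuple[int, int] = (2, 4),
    margin: int = 15_000,
) -> List[GeneModel]:
    """Place non-overlapping multi-exon genes on both strands.

    Gene starts are at least ``min_spacing`` apart so each gene's ±10-kb
    neighbourhood is unambiguous; a ``margin`` keeps upstream windows inside
    the contig.  Roughly every fourth gene is emitted as a non-coding model
    (no CDS record).
    """
    rng = np.random.default_rng(seed)
    contigs = sorted(contig_lengths)
    max_glen = gene_length_range[1]
    # fixed slots pitch apart guarantee the spacing even after jitter
    pitch = min_spacing + max_glen
    slots = []
    for contig in contigs:
        usable = contig_lengths[contig] - 2 * margin - max_glen
        for k in range(max(0, usable) // pitch + (1 if usable >= 0 else 0)):
            slots.append((contig, margin + k * pitch))
    if len(slots) < n_genes:
        raise ValueError("could not place the requested number of genes; enlarge contigs")
    chosen = [slots[i] for i in rng.choice(len(slots), size=n_genes, replace=False)]
    genes: List[GeneModel] = []
    for contig, slot_start in chosen:
        glen = int(rng.integers(gene_length_range[0], gene_length_range[1] + 1))
        start = slot_start + int(rng.integers(0, max_glen - glen + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        n_exons = int(rng.integers(exon_range[0], exon_range[1] + 1))
        # split the gene into alternating exon/intron blocks
        cuts = np.sort(rng.choice(np.arange(1, glen), size=2 * n_exons - 2, replace=False))
        bounds = [0, *cuts.tolist(), glen]
        exons = [
            GenomicInterval(contig, start + bounds[2 * i], start + bounds[2 * i + 1], strand)
            for i in range(n_exons)
        ]
        gene_id = f"LOC{900000 + len(genes):06d}"
        coding = rng.random() < 0.75
        cds: List[GenomicInterval] = []
        if coding and exons:
            # CDS = exons minus a short UTR at each end of the gene
            utr5 = int(rng.integers(50, 300))
            utr3 = int(rng.integers(50, 300))
            cds_lo = start + min(utr5, glen // 4)
            cds_hi = start + glen - min(utr3, glen // 4)
            for e in exons:
                s, t = max(e.start, cds_lo), min(e.end, cds_hi)
                if s < t:
                    cds.append(GenomicInterval(contig, s, t, strand))
        genes.append(
            GeneModel(
                gene_id=gene_id,
                span=GenomicInterval(contig, start, start + glen, strand),
                exons=tuple(exons),
                cds=tuple(cds),
                description=f"synthetic gene {len(genes)}",
                biotype="protein_coding" if cds else "ncRNA",
            )
        )
    genes.sort(key=lambda g: (g.span.contig, g.span.start))
    return genes


def _peak_scores(rng: np.random.Generator) -> Tuple[float, float, float]:
    fold = round(float(rng.uniform(3.0, 8.0)), 3)
    nlp = round(float(rng.uniform(6.0, 60.0)), 3)
    nlq = round(nlp - float(rng.uniform(0.5, 3.0)), 3)
    return fold, nlp, nlq


def _make_peak(
    rng: np.random.Generator,
    contig: str,
    contig_len: int,
    anchor: int,
    name: str,
) -> Peak:
    half = int(rng.integers(150, 301))
    start = max(0, anchor - half)
    end = min(contig_len, anchor + half)
    fold, nlp, nlq = _peak_scores(rng)
    return Peak(
        interval=GenomicInterval(contig, start, end),
        name=name,
        fold_enrichment=fold,
        neg_log10_p=nlp,
        neg_log10_q=nlq,
        summit_offset=anchor - start,
        score=int(min(1000, nlq * 10)),
    )


def generate_replicate_peaks(
    truth_anchors: Sequence[Tuple[str, int]],
    contig_lengths: Dict[str, int],
    jitter_sd: float = 50.0,
    n_noise_per_rep: int = 10,
    seed: int = 0,
    noise_clearance: int = 2_500,
) -> Tuple[List[Peak], List[Peak], Dict]:
    """Two replicate peak sets sharing jittered true peaks plus noise.

    Each true anchor appears in both replicates with an independent summit
    jitter clipped to ±500 bp (so the pair stays within the 1-kb rule).
    Noise peaks are placed at least ``noise_clearance`` bp from every true
    anchor and from each other (across both replicates), so reconciliation
    recovery on this fixture is exact.
    """
    rng = np.random.default_rng(seed)
    reps: Tuple[List[Peak], List[Peak]] = ([], [])
    truth_pairs = []
    for idx, (contig, anchor) in enumerate(truth_anchors):
        clen = contig_lengths[contig]
        jitters = np.clip(rng.normal(0.0, jitter_sd, size=2), -500, 500).astype(int)
        pair_anchors = []
        for r, jit in enumerate(jitters):
            a = int(np.clip(anchor + jit, 400, clen - 400))
            reps[r].append(_make_peak(rng, contig, clen, a, f"rep{'ab'[r]}_true{idx}"))
            pair_anchors.append(a)
        truth_pairs.append({"contig": contig, "anchor": anchor, "replicate_anchors": pair_anchors})

    exclusion: Dict[str, List[int]] = {}
    for contig, anchor in truth_anchors:
        exclusion.setdefault(contig, []).append(anchor)
    contigs = sorted(contig_lengths)
    noise_records = {0: [], 1: []}
    for r in range(2):
        placed = 0
        guard = 0
        while placed < n_noise_per_rep and guard < n_noise_per_rep * 1000:
            guard += 1
            contig = contigs[int(rng.integers(len(contigs)))]
            clen = contig_lengths[contig]
            pos = int(rng.integers(500, clen - 500))
            if any(abs(pos - a) < noise_clearance for a in exclusion.get(contig, [])):
                continue
            exclusion.setdefault(contig, []).append(pos)
            reps[r].append(_make_peak(rng, contig, clen, pos, f"rep{'ab'[r]}_noise{placed}"))
            noise_records[r].append({"contig": contig, "anchor": pos})
            placed += 1
        if placed < n_noise_per_rep:
            raise ValueError("could not place noise peaks; enlarge contigs or reduce count")
    truth = {
        "true_pairs": truth_pairs,
        "noise_a": noise_records[0],
        "noise_b": noise_records[1],
    }
    return reps[0], reps[1], truth


def generate_sc_counts(
    n_clusters: int = 4,
    cells_per_cluster: int = 100,
    n_genes: int = 2_000,
    markers_per_cluster: int = 5,
    fold: float = 8.0,
    nb_dispersion: float = 0.5,
    seed: int = 0,
    cluster_ids: Optional[Sequence[int]] = None,
    marker_min_base_mean: float = 0.5,
) -> Tuple[CountTable, pd.Series, Dict[int, List[str]]]:
    """Negative-binomial cell×gene counts with planted per-cluster markers.

    Marker genes have cluster mean = ``fold`` × base mean; counts follow a
    Gamma–Poisson mixture with var = mu + dispersion·mu².  Markers are
    planted only in genes whose base mean is at least
    ``marker_min_base_mean`` — a marker is by definition a detectably
    expressed gene.  ``fold=1`` (or ``markers_per_cluster=0``) gives an
    exchangeable global null.
    """
    if nb_dispersion <= 0:
        raise ValueError(f"nb_dispersion must be > 0, got {nb_dispersion}")
    if fold < 1:
        raise ValueError(f"fold must be >= 1, got {fold}")
    rng = np.random.default_rng(seed)
    ids = list(cluster_ids) if cluster_ids is not None else list(range(n_clusters))
    if len(ids) != n_clusters:
        raise ValueError("cluster_ids length must equal n_clusters")
    base_mean = np.exp(rng.normal(0.3, 1.0, size=n_genes))
    gene_ids = [f"gene{g:05d}" for g in range(n_genes)]
    marker_truth: Dict[int, List[str]] = {c: [] for c in ids}
    eligible = np.flatnonzero(base_mean >= marker_min_base_mean)
    n_needed = markers_per_cluster * n_clusters
    if n_needed > len(eligible):
        raise ValueError("not enough sufficiently expressed genes to plant markers")
    marker_gene_idx = rng.choice(eligible, size=n_needed, replace=False)
    for k, c in enumerate(ids):
        chosen = marker_gene_idx[k * markers_per_cluster : (k + 1) * markers_per_cluster]
        marker_truth[c] = [gene_ids[g] for g in chosen]

    n_cells = n_clusters * cells_per_cluster
    mu = np.tile(base_mean, (n_cells, 1))
    labels = np.repeat(ids, cells_per_cluster)
    for k, c in enumerate(ids):
        rows = labels == c
        cols = marker_gene_idx[k * markers_per_cluster : (k + 1) * markers_per_cluster]
        mu[np.ix_(rows, cols)] *= fold
    shape = 1.0 / nb_dispersion
    lam = rng.gamma(shape, mu * nb_dispersion)
    counts = rng.poisson(lam)
    cell_ids = [f"cell{i:05d}" for i in range(n_cells)]
    table = CountTable(counts=pd.DataFrame(counts, index=cell_ids, columns=gene_ids))
    label_series = pd.Series(labels, index=cell_ids, name="cluster")
    return table, label_series, marker_truth


def generate_hit_tables(
    n_a: int,
    n_b: int,
    n_true_pairs: int,
    seed: int = 0,
    decoys_per_query: int = 3,
) -> Tuple[pd.DataFrame, pd.DataFrame, List[Tuple[str, str]]]:
    """Two directed homology hit tables with planted mutual-best pairs.

    Planted pairs get dominant bitscores (decoys never exceed them).  Every
    non-planted query's best hit points at a planted subject (or, with no
    planted pairs, at a shifted partner), so no accidental reciprocal pair
    arises; requires ≥3 ids per side when ``n_true_pairs == 0``.
    """
    if n_true_pairs > min(n_a, n_b):
        raise ValueError("n_true_pairs cannot exceed min(n_a, n_b)")
    if n_true_pairs == 0 and min(n_a, n_b) < 3:
        raise ValueError("the zero-pair construction needs at least 3 ids per side")
    rng = np.random.default_rng(seed)
    ids_a = [f"A{i:04d}" for i in range(n_a)]
    ids_b = [f"B{j:04d}" for j in range(n_b)]
    pairs = [(ids_a[i], ids_b[i]) for i in range(n_true_pairs)]

    def decoy_rows(query: str, subjects: List[str], best_subject: str, best_score: float):
        rows = [
            {"qseqid": query, "sseqid": best_subject, "bitscore": best_score,
             "evalue": float(10 ** -rng.uniform(20, 80))}
        ]
        pool = [s for s in subjects if s != best_subject]
        k = min(decoys_per_query, len(pool))
        for s in rng.choice(pool, size=k, replace=False):
            rows.append(
                {"qseqid": query, "sseqid": str(s),
                 "bitscore": round(float(rng.uniform(50, 150)), 1),
                 "evalue": float(10 ** -rng.uniform(2, 15))}
            )
        return rows

    a2b_rows, b2a_rows = [], []
    for i, a in enumerate(ids_a):
        if i < n_true_pairs:
            best, score = ids_b[i], round(float(rng.uniform(200, 400)), 1)
        elif n_true_pairs > 0:
            best, score = ids_b[int(rng.integers(n_true_pairs))], round(float(rng.uniform(150, 199)), 1)
        else:
            best, score = ids_b[(i + 1) % n_b], round(float(rng.uniform(150, 199)), 1)
        a2b_rows.extend(decoy_rows(a, ids_b, best, score))
    for j, b in enumerate(ids_b):
        if j < n_true_pairs:
            best, score = ids_a[j], round(float(rng.uniform(200, 400)), 1)
        elif n_true_pairs > 0:
            best, score = ids_a[int(rng.integers(n_true_pairs))], round(float(rng.uniform(150, 199)), 1)
        else:
            best, score = ids_a[(j + 2) % n_a], round(float(rng.uniform(150, 199)), 1)
        b2a_rows.extend(decoy_rows(b, ids_a, best, score))
    return pd.DataFrame(a2b_rows), pd.DataFrame(b2a_rows), pairs


@dataclass
class ChipStudyTruth:
    """Planted ground truth for a full synthetic ChIP study."""

    seed: int
    peak_truth: Dict
    pupal_peak_truth: Dict
    target_genes: List[str]
    pupal_target_genes: List[str]
    orphan_peaks: int
    gene_ids: List[str]

    def to_dict(self) -> Dict:
        return {
            "seed": self.seed,
            "peak_truth": self.peak_truth,
            "pupal_peak_truth": self.pupal_peak_truth,
            "target_genes": self.target_genes,
            "pupal_target_genes": self.pupal_target_genes,
            "orphan_peaks": self.orphan_peaks,
            "gene_ids": self.gene_ids,
        }


def generate_chip_study(
    seed: int,
    n_contigs: int = 3,
    contig_length: int = 400_000,
    n_genes: int = 24,
    n_targeted: int = 16,
    n_orphans: int = 4,
    n_noise_per_rep: int = 8,
    pupal_shared_fraction: float = 0.5,
    window: int = 10_000,
    gc: float = 0.35,
) -> Tuple[Dict[str, str], List[GeneModel], Dict[str, List[Peak]], ChipStudyTruth]:
    """A complete two-condition synthetic ChIP study with known targets.

    True adult peaks are planted near ``n_targeted`` genes (within the
    ±``window`` rule) plus ``n_orphans`` peaks far from every gene; the
    pupal condition reuses a fraction of the adult peaks and adds
    pupal-specific ones near otherwise-untargeted genes, mirroring the
    shared/specific structure a condition comparison should recover.
    """
    rng = np.random.default_rng(seed)
    contigs = {f"ctg{i + 1}": contig_length for i in range(n_contigs)}
    genome = generate_genome(int(rng.integers(2**31)), contigs, gc=gc)
    genes = generate_gene_models(int(rng.integers(2**31)), contigs, n_genes=n_genes)
    if n_targeted + n_orphans > len(genes):
        raise ValueError("not enough genes to host the requested peaks")

    order = rng.permutation(len(genes))
    adult_idx = order[:n_targeted]
    n_pupal_shared = int(round(n_targeted * pupal_shared_fraction))
    pupal_new_idx = order[n_targeted : n_targeted + max(0, n_targeted - n_pupal_shared)]

    def anchor_near(gene: GeneModel) -> Tuple[str, int]:
        offset = int(rng.integers(-(window - 1_000), window - 1_000))
        if rng.random() < 0.5:  # put some peaks inside the gene body
            pos = int(rng.integers(gene.span.start, gene.span.end))
        else:
            pos = gene.span.start + offset if offset < 0 else gene.span.end + offset
        return gene.span.contig, int(np.clip(pos, 1_000, contig_length - 1_000))

    adult_anchors = [anchor_near(genes[i]) for i in adult_idx]
    # orphan peaks: mid-gap positions at least window + 1 kb from every gene span
    orphan_anchors: List[Tuple[str, int]] = []
    guard = 0
    while len(orphan_anchors) < n_orphans and guard < n_orphans * 2000:
        guard += 1
        contig = f"ctg{int(rng.integers(n_contigs)) + 1}"
        pos = int(rng.integers(1_000, contig_length - 1_000))
        clear = all(
            g.span.contig != contig
            or not (g.span.start - window - 1_000 <= pos <= g.span.end + window + 1_000)
            for g in genes
        )
        if clear and all(
            c != contig or abs(pos - a) > 3_000 for c, a in adult_anchors + orphan_anchors
        ):
            orphan_anchors.append((contig, pos))
    if len(orphan_anchors) < n_orphans:
        raise ValueError("could not place orphan peaks; enlarge contigs")

    shared = adult_anchors[:n_pupal_shared]
    pupal_anchors = shared + [anchor_near(genes[i]) for i in pupal_new_idx]

    rep_a, rep_b, adult_truth = generate_replicate_peaks(
        adult_anchors + orphan_anchors,
        contigs,
        n_noise_per_rep=n_noise_per_rep,
        seed=int(rng.integers(2**31)),
    )
    pup_a, pup_b, pupal_truth = generate_replicate_peaks(
        pupal_anchors,
        contigs,
        n_noise_per_rep=n_noise_per_rep,
        seed=int(rng.integers(2**31)),
    )
    truth = ChipStudyTruth(
        seed=seed,
        peak_truth=adult_truth,
        pupal_peak_truth=pupal_truth,
        target_genes=sorted(genes[i].gene_id for i in adult_idx),
        pupal_target_genes=sorted(
            genes[i].gene_id for i in list(adult_idx[:n_pupal_shared]) + list(pupal_new_idx)
        ),
        orphan_peaks=n_orphans,
        gene_ids=[g.gene_id for g in genes],
    )
    replicates = {"adult_a": rep_a, "adult_b": rep_b, "pupal_a": pup_a, "pupal_b": pup_b}
    return genome, genes, replicates, truth
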