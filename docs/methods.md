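# Methods

This note documents the models, rules and numerical choices behind each
stage, what the synthetic-data generators do and do not emulate, and the
design decisions taken where the procedure was genuinely open.

## Coordinates and formats

All internal coordinates are 0-based half-open intervals; 1-based inclusive
conventions (GFF3, `contig:first-last` region strings) are converted exactly
once at the I/O boundary, so a region string such as
`NC_037652.1:7063408-7063595` is a 188-bp interval and formats back to the
identical text. narrowPeak −log₁₀ scores are stored as printed; q-value
thresholds are converted to the −log₁₀ scale once, at filter time.
Multi-isoform genes collapse to their union span and union exon set because
peaks are annotated per gene, not per transcript; overlapping genes are all
retained, and no winner is chosen. UTR intervals are derived as exon
territory outside the CDS hull and are emitted only when CDS records exist;
without coding annotation a center inside an exon is labelled `Exon`.

## Replicate reconciliation

Two replicate peak lists are matched one-to-one per contig. A pair is
eligible when the anchors are ≤ 1000 bp apart (inclusive); the anchor is the
summit when the caller reported one (MACS2's best position estimate), else
the interval midpoint, and the choice is configurable. Among eligible
pairings the matching maximizes the number of pairs and, among those,
minimizes the total anchor distance (Jonker–Volgenant assignment with a
big-M cost on ineligible pairs). A greedy nearest-neighbour rule can differ
on crowded loci and is order-sensitive, which is why the global optimum is
used; output order is fixed by (contig, lower anchor). The representative
peak of a pair is the member with the larger −log₁₀(q) — top-signal tables
rank by the smallest q-values, so the representative carries the statistics
a report shows. The signal center is the midpoint of the two anchors;
motif-discovery input is the ±150-bp (300-bp) window around it, clipped and
flagged at contig edges.

## Target assignment and condition comparison

Qualification and classification are deliberately separated: a gene
qualifies when the representative peak interval overlaps the gene span
extended by the 10-kb window on both sides (edge overlap, not
center-distance — a signal region near a gene makes that gene a candidate),
while the position label is decided at the single signal center so that each
(signal, gene) pair gets exactly one label with priority UTR > Exon >
Intron inside the span. Signals with no gene in range produce explicit
orphan records, and multi-gene signals expand to side-numbered report rows.
Strandless genes default to '+' for Upstream/Downstream labelling, with a
warning. Whether the original window was measured from peak edge or summit
is not recoverable; edge overlap is the default here. Condition
comparisons are exact set algebra on gene ids; displayed percentages round
half-up to integers (138/263 → 52%).

## Motif counting and upstream windows

Counting is exact-string matching at every start position with overlaps
allowed (`GAGAG` = one GAGA + two GAGs), implemented with a zero-width
regex lookahead and property-tested against the naive enumeration. `N`
never matches; windows overlapping assembly gaps report their effective
(non-N) length. Upstream windows of 2 kb and 10 kb are cut immediately 5′
of the TSS and oriented 5′→3′ with respect to the gene, so '−'-strand
windows are reverse-complemented. Counting is done on this gene-sense
strand only by default — upstream flanks served by annotation databases
are gene-oriented — and a both-strands mode is provided, which can only
increase counts. Motif specs accept IUPAC codes and at most one
parenthesized optional base: `AT(C)TTTGTA` expands to ATTTTGTA and
ATCTTTGTA. For multi-isoform genes the TSS is the 5′-most isoform start
(the union-span convention); species whose homolog has several annotated
isoforms can shift counts under a different convention. Per-species tables
cover the full subject × motif × window cross-product, reporting a missing
upstream record as absent, never as zero.

## Expression integration

Bulk ranking divides a gene's count by its length and keeps the top 40;
ties break by raw count, then gene id, making the ranking invariant to
input order. "Gene length" is the union-exon length when exon structure is
available, else the genomic span — the convention is configurable because
published length-normalized rankings rarely state it, and ranks of
borderline genes can depend on it.

Marker detection mirrors the standard single-cell one-vs-rest recipe:
per-cell counts are normalized to counts-per-10k and log1p-transformed
(a deliberate simplification of variance-stabilizing transforms, which are
out of scope); genes are prefiltered to those expressed in ≥ 10% of the
cluster's cells with |log₂ fold change| ≥ 0.25 (cluster mean vs rest mean
on the CP10K scale, pseudocount 1); the two-sided Wilcoxon rank-sum test is
applied per gene, and p-values are Bonferroni-adjusted over all genes in
the matrix (Benjamini–Hochberg available). Clusters with fewer than 3
cells are excluded with a warning. The target–marker intersection counts a
gene as a candidate when it is a *positive*-effect marker (higher
expression) in at least one configured Kenyon-cell cluster — default
clusters {1, 2, 6, 7} — and buckets candidates by whether they mark 3+, 2,
or 1 of those clusters; the buckets partition the candidate set.

Reciprocal best hits take each query's best subject by bitscore, breaking
ties by smaller e-value then lexicographic subject id; duplicate
(query, subject) rows keep the best-scoring one with a warning. The output
is symmetric under swapping table roles.

## Synthetic data: what it emulates, and what it does not

The generators are pure functions of seed and parameters (byte-identical
reruns) and record planted truth sufficient to predict every deterministic
downstream output exactly.

- **Genome**: i.i.d. bases at 35% GC, typical of hymenopteran assemblies.
  No repeats, assembly gaps (unless planted as N), or compositional
  heterogeneity.
- **Genes**: multi-exon models on both strands placed on a jittered grid
  with ≥ 30 kb between gene starts, so each ±10-kb neighbourhood contains
  at most one gene and planted target catalogs are unambiguous. Roughly a
  quarter of genes are emitted as non-coding (no CDS).
- **Replicate peaks**: each true anchor appears in both replicates with
  independent Gaussian summit jitter (SD 50 bp, clipped at ±500 so pairs
  always satisfy the 1-kb rule); noise peaks are placed > 2.5 kb from every
  true anchor *and from each other across replicates*, so reconciliation
  recovery is exact by construction. Peak scores are internally consistent
  (−log₁₀ q ≤ −log₁₀ p) and pass the default q filters. Real ChIP noise is
  not this polite; near-miss ambiguity (noise 1–2 kb from true peaks) is a
  stress case, not the default fixture.
- **Planted motifs**: GAGA/GAG instances are written at random positions
  with ≥ 1 background base between placements; because background sequence
  and the GAG inside every GAGA also count, the generator re-counts the
  window with the pipeline's own counter and records *realized* values —
  the invariant tested is realized-equals-recount, not realized-equals-
  requested.
- **Single-cell counts**: Gamma–Poisson (negative binomial) with
  var = μ + 0.5·μ², lognormal base means, 100 cells per cluster; markers
  are planted at fold 8 in genes with base mean ≥ 0.5, since a marker is by
  definition a detectably expressed gene. No library-size variation,
  dropout model, doublets or batch effects — cluster labels are inputs to
  the real pipeline, and none of those artefacts affect the rank-sum
  arithmetic being verified.
- **Hit tables**: planted mutual-best pairs receive dominant bitscores
  (200–400) over decoys (50–199); non-planted queries' best hits point at
  planted subjects (or shifted partners when no pairs are planted), so no
  accidental reciprocal pair can arise.

Passing these tests shows the *rules* are implemented correctly and
recover planted structure perfectly under clean conditions; it does not
certify performance on real data with ambiguous peaks, fragmented
assemblies, or uncorrected single-cell artefacts.

## Simulation sizes and statistical checks

Marker power is estimated over 100 simulation replicates (4 clusters × 100
cells, 500 genes, one planted fold-8 marker per cluster, dispersion 0.5)
and required to reach ≥ 0.95; the observed power is 1.0. Type-I control
uses 50 exchangeable-null replicates at 2000 genes: the per-family
(per-cluster) false-marker rate must stay within the Bonferroni α = 0.05
plus three standard errors of Monte-Carlo slack. These problem sizes were
chosen so the full suite runs in seconds while leaving the per-replicate
conditions (cells, fold, dispersion) at their stated values.

## Catalog-scale results requiring external data

Numbers tied to the original sequencing data are documented rather than
recomputed: the 593 adult and 263 pupal target-gene counts (and the 138
pupal-specific genes, 52%) require the public ChIP-seq accession processed
through read alignment and peak calling, both outside this package's
scope; the per-species upstream GAGA/GAG counts (e.g. the sawfly's 41 GAGs
within 2 kb versus > 100 GAGs and > 30 GAGAs in aculeate species) require
the listed genome assemblies; and the bulk-expression rank of Mblk-1 (38th)
requires the public mushroom-body RNA-seq counts. The package's operations
reproduce each of these computations given those inputs — `compare`,
`motif-count` and `rank` respectively — and the acceptance script verifies
the printed set arithmetic and all desk-scale rules exactly.

## Known limitations

- Reconciliation optimizes summed anchor distance; when multiple optima
  tie, the reported pairing is deterministic but one of several equally
  valid sets (tests compare cardinality and total distance).
- The rank-sum test is asymptotic; for clusters of just a few cells its
  p-values are approximate, and the 3-cell floor is a pragmatic cutoff.
- BED12 carries no gene descriptions or biotypes; cross-dialect equality
  is structural (span, exons, CDS, TSS).
- The both-strands motif mode deduplicates by (position, strand), so a
  palindromic site counts once per strand by design.
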