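# Methods

This note documents the models and procedures implemented in
`cageatlas`, the defaults and why they were chosen, what the synthetic
panel does and does not emulate, and the numerical choices that affect
results.

## Coordinates and formats

All internal coordinates are 0-based half-open. GFF3 input (1-based
inclusive) is converted on load; BED and bedGraph are handled natively.
Canonical interchange for tag signal is text (BED6 single-bp 5′ records
with score = count, or `.plus.bedGraph`/`.minus.bedGraph` pairs)
because integer counts round-trip bit-exactly, which the tests rely on.
Methylation input is a CGmap-dialect TSV (contig, C/G strand
nucleotide, 1-based position, context, dinucleotide, level, methylated
count, coverage).

## CTPM normalisation

`CTPM = count / total_mapped × 10⁶` per sample. The invariant
Σ CTPM = 10⁶ (absolute tolerance 10⁻³ in tests) is exact up to float
summation order. Pooling across samples sums either raw counts or CTPM;
the pooled clustering signal defaults to CTPM so that deeply sequenced
tissues do not dominate cluster boundaries, with `mode="raw"`
available.

## Uni-directional TSS clustering

Per contig and strand, maximal runs of nonzero positions with
consecutive gaps ≤ `merge_dist` become clusters. `merge_dist` defaults
to 20 bp, the conventional promoter-clustering neighbourhood; clustering
is deterministic and order-independent, and the cluster count is
non-increasing in `merge_dist` (property-tested). The peak is the
pooled-signal argmax, ties resolved to the 5′-most position on the
cluster strand so the rule is strand-symmetric.

Filtering is two-stage, in this order: (1) clusters with pooled raw
count < `min_cluster_count` (10) are removed; (2) a cluster must be
*present* in ≥ `representation_min_tissues` tissues, computed as
⌊n × 2/3⌋ by default — 37 for a 56-tissue panel. Presence defaults to
raw count ≥ 10; `ctpm_gt_10` is available because an expression-based
presence rule (> 10 CTPM) is equally defensible, and the two differ only
for libraries whose depth is far from 10⁶. The count filter is applied
at cluster level; a per-bp pre-filter option exists but is off by
default since single-bp thresholds interact badly with positional
jitter of initiation.

Tissue-specific clusters use the complementary rule — > 10 tags in
exactly one tissue, no representation filter — mirroring how
single-tissue candidates must be screened when no replicates exist.

## Bi-directional (TSS-Enhancer) detection

For a candidate midpoint *m* with window halfwidth *w* = 200 bp, the
arms are minus-strand [m − w, m) and plus-strand (m, m + w]. With the
4-way tally (upstream−, downstream+, upstream+, downstream−) normalised
to proportions **p**, the balance is the Bhattacharyya coefficient
against the ideal divergent profile (½, ½, 0, 0):

    B = √(0.5·p_um) + √(0.5·p_dp)

B is scale-invariant, 1 for perfectly divergent signal and √0.5 ≈ 0.707
when all tags sit on a single divergent arm. Candidate midpoints are
*every* position within one window of signal on either strand — not
only positions carrying signal. This matters: divergent loci produce a
plateau of B = 1 midpoints between their arms, and restricting
candidates to tagged positions biases the called midpoint by roughly
the arm offset, which then corrupts the promoter-distance test. Each
contiguous run of passing candidates (B ≥ 0.95, both divergent arms
nonzero) yields one call at the run centre; the centre is robust to
small interior dips caused by stray tags, where an argmax rule is not.

Retained loci must additionally have a pooled tag count ≥ 10 (the same
cluster-level count rule as uni-directional clusters; without it,
isolated single tags on opposite strands form spurious perfect-balance
pairs) and a midpoint 400–1,000 bp (inclusive) from the nearest
promoter centre (transcript 5′ end). The promoter centre and the
midpoint of the ± 100 bp promoter window coincide by construction here;
if promoter windows are ever made asymmetric the anchor definition must
be revisited.

Co-expression links: every bidirectional–unidirectional pair within
10 kb on a contig is tested with Kendall τ-b over per-sample CTPM
vectors (constant vectors skipped), Benjamini–Hochberg adjusted across
all tested pairs, and reported at q ≤ 0.05. Both the 10 kb reach and
the q cutoff are configuration keys; 10 kb covers the distance band in
which enhancer–promoter co-expression is commonly interpretable, and
BH at 0.05 is the field's default notion of "significant" when nothing
stricter is specified.

## Genomic-region hierarchy

Classes: promoter (± `promoter_halfwidth` = 100 bp around the
transcript 5′ end), proximal (`proximal_length` = 1,000 bp immediately
upstream), fiveUTR, threeUTR, exon, intron, intergenic (everything
beyond the 1 kb margin of any gene model). A position hit by several
classes across overlapping transcripts takes the highest-precedence
class in the order above; the order is configurable but the default
mirrors the biological reading (a promoter position inside another
gene's intron is still a promoter). Promoter/proximal matching is
strand-aware by default with a flag to relax (antisense tags then count
toward sense promoters). Clusters are classified by their peak
position; gene assignment uses promoter-window overlap of the whole
cluster interval. Equivalence with a per-bp brute-force classifier and
the exactly-one-class tiling invariant are tested on random small
annotations.

When a transcript lacks an annotated 5′UTR the transcript 5′ end is
used as the promoter anchor, so unannotated-CDS gene models still get
promoters.

## Novel-vs-annotated TSS

A cluster is *annotated* at range *w* when its interval overlaps the
inclusive window [anchor − w, anchor + w] around any transcript 5′ end;
w = 50 bp (short range) and 400 bp (long range). The boundary is
inclusive: a cluster exactly 50 bp away is annotated. Matching is
strand-agnostic by default (the common overlap-join behaviour);
interval-based rather than peak-based, with a peak-based mode
available. Per-tissue tables count the clusters present in that tissue
(presence rule above) and report % novel at short range.

## Beta-Binomial HMM for hypomethylated regions

After symmetric-CpG merging (+ strand C at p with − strand C at p + 1,
counts summed, reported at p; lone cytosines kept) and a ≥ 10× coverage
filter, each contig chain (broken at CpG gaps > `desert_size` = 1 kb)
is modelled with a two-state HMM whose state-s emission for a site with
coverage n and methylated count m is Beta-Binomial(α_s, β_s):

    log P(m|n) = log C(n,m) + log B(m+α, n−m+β) − log B(α, β)

which accounts for read-depth-dependent confidence in the per-site
methylation level. Baum–Welch EM re-estimates π and the transition
matrix in closed form; the emission shapes are re-estimated each
iteration by Nelder–Mead maximisation of the posterior-weighted
expected log-likelihood in log-parameter space (positivity by
construction). Duplicate (m, n) observations are collapsed with summed
posterior weights first — an exact reformulation that makes each
M-step O(#unique pairs). Initialisation is deterministic (hypo mean
0.2 via (2, 8), hyper mean 0.8 via (8, 2), self-transition 0.99,
uniform π), so no seed is needed; EM stops when the log-likelihood
improves by < 10⁻⁴ or at 100 iterations, returning best-so-far with a
convergence flag. States are relabelled after fitting so state 0 always
has the smaller mean. The forward/backward/Viterbi recursions are
scaled (not log-space) with per-row emission shifting, compiled with
numba.

Hypomethylated regions are maximal Viterbi hypo-state runs of
≥ `min_cpgs` = 3 CpGs, extended 2 bp past the last CpG to cover the
dinucleotide. The per-CpG hypomethylation score exported as bedGraph is
the posterior hypo probability. TSS validation is pure ≥ 1 bp interval
overlap between cluster and region — no score cutoff — yielding the
four categories annotated/novel × +HypoCpG / w/o.

## MI tissue distance

Expression vectors are binned equal-width (n = 10) over their own
[min, max]; a constant vector occupies one bin. Plug-in mutual
information uses natural logs so that δ = √(1 − e^(−2·MI)) equals |ρ|
exactly for bivariate normal data (checked empirically in the tests),
and the distance is d = 1 − δ ∈ [0, 1], strictly decreasing in MI.
Equal-frequency binning is available by flag. Tissue dendrograms use
average linkage on d (the linkage choice is not critical at the
separations involved and average linkage is the least shape-biased
default); trees are exported as Newick with branch lengths. The same
MI-distance path serves both CAGE CTPM and mRNA-Seq TPM matrices. The
CAGE–mRNA sanity check is a plain Pearson correlation over matched
(cluster CTPM, transcript TPM) pairs across shared tissues.

## Synthetic panel: what it emulates, and what it does not

The generator plants, on 2 × 500 kb contigs with 200 single-transcript
genes in fixed 5 kb slots (alternating strands):

* **Widely-shared TSS** at every gene 5′ end, expressed in 45–56 of 56
  tissues with Negative Binomial counts (mean 50, dispersion 0.5 in the
  var = μ + φμ² sense) and ± 2 bp positional jitter. The lower edge of
  the sharing range keeps the 37-of-56 filter operating near its design
  point: with NB dropout below 10 counts (~6 % per tissue), loci planted
  at exactly the threshold would be removed by sampling noise rather
  than by design, so the generator leaves that margin and instead plants
  explicitly under-threshold loci (below).
* **Second promoter TSS** in 10 % of genes, 40 bp inside the promoter
  window (distinct cluster, same gene).
* **Novel TSS** (40 % of retained loci), 1,300–1,750 bp upstream of a
  gene anchor — always > 400 bp from every promoter.
* **Tissue-specific loci** (1 tissue, counts > 10) and
  **tissue-restricted loci** (5–36 tissues): both must be excluded by
  the representation filter.
* **Divergent enhancers** in 20 % of gene slots at 410–990 bp from the
  anchor (arms ± 80 bp, counts tracking the host gene in 15–30 of its
  tissues — eRNA being more tissue-restricted than promoters, which
  also keeps enhancer arm clusters below the uni-directional
  representation threshold), plus decoys at 150–300 bp or
  1,850–2,300 bp that the distance window must reject.
* **Four tissue families** (14 tissues each) realised as
  family-specific cluster blocks (24 loci per family, expressed only in
  that family) plus 4× expression multipliers on half of the shared
  loci; this is the structure the MI dendrogram must recover.
* **Methylation islands** (± 300 bp, dense CpGs at ~12 bp spacing vs
  ~60 bp background) over 90 % of promoters and exactly 30 % of novel
  TSS; island sites draw p ~ Beta(1, 9), background Beta(9, 1),
  per-strand coverage Poisson(10) so merged coverage is Poisson(20).
* **Noise tags** at 10⁻⁵ tags/bp per tissue, count 1 — below every
  filter, but present so the filters have something to do.
* **mRNA TPM tables** (kallisto-style) proportional to the host gene's
  CAGE counts with lognormal noise, for 52 tissues.

Everything derives from one seeded generator; a fixed seed gives
byte-identical files.

Deliberately not emulated: sequence content (CpG islands exist as
coordinates, not sequence), read-level artefacts (mapping ambiguity,
duplicates, bisulfite conversion failure), overlapping gene models,
multi-transcript genes, expression gradients within a cluster wider
than the jitter, and inter-tissue methylation differences (islands are
shared across the WGBS tissues). Passing the planted-recovery tests
therefore demonstrates the correctness of the clustering, filtering,
windowing, segmentation and distance machinery under the stated noise
model — not robustness to alignment artefacts or annotation errors in
real data.

Problem sizes were chosen so the full panel analysis (56 tissues,
1 Mb genome, 8 WGBS tracks of ~28,000 CpGs) completes in tens of
seconds: large enough that all count filters, representation
thresholds and EM fits operate in their intended regimes, small enough
to run everywhere.

## Degenerate inputs and tie-breaks

Empty tag files load but refuse CTPM scaling ("empty library"); empty
pooled signal yields an empty cluster set; all-zero balance tallies are
an error rather than 0; constant expression vectors are skipped in
link testing and map to a single bin in MI; an HMM decode that never
visits the hypo state legitimately returns zero regions; fully
methylated tracks produce no regions. Peak ties break 5′-most on the
cluster strand; balance plateaus break to the centre; greedy
nearest-neighbour matching in recovery scoring breaks ties by distance
then index order.

## Known limitations

* The two-state HMM has no explicit "partially methylated domain"
  state; long intermediate-methylation stretches will be split
  arbitrarily between the two states.
* Links are marginal Kendall tests; no conditioning on shared library
  depth, so strongly co-varying sequencing depth could inflate link
  counts on real data.
* The novelty rule annotates against transcript 5′ ends only;
  unannotated alternative promoters of annotated genes count as novel,
  which is the intended reading but worth remembering when interpreting
  % novel.
* Region classification resolves overlaps by a fixed precedence rather
  than reporting multi-label assignments.
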