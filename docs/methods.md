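# Methods

This note records the statistical model behind each stage, the defaults
and why they were chosen, the numerical details that matter for
reproducing results, and the known limitations. Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Probe-level enrichment: the reflection null

**Model.** A two-channel promoter array yields per-probe log2 intensities
x (input) and y (IP). The only distributional assumption is *symmetry*:
non-enriched probes scatter symmetrically about the diagonal x = y.
Everything below the diagonal is then a sample from (the reflection of)
the null, regardless of its shape or of how spread varies with intensity.

**Normalization.** Dye and amplification bias appear as a smooth trend of
m = y − x against mean intensity a = (x + y)/2. We remove it by lowess
(`span` = 0.3 by default, with the point-combining `delta` set to 1% of
the intensity range so arrays of 10⁵ probes normalize in well under a
second). Probes with a non-positive raw channel are dropped with a logged
warning, never imputed. On an exactly linear bias with span → 1 the
procedure coincides with ordinary least-squares line removal (tested).

**Null model.** With d = (y − x)/√2 the signed perpendicular distance:

- below-diagonal probes (d < 0) are split into 10 equal-count bins by a;
  equal-count (not equal-width) bins are robust to the skewed intensity
  distributions of real arrays;
- the local scale s(a) is a cubic spline through the per-bin robust scale
  1.4826 · median|d| (the MAD about 0, consistent for a Gaussian σ but
  defined without assuming one), clamped to its end values outside the
  fitted range and floored away from zero;
- the null sample is the symmetrized set {±|d|/s(a)} over below-diagonal
  probes; p(z) = (1 + #{v ≥ z}) / (1 + N) is its empirical upper tail,
  so the smallest attainable p is 1/(1 + N) and ties in z share p.

**Threshold curve.** The positive/negative boundary is the quantile
q = 0.999 (exposed as `--null-quantile`; no canonical value exists for
this kind of curve, and 0.999 puts the per-probe false-positive rate at
(1 − q)/2 ≈ 5·10⁻⁴) of the below-diagonal |d| at each intensity,
mirrored above the axis. It is computed as s(a) · z_q with z_q the
*global* quantile of the normalized below-diagonal |d| — a
variance-stabilized local quantile. Estimating a 0.999 quantile inside
each ~5000-probe bin separately would carry a standard error of ~0.13σ
and an interpolating spline through such noisy knots can overshoot;
borrowing the tail from all below-diagonal probes removes that noise and
makes the consistency identity exact: the positive set equals
{p ≤ p*} for the p* implied by q, up to ties at the boundary.

**Choices deliberately made and recorded.**

- The p-value is an empirical tail count, not a parametric fit: it
  assumes exactly what the symmetry argument assumes and nothing more.
  For large arrays the two converge.
- Distance is perpendicular ((y − x)/√2) rather than vertical (y − x);
  they differ by √2 and the choice only fixes the scale of z.
- p-values are invariant under any common rescaling of the raw
  intensities (equal-count bins and MAD are equivariant; tested).

## Gene-level calls

Probes map to a gene when their midpoint offset lies in the half-open
promoter window [−5500, +2500) around the TSS, strand-aware. "Best
probe" is interpreted as the per-replicate minimum p over the promoter's
probes, then combined across replicates by geometric mean — well-defined
even when replicates disagree about which probe is best. The alternative
reading (fix the single best probe overall, average its p across
replicates) is implementable via the returned best-probe-id matrix but is
not the default. Comparisons follow the rule as stated: geometric mean
uses ≤, the per-replicate count uses strict <; the boundary cases are
unit-tested. Lowering any p never loses a positive (monotonicity,
property-tested).

A practical constraint worth knowing: the geometric-mean threshold can
only bind if the empirical null can reach it. With N symmetrized null
values the floor is 1/(1 + N); a 10⁻⁴ rule therefore needs ≳ 5000
below-diagonal probes per replicate. The default simulation uses 14
probes per promoter (the density of a ~244k-probe array covering ~17k
genes), giving a floor near 7·10⁻⁵.

## Motif analysis

**Discovery** is an explicitly simplified word-seeded algorithm in the
MDscan/MDmodule family, not a reimplementation of any specific program:
all width-w words (strand-folded; a word and its reverse complement are
one seed) are ranked by log(observed/expected) against an order-k Markov
background with add-one smoothing; the top `n_seeds` (10) seeds are
extended to frequency matrices from every site within Hamming radius 1;
each matrix is refined by up to 3 rounds of rescanning, keeping each
sequence's best site at ≥ 75% similarity. Final motifs are ranked by
total information content × log(n_sites), ties broken lexicographically
by consensus. The procedure is deterministic given its inputs. Width is
fixed per run; the CLI loops over widths.

**Scanning** (Profit-style): a window's score is Σ_j m[base_j, j], its
percent similarity 100·score/max-score (no minimum-score offset — the
simplest reading of "% similarity" for a frequency matrix; switchable in
principle, recorded here). Hits require ≥ 75%. Both strands are scanned
even for palindromic motifs like TAATTA. Scanning is case-insensitive by
default; masked bases (N, or lowercase when the caller encodes with
`mask_lowercase=True`) contribute 0 at their columns.

**Enrichment** is a chi-square homogeneity test on per-sequence best
percent scores of positives vs controls, binned by pooled-sample decile
edges (10 bins; no canonical binning exists), merging bins with pooled
expected count < 5.

**Selection bias and the held-out split.** Testing a motif on the same
positive set it was discovered in is anti-conservative by construction:
the seed was chosen *because* it is over-represented there, and the
chi-square would reject far too often on motif-free data. The pipeline
helper `discover_and_test` therefore splits the positives, discovers on
half, and tests held-out positives against controls — under the null the
held-out positives and the controls are exchangeable, which is what makes
the reported p honest. The type-I rate of this protocol is measured
empirically over 100 seeded motif-free runs in the acceptance suite.

**The TAATTA matrix** shipped by `taatta_matrix()` is a synthetic
stand-in built from the consensus with pseudocount 0.01 — the reference
binding preference was characterised on protein-binding microarrays and
no numeric matrix is redistributed here. Users can supply any
JASPAR/TRANSFAC matrix.

## Expression analysis

Ratios are lowess-normalized per array exactly as in the ChIP module,
then filtered on mean channel intensity (default threshold: 1st
percentile of pooled intensities; any explicit value can be passed — the
simulation's bimodal intensity design has its antimode near 7.5 log2
units). Genes masked in every replicate are dropped; remaining missing
entries are imputed as 0 (log-ratio = no change) *for clustering only*,
never for differential expression.

**Clustering** is agglomerative centroid linkage under
1 − uncentered correlation (Σxy/√(Σx²Σy²)), the classic Cluster/TreeView
configuration; a cluster's centroid is the mean profile of its genes.
Genes are processed in sorted-id order, so results are invariant to input
order. Two caveats of centroid linkage are inherited knowingly: merge
heights can invert (no monotone dendrogram is asserted; the cut breaks
the n_clusters − 1 *largest* merges rather than the last ones), and
although every leaf-leaf distance is scale-free, the *full* dendrogram is
not invariant to rescaling one gene's profile, because that gene then
dominates its cluster's mean. The cluster count is a user parameter
(7 by default, matching the source design); no automatic cut selection
is attempted. The clustering operates on the "responsive" genes —
profile SD > 0.5 log2 units, the midpoint between the simulation's null
spread (0.2) and its pattern amplitude (~1) — mirroring heatmaps built
from differentially expressed genes only.

**Differential expression** (knockout-vs-wild-type reanalysis): the
per-gene test of the original software is unstated, so a Welch two-sample
t-test on log2 values is used (documented, switchable in principle to
paired or moderated variants); BH step-up adjustment at α = 0.05; fold
change is the ratio of linear-scale group means with the −1/r convention
below 1, cut at |FC| ≥ 1.1. Genes with zero variance in both groups get
p = 1 when means agree.

**Gene-set enrichment** is a one-sided hypergeometric (Fisher) upper
tail against an explicit background universe ("the genes on the array"),
with categories hitting fewer than 3 list genes excluded.

## Integration arithmetic

Venn counts, deregulated fractions (per comparison and over the union of
comparisons), and direction cross-tabs operate on upper-cased gene
symbols; an alias table can be supplied, full synonym resolution cannot.
Percentages are reported raw and rounded two ways — one decimal
(results-style) and nearest integer (abstract-style) — because published
texts mix both. Direction conventions are stated in the report itself:
overexpression direction = sign of the mean log2 ratio; knockout
direction = sign of the DE fold change; "same regulation" compares these
signed directions. qPCR %-input is 100·2^−ΔCt with
ΔCt = Ct(IP) − (Ct(input) − dilution factor); luciferase activity is
firefly/Renilla as a percentage of the mean control-well ratio.

## The synthetic-data generators

The generators emulate the *statistical structure* the analysis assumes,
with known truth labels throughout; they are the package's test bed, not
models of any particular scanner.

- **ChIP arrays**: per-probe mean intensity a ~ N(11, 1.2²) clipped to
  [8, 14] log2 units; null distance d symmetric about 0 (Gaussian by
  default; a Laplace switch probes robustness of the empirical null,
  which assumes only symmetry); enriched probes shifted by +`effect_delta`
  identically in all replicates, on 3 contiguous probes per bound gene
  (tiled arrays typically light up short probe runs). Default
  `noise_scale` = 0.35 log2 units of perpendicular distance (a null
  log-ratio SD of ~0.5, typical of two-colour arrays) and
  `effect_delta` = 2. The base simulation is homoscedastic; the
  low-intensity funnel s(a) = noise_scale·(1 + c·e^{−a/τ}) (c = 50,
  τ = 2, spanning a scale factor ~1.9 at a = 8 falling to ~1.05 at
  a = 12) is exercised by dedicated calibration tests rather than being
  the default, since no noise law is prescribed for the arrays being
  emulated. 14 probes per promoter, tiled at 100–300 bp spacing inside
  (−5.5 kb, +2.5 kb).
- **Sequences**: i.i.d. or order-k Markov background at a chosen GC
  content; a site sampled column-wise from the planted matrix replaces
  the background at a recorded offset/strand in `plant_fraction` of
  sequences (450 bp, 200 sequences by default — the size of a
  best-probes discovery set).
- **Expression**: 7 clusters × 50 genes over 6000 null genes (regulated
  fraction ≈ 5.5%, matching a design where ~2000 clustered genes sit on
  a ~39k-probe array). Keeping the regulated fraction small is not
  cosmetic: lowess ratio normalization assumes most genes are unchanged,
  and with a majority-regulated gene set the per-replicate imbalance of
  cluster patterns leaks into null-gene ratios and degrades downstream
  clustering. Cluster sign patterns are drawn with pairwise uncentered
  correlation ≤ 0.5 and non-zero sum, so clusters are separable *and*
  carry an up/down direction; amplitude 1, noise SD 0.2, 8 replicates.
- **Two-group DE**: 1000 genes, 10% shifted by 2·SD (SD = 0.3 log2),
  6 samples per group — small-sample conditions under which BH+Welch
  should still control FDR.
- **qPCR**: Ct tables exactly consistent with a known %-input (no noise);
  the generators' inverses are the tests.

**What passing these tests shows — and does not.** Calibration and
recovery on these generators demonstrate that the algorithms are
implemented correctly and behave as designed under their own
assumptions (symmetric null, smooth bias, independent probes,
well-separated clusters). They do not demonstrate performance on real
arrays, where probe effects are sequence-dependent and correlated along
the genome, enrichment profiles are peak-shaped rather than flat shifts,
cross-hybridization breaks symmetry locally, and cluster structure is
far from block-constant. In particular the near-perfect gene recall of
the default simulation reflects a comfortably large effect (≈ 5.7σ),
not a general property of the rule.

## Numerical details

- Random streams: `numpy.random.default_rng` everywhere; every generator
  takes an explicit seed and is bit-reproducible; derived seeds are drawn
  below 2³¹.
- Splines: `scipy.interpolate.UnivariateSpline`, k = min(3, bins − 1),
  s = 0 (interpolating) through bin summaries; evaluation clamped to the
  fitted intensity range.
- Empirical p-values use the +1/(N + 1) convention, so p ∈ (0, 1] and a
  probe tied with the null maximum still gets a positive p.
- Chi-square uses no continuity correction (df = bins − 1 after
  merging); identical score multisets short-circuit to (0, df, 1).
- Ties: seed ranking and motif ranking break ties lexicographically;
  clustering breaks merge-distance ties by the smallest cluster pair in
  canonical (sorted gene id) order.
- Degenerate inputs raise informative errors: all probes on the diagonal
  (zero robust scale), < 100 below-diagonal probes, zero expression
  profiles under uncentered correlation, empty enrichment backgrounds,
  zero Renilla wells.
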