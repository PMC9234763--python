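# Methods

This note documents the statistical models, numerical choices and
synthetic-data assumptions behind `durameth`, and what its tests do and do
not establish about real array data.

## Data model

A cohort bundles a probes × samples β matrix (methylation fraction in
[0,1]), the combined methylated + unmethylated intensity matrix, a sample
sheet (tissue, patient pairing, grade, NF2 status, sex, batch, exclusion
flag), a probe manifest (chromosome, 1-based position, mask flag) and a
gene annotation (strand, 1-based inclusive start/end). Identifiers are
aligned and sorted lexicographically at load; all genomic coordinates are
1-based inclusive internally, converting to 0-based half-open only at BED
boundaries. β values arrive already normalized — IDAT import, functional
normalization and probe-type correction are upstream of this package by
design.

Missing β values are encoded as empty fields. Each operation states its
missing-value policy: the differential tests are complete-case per feature,
promoter scoring drops missing probes from the denominator, probe-shift
classification reports a `missing` class.

## Probe-level differential methylation

The variability filter retains a probe iff its baseline mean β is < 0.2
with at least 10% of tumors above 0.2, or > 0.8 with at least 10% of
tumors below 0.7. The asymmetric 0.7 bound in the high branch is
intentional and preserved. "At least 10%" is evaluated as a count
≥ ceil(0.10 × n_tumors), so 4/31 tumors (12.9%) qualifies and 3/31 (9.7%)
does not. The baseline mean is taken over dura samples by default — the
rule contrasts a stable normal baseline against a divergent tumor minority
— with `mean_over="tumor"|"all"` as explicit alternatives, since the
convention is genuinely ambiguous.

Testing operates on M = log2(β′/(1−β′)) with β′ clipped to [ε, 1−ε]
(ε = 1e-6): the logit scale stabilizes the strong mean–variance dependence
of β near its boundaries.

The moderated t-test is implemented from first principles. Per feature, an
ordinary least-squares fit of the design gives the contrast estimate and a
residual variance s²_g on d residual df. The variance prior (d₀, s₀²) is
estimated by method of moments on z_g = log s²_g, using
E[z] = log s₀² + ψ(d/2) − log(d/2) − ψ(d₀/2) + log(d₀/2) and
Var[z] = ψ′(d/2) + ψ′(d₀/2); the trigamma equation is inverted by Newton
iteration started at the asymptotic value 0.5 + 1/y. The posterior
variance s̃² = (d₀s₀² + ds²)/(d₀+d) yields t with d₀ + d df.

Numerical choices:

- d₀ is capped at 1e7 and treated as infinite above the cap (the statistic
  becomes a z-score against s₀).
- When the observed excess dispersion of log s² is non-positive, d₀ is
  capped and s₀² falls back to exp(mean of corrected log-variances);
  if the variances are numerically identical (a degenerate input where no
  sampling dispersion exists) s₀² is their common value, so the moderated
  t collapses exactly to the ordinary statistic.
- Residual variances and effects below the floating-point floor
  (relative 1e-9 of the feature scale) are snapped to exact zero. Without
  this, features that are numerically constant (e.g. promoter percent
  scores that are exactly 0 or 100 everywhere) leave rounding dust in the
  residuals, the log-variance moment fit is poisoned by values near 1e-30,
  and spurious t ≈ 6 statistics appear on identically-zero effects.
- A single feature (prior not estimable) falls back to the ordinary t with
  a warning; rank-deficient designs are rejected naming the collinear
  columns.

BH adjustment is the textbook step-up: q_(i) = min_{j≥i} p_(j)·n/j clipped
at 1, missing p propagated and excluded from n.

Per-tumor probe classification calls a probe hyper- (hypo-)methylated in
tumor t iff β_tg − mean_dura(β_g) ≥ +0.2 (≤ −0.2), boundaries inclusive; a
1e-12 slack keeps decimal inputs that land exactly on the boundary from
being lost to binary rounding.

## Consensus clustering and k selection

Tumors are clustered on the β values of the called DMPs (items ×
features), under the Euclidean metric — k-means on a precomputed distance
matrix is ill-defined, so the package clusters the feature matrix
directly, which realizes the same intent. Each of `reps` repetitions draws
80% of items without replacement and runs k-means (k-means++, n_init=10)
for every k in 2..max_k; the consensus entry for an item pair is its
co-clustering count divided by its co-sampling count (never co-sampled →
0 with a warning). Final labels per k cut an average-linkage tree of
1 − consensus. Feature subsampling is not used.

k selection was genuinely open, and the obvious rule is defective.
Defining A(k) as the area under the empirical CDF of off-diagonal
consensus entries (equal to 1 − mean consensus) and
Δ(k) = (A(k)−A(k−1))/A(k−1) with Δ(2) = A(2), the rule "largest k with
Δ(k) ≥ 0.05" over-segments even perfectly separated data: at k_true + 1
k-means must split a coherent cluster, the split flips between subsamples,
and the resulting intermediate consensus entries keep adding CDF area
(measured Δ(k_true+1) ≈ 0.07–0.10 on clean 4-block data, never below a 5%
threshold). The implemented rule therefore combines both signals: the
candidate set is every k with Δ(k) ≥ 0.05 (structure still being gained),
and among candidates the selected k minimizes the proportion of ambiguous
consensus entries (PAC, fraction of off-diagonal entries in (0.1, 0.9)),
ties resolved toward the largest candidate — the finest partition that is
both informative and stable. On separable data PAC is exactly 0 at the true
k and jumps at k_true ± 1, making the selection sharp; degenerate inputs
with no candidate return k = 2 with a warning.

PCA uses column-centered SVD; explained-variance fractions are σ²ᵢ/Σσ²ⱼ.
The component–covariate screen relates each PC to each covariate with
Kruskal–Wallis (categorical) or the regression-slope p (numeric), dropping
missing values pairwise and recording single-level covariates as missing
with a warning.

## Promoter analysis

Probes are methylated iff β ≥ 0.3 (the threshold sits between the
unmethylated and methylated modes of the β density). The promoter of a
gene is TSS ± 2000 bp, inclusive on both ends (4001 bp); TSS is `start` on
+ strand, `end` on −. One TSS per annotation record: transcript-level
annotations must be pre-collapsed per gene. A probe may serve several
promoters. Percent methylation is 100 × methylated / non-missing
overlapping probes — an exact rational, tested to 1e-9.

Differential promoter analysis reuses the moderated t on the percent
values directly (a logit option exists but is off by default, matching the
linear-model treatment of percent scores). Contrasts are declarative
selectors over the sample sheet; a paired contrast adds one indicator
column per patient (no intercept) plus the case indicator, so the tested
coefficient is the within-pair difference; unmatched patients are an
error listing the ids. A tumor-contaminated dura sample invalidates its
whole pair for the paired design only — the pipeline excludes both samples
of that patient from paired contrasts while the tumor remains in the
unpaired comparisons.

## Copy number

Bins tile each chromosome's probe-covered span in 50 kb windows, merged
greedily until ≥ 15 probes, never beyond 5000 kb; a trailing underfilled
window merges backward. Per sample, log2 intensities are median-centered,
the reference is the mean centered log-intensity over the dura pool, bin
ratios are probe means of sample − reference, and a final per-sample shift
sets the genome-wide median ratio to zero. This normalization makes
diffuse whole-genome changes unidentifiable by construction — only
relative departures from each sample's own baseline are callable, which is
the standard limitation of ratio-based array CNV.

Segmentation is classical CBS: per chromosome, the maximal standardized
circular-arc statistic |S_j − S_i − m·x̄| / (σ√(m(n−m)/n)) over all arcs of
width ≥ 3 bins is referred to a permutation null (1000 shuffles,
add-one-smoothed p); a significant arc (α = 0.01) splits the segment and
recursion continues. The permutation loop is vectorized over arc widths;
segments always partition the chromosome's bins.

Calls use the log2-ratio scale with inclusive boundaries: ≥ +0.25
amplified, ≤ −0.25 deleted, otherwise neutral (the neutral interval is
open). Locus reports average the overlapping bins; the interval-overlap
branch for external integer-CN calls flags loci overlapping both CN < 2
and CN > 2 intervals as `conflict` rather than silently preferring one.

## Supporting statistics

Pearson chi-squared uses no continuity correction by default — required to
reproduce the printed sex-by-grade statistic (4.03), and verified by brute
force over all seven integer completions of the cohort marginals; a Yates
option exists for 2×2 tables. ANOVA/Tukey delegate to the standard F and
studentized-range machinery, with n = 1 groups allowed in the ANOVA but
excluded from HSD. Enrichment p is the hypergeometric upper tail
P(X ≥ k); the q-value is BH-adjusted p (not the Storey estimator), a set
is enriched iff p < 0.05 and q < 0.2, and the default universe is the
genes with ≥ 1 promoter probe. ΔΔCt averages replicate target−reference
differences per sample before differencing against the control-group mean;
fold change is 2^−ΔΔCt. Variant filtering applies the printed
strictness exactly: gnomAD AF < 1e-4 (strict; missing AF = absent = 0),
VAF > 0.05 (strict), supporting reads ≥ 5 (inclusive), exonic only, gene
on the allowlist. The bundled 73-gene allowlist is a synthetic stand-in
assembled from meningioma drivers, BAF-complex members and broad cancer
genes; it is user-replaceable and clearly labelled.

## The synthetic cohort

The generator emulates the statistical structure the analysis assumes, at
the study's scale: 12 dura/tumor pairs plus 19 unpaired tumors, four
clusters of sizes 12/7/8/4, planted β shifts of 0.3, beta noise at
concentration 50 (sd ≈ 0.05 at β = 0.5).

Design choices, fixed once:

- **Genome**: two 50 Mb chromosomes — the smallest structure that
  exercises per-chromosome binning and segmentation independence.
- **Probe layout**: promoter-enriched, as on the real array: three probes
  inside each gene's TSS ± 2 kb window, the rest uniformly spaced
  background. A uniform-only layout at this density would leave promoters
  with ≤ 1 probe and make percent scores degenerate.
- **Baseline**: per-probe bimodal means (unmethylated mode 0.08,
  methylated 0.85, methylated fraction 0.45), promoter probes coherent
  within a gene; noise is Beta(mean·c, (1−mean)·c), keeping support in
  (0,1) and reproducing the boundary heteroskedasticity that motivates
  M-value testing.
- **Planted probe effects**: 2% of probes hypermethylated and 0.5%
  hypomethylated in tumors (the 4:1 split mirrors the hyper-dominance of
  tumor-vs-dura differences); hyper effects are planted on
  unmethylated-baseline probes and hypo on methylated ones so the ±0.3
  shift survives truncation to [0.001, 0.999]. Effect probes are drawn
  outside promoter windows and are never masked, so probe-level truth does
  not leak into promoter truth.
- **Clusters**: disjoint 100-probe blocks within the hyper set get an
  extra +0.25 shift in one cluster each — clustering operates on DMPs, so
  the cluster structure must live inside them. The grade-III cluster
  additionally shows diffuse hypomethylation (−0.25 on 600 methylated
  background probes), driving its per-tumor hypomethylated-probe counts
  without constituting cohort-wide effects; those probes carry their own
  truth class (`diffuse_hypo`), distinct from both `null` and the
  cohort-wide classes, because they are neither.
- **NF2**: the altered state defines one methylation cluster (as the
  dominant driver lesion does in real cohorts) and is assigned to all
  tumors; the cluster assignment is constrained so exactly 5 of the 12
  paired tumors are altered. Group-specific promoter effects (±0.5/−0.6 β
  on whole promoters) apply per NF2 group; genes shifted in only one
  group carry the truth class `group_specific` in the tumor-vs-dura view.
- **CNV**: probe intensities are log-normal (per-probe affinity sd 0.5,
  per-sample scale sd 0.1, noise sd 0.25), multiplied by 2^effect inside
  planted segments. Larger segments are planted in the higher-grade
  clusters so the burden-by-grade comparison has signal.
- **Contamination**: one wildtype paired dura receives a 30% leak of its
  tumor's β signal, exercising the paired-analysis exclusion path.

What passing tests show — and do not. Recovery results (DMP sensitivity
≥ 0.9 at empirical FDR ≤ 0.1, ARI 1.0 at k = 4, exact NF2 shared-set
recovery) certify the correctness and calibration of the implementations
under the generator's assumptions: independent probes, clean bimodal
baselines, block-structured clusters, no batch effects, no cell-type
mixture. Real 450K data violate all of these — correlated neighboring
probes, probe-type chemistry, continuous subtype gradients — so these
numbers are upper bounds on, not estimates of, real-data performance. The
generator is a harness for verifying the machinery, not a simulator of
array physics.

## Problem sizes

Default simulations use 20 000 probes × 43 samples and 2 000 genes;
consensus clustering in the main pipeline uses 200 repetitions (the
cluster-count reproduction uses the full 1000), and CBS permutation tests
use 1000 shuffles (100–500 in fast paths). These sizes keep a full
pipeline run near one minute on a single CPU while leaving every stage's
statistical behavior measurable.

## Known limitations

- No batch-effect simulation or correction beyond covariate columns in
  the design.
- Gene-level TSS only; transcript-level promoters must be collapsed
  upstream.
- The CBS permutation null uses the global-variance z form of the arc
  statistic, not the exact two-sample t of the original formulation; at
  the tested sizes the two are interchangeable.
- Diffuse genome-wide methylation or copy-number shifts are
  unidentifiable after median normalization, by construction.
- The k-selection hybrid (delta-area candidates + minimal PAC) is sharp on
  block-structured data but, like all consensus criteria, can be
  indecisive on continuous gradients.
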