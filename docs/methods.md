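# Methods

## Data model and scope

The pipeline operates on a dense genes × cells matrix of normalized expression
(FPKM/TPM-like units), optionally log-transformed here as
log₂(value + pseudocount), pseudocount 1 by default. Library-size
normalization, alignment and UMI counting are out of scope: the input is
assumed appropriately normalized across cells. Collection-time labels, when
present, are used **only** for evaluation, never for ordering.

## Preprocessing

1. **Zero-gene filter.** Genes with zero expression in every cell are dropped.
2. **Gene clustering.** The retained G′ genes are grouped by agglomerative
   hierarchical clustering (Euclidean distance, complete linkage; scipy) and
   the tree is cut to H = max(1, round(0.05·G′)) clusters. Rounding is
   half-away-from-zero; the 5% is computed on all non-zero genes, before any
   constant rows are dropped. Averaging each cluster per cell yields the H × N
   matrix E — pooling many co-expressed genes shrinks the estimation variance
   of each feature and dilutes the impact of drop-out events (expressed genes
   reading zero by capture chance).
3. **Standardization and PCA.** Each row of E is scaled to mean 0, SD 1
   (SD with ddof = 1). Rows with zero SD would produce NaNs and are dropped
   with a warning. PCA treats cells as observations; component signs are fixed
   by making each component's largest-magnitude loading positive, so results
   are reproducible across runs and BLAS builds. Scores are not whitened.
4. **Choosing K.** With λᵢ the variance explained by PC i and vᵢ = √λᵢ (a
   non-increasing scree), a continuous two-segment linear model is fit for
   every candidate breakpoint k: f(i) = a + b(i−k) for i ≤ k and a + c(i−k)
   for i > k. This parameterization enforces the continuity constraint exactly,
   so each candidate is a 3-parameter ordinary least squares over all scree
   points. The k minimizing the SSE wins; ties go to the smallest k. The fit
   uses the first min(20, N−1, H) PCs and candidates k ∈ [2, m−1]; with fewer
   than 4 scree points the caller must pass an explicit K. The selection is
   invariant to positive rescaling of the scree.

## Cell clustering

Default: a mixture of multivariate Gaussians with unconstrained full
per-component covariances, fit by EM (scikit-learn) for each candidate count
in 2..9, the count chosen by BIC in the maximize convention
2 log L − p log N with p = (c−1) + cK + cK(K+1)/2. Cells take the component of
largest posterior probability. EM details:

* deterministic initialization from a complete-linkage partition of the cells,
  plus 5 random restarts per candidate (best final likelihood wins);
* EM is driven one step at a time so the log-likelihood trace is recorded; the
  ascent property (non-decreasing trace) is asserted on every fit;
* covariances are regularized by adding 1e-6 × the mean coordinate variance to
  the diagonal; a candidate whose best fit leaves a component empty is skipped
  with a warning, and if all candidates fail the error suggests k-means.

The candidate range 2..9 excludes a 1-cluster solution because the tree needs
at least 2 nodes; a user-forced single cluster falls back to ordering cells by
PC 1 with a prominent warning.

Ablations: `kmeans` (Lloyd's with 10 restarts; the count, when not given, from
an elbow rule: the proportion of total variance unexplained by the partition —
within-cluster SS over total SS — is computed per candidate count and the same
two-segment model is fit to that curve over the counts, returning the
breakpoint count; a breakpoint at the first count degenerates to a single
straight line, so a featureless curve yields the smallest candidate) and
`none` (every cell its own cluster, so the tree connects individual cells).

Whatever the method, the cluster centers used for tree building are the
empirical means of the member cells' PC coordinates, which treats gmm, kmeans
and none uniformly.

## Tree building and cell ordering

The MST over cluster centers (Euclidean lengths) is built with Prim's
algorithm from the lowest-indexed node; equal-length frontier edges are broken
by the smallest (min id, max id) pair. MSTs are not unique under ties — the
deterministic rule makes reruns byte-identical.

The **main path** is the leaf-to-leaf path with the most clusters; ties are
broken by most member cells, then by the lexicographically smallest canonical
id sequence. The origin defaults to the first cluster of the (possibly
marker-oriented) main path — a deterministic stand-in for an arbitrary choice
of end, since silent randomness would break reproducibility. All simple paths
from the origin to each leaf are enumerated; non-main ones are branch paths.
A marker gene with a known direction orients the path by the sign of the
least-squares slope of per-cluster marker means (an exactly flat trend keeps
the input orientation and warns). Users may instead supply the cluster
sequence verbatim; it is validated against the tree's edges.

Cells are assigned to edges as follows: first-cluster cells to the first edge,
last-cluster cells to the last edge, and interior-cluster cells to the edge
toward whichever neighboring center is nearer in Euclidean distance (ties: the
earlier edge). The projection of cell k on edge (Cᵢ, Cⱼ) is the raw inner
product vᵢⱼᵀẼₖ/‖vᵢⱼ‖ with vᵢⱼ = centerⱼ − centerᵢ, exactly as printed —
no centering, since only the relative order matters. The global sort key is
(cluster position, edge index, projection value, stable input index) and
pseudotime is the resulting rank 1..N. Each path is ordered independently;
branch paths do not reuse main-path projections. A marker-only baseline
(sort cells by one gene's expression) is provided for comparisons.

## Differential expression

Per gene, a Gaussian likelihood-ratio test compares a smooth trend in
pseudotime against a constant model. The smooth is a natural cubic spline with
3 basis columns (truncated-power natural basis; interior knots at the 1/3 and
2/3 quantiles of pseudotime, boundary knots at the ends), fit by OLS —
a fixed-df spline reproduces the flexibility of a penalized GAM at effective
df 3 deterministically. The statistic 2Δlog L = n·log(RSS₀/RSS₁) is referred
to χ² with df equal to the number of smooth basis columns (3), i.e. the
parameters the smooth model adds beyond the intercept; the df is computed from
the actual basis rather than hard-coded. The χ² reference is asymptotic
(the exact small-sample law is an F), so the type-I error at nominal 0.05 is
slightly above nominal at moderate N — the null-calibration test checks it
against the binomial 95% interval on 500 simulated null genes at N = 200.
A constant gene gives LR 0 and p = 1; a perfect fit reports the smallest
positive float. P-values are converted to FDR by Benjamini–Hochberg step-up
(statsmodels); with the identity of the original FDR method ambiguous, BH is
the field default and the method is exposed as a parameter. Genes are ranked
by ascending FDR, ties by ascending p, then stable input order; the
differential flag is fdr < 0.05 by default.

## Evaluation metrics

**POS.** Collection-time labels are converted to indices τ ∈ {1..V} by ranking
the distinct labels (raw-time weighting is available as an option; the index
form is the default because the pairwise score is defined on time-point
subscripts). For an ordering π, POS = Σ_{i<j} (τⱼ − τᵢ) / D with
D = Σ_{unordered pairs} |τₐ − τᵦ|. D is exactly the numerator attained by any
time-sorted ordering, hence the tight bound making POS ∈ [−1, 1] with the
extremes attained — verified in the tests by exhaustive permutation on small
fixtures. Same-time pairs contribute 0 to both numerator and denominator.
With a single time point D = 0 and POS is defined as 0 with a warning.

**Similarity.** For orderings π₁, π₂ with cell-union A,
s = 2/(|A|(|A|−1)) · Σ over unordered pairs of h, where h = 1 only when both
cells occur in both orderings with the same relative order. Identity gives 1,
exact reversal 0, disjoint sets 0.

**Perturbation and robustness.** Cell-level: keep a uniform sample of
round(x·N) cells (x ∈ {0.95, 0.9, 0.75} typically), columns bit-identical,
order preserved (rounding half away from zero). Expression-level: per gene,
residuals about the cross-cell mean are scaled by κ (κ ∈ {0.05, 0.1, 0.25}
typically), permuted across cells independently per gene, and added back —
per-gene means are conserved exactly and the variance inflates by ≈ (1 + κ²).
Robustness runs the ordering pipeline on the original and on 100 independently
perturbed replicates, scoring each against the original ordering; failed
replicates are excluded from the mean with a logged count. Orientation and
marker choices are frozen from the original run's configuration and re-applied
to every replicate. Note that robustness alone cannot certify an ordering: a
pipeline that ignores expression entirely is perfectly robust to expression
noise (a property the tests document).

**Gold genes.** Mean DE rank of an externally known differential-gene set,
and counts recovered in the top R for R = 200, 400, …, 2000 (truncated at the
number of tested genes).

## Synthetic data

The generator emulates a pooled time-course experiment on the log₂ scale.
Latent pseudotime t ~ Uniform(0,1); trend genes follow linear, sigmoid
(logistic in t, midpoint 0.5, steepness 10) or transient (Gaussian bump at
t = 0.5, width 0.15) shapes with amplitude 3 log₂ units over a baseline of 1;
flat genes sit at a uniform baseline in [1, 4]. Gaussian noise (SD 1.0) is
added, values are clamped at 0, and dropout zeroes each entry independently
with probability dropout_rate·exp(−expression), so low-expression entries drop
out preferentially. Collection time is the equal-width bin index of t into V
bins — noise crosses bin edges, so time labels only roughly reflect the true
order, as in real time-course data. In branched mode, cells past the branch
point split into two lineages and odd-indexed trend genes retrace the
trajectory on lineage B.

Defaults — 300 cells, 500 genes (100 trend), noise SD 1.0, dropout rate 0.2,
4 time points — mirror the scale of published single-cell time courses of a
few hundred cells over four collection points, with enough noise that a single
marker gene orders cells only moderately well while the pooled representation
orders them accurately. What the generator does **not** model: count-level
sampling (negative-binomial library-size effects), batch structure, cell-cycle
confounding, doublets. Passing tests therefore demonstrate correctness of the
algorithms and sensible behavior under idealized dropout/noise, not
performance claims on real droplet data.

`simulate_scree` builds two-segment linear screes (continuous at the
breakpoint, slopes ≤ 0, optional noise, re-sorted non-increasing) as fixtures
for the PC-selection rule; with noise SD 0.1 against a slope change of ~2 the
breakpoint is recovered in ≥95% of seeds.

## Numerical and design choices

* One global seed fans out to per-stage seeds through
  `numpy.random.SeedSequence`, so stages can be rerun in isolation and reruns
  are byte-identical.
* Trimming rules ("GENE>value", repeatable) remove a cell only when **all**
  active criteria hold (conjunction), before ordering.
* TSV reads use round-trip float parsing so load → write → load is
  bit-identical.
* Equal projection values, equal marker means, duplicate centers and other
  ties all break deterministically (stable input index / smallest id).
* Problem sizes in the test suite (≤ 300 cells, ≤ 500 genes, 100 robustness
  replicates with a lightweight ordering baseline) keep the full suite under
  a minute while exercising every code path; the same generator scales to
  larger studies.

## Known limitations

* P-values and FDR assume the ordering is fixed and known; uncertainty in the
  ordering itself is not propagated (a recognized open problem for this class
  of methods).
* Integer-rank pseudotime carries no arc-length information.
* The GMM-BIC cluster count is sensitive to strong non-Gaussian structure;
  the k-means and manual-count options are the practical escape hatches.
* POS requires ≥ 2 distinct collection times; single-time datasets can only be
  evaluated by robustness and gold-gene metrics.
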