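# Methods

This note documents the models behind `landgen`, the defaults and why
they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical decisions that shape edge-case behavior.

## The synthetic landscape generator

The generator is a logit-normal frequency model, not a genealogical
simulator. Its purpose is to produce data whose *spatial statistical
structure* matches the scenario the pipeline targets — isolation by
habitat resistance with local adaptation layered on top — while keeping
every quantity needed for truth-recovery checks in closed form.

- **Environment.** Each layer is white noise smoothed with a Gaussian
  kernel (`autocorr_range`, in cells; default 6) plus a linear trend of
  random orientation (`trend_weight`, default 1), standardized to zero
  mean and unit variance over cells. The trend gives layers the
  large-scale gradients real climate surfaces have; as a side effect,
  layers are weakly correlated at sampling locations, as real predictors
  are.
- **Habitat.** Cellwise logistic in the layers
  (`expit(intercept + Σ c_k·env_k)`, defaults c = (1.2, −0.8, 0.6, 0),
  intercept 0.5), giving a smooth suitability surface in (0, 1) tied to
  the same variables that drive selection — the realistic, and
  deliberately confounded, case. `patchy_habitat` and
  `block_gradient_environment` build contrast scenarios: rectangular
  habitat blocks behind near-impassable barriers, optionally with
  environmental gradients parallel to the block divisions (the
  "gradients parallel population structure" situation).
- **Populations and genotypes.** `n_populations` (default 60) locations
  with ≥ `min_spacing` cells separation in habitat ≥ 0.2;
  `n_individuals` diploids each (default 12) — the sampling design of a
  typical range-wide RAD-seq study of a desert annual. Neutral locus
  logits are jointly Gaussian over locations with covariance
  `σ²·exp(−D/φ)` around a locus-specific base logit (base frequencies
  Beta(0.8, 0.8) clipped to [0.05, 0.95]); D is the least-cost
  resistance distance by default (`distance_mode` switches to geographic
  or environmental distance for contrast scenarios). σ² = 1 and φ = 60
  resistance units put mean pairwise θ near 0.1 on the default
  landscape — the moderate differentiation regime of outcrossing desert
  annuals. Adaptive loci (default 20 of 500, 4%) follow
  `logit p = logit(base) + β·env_std + ε`, β = 2 per standardized
  environmental unit and ε ~ N(0, 0.25²); genotypes are Binomial(2, p).
- **What it does not emulate.** No linkage, no mutation/recombination
  models, no site-frequency-spectrum realism, no within-location family
  structure (panmixia within a location is assumed, since no
  within-location sampling model is available), no sequencing error or
  allele-specific depth. Passing tests therefore certify that the
  *estimators and algorithms* behave correctly under the intended spatial
  model, not that they are robust to genotyping artifacts.

Determinism: one seeded `numpy` generator drives everything; the seed is
recorded in the VCF header and `truth.json`.

## Genotype statistics

Filters run in a fixed, tested order: individuals by missingness (> 30%
removed), then SNPs by minor-allele count (< 3), excess mean depth
(above the 99th linear-interpolation quantile of the retained set;
per-SNP mean depth, not per-genotype masking), and observed
heterozygosity (> 0.7). The per-location call-rate filter (r = 0.5) is
available but off by default. The depth rule requires depth metadata and
errors without it rather than silently skipping.

Weir–Cockerham θ uses the 1984 variance components with multi-locus
ratio-of-sums (Σa / Σ(a+b+c)); negative pairwise values are retained.
Both the mean of pairwise values and an all-populations ratio-of-sums θ
are reported, since summaries in the literature vary. The one-level
AMOVA partitions squared Euclidean dosage distances
(missing-pairwise-deleted, rescaled to the full locus count); negative
among-group components are floored at zero and logged. H_e and π use the
unbiased 2n/(2n−1) correction; for complete biallelic data the two
coincide per site, and they diverge only through missingness.

## Population structure

PCA is SVD on mean-imputed, centered dosages. K is the argmin of
`BIC(K) = n·log(WSS/n) + K·log(n)` over the best of `n_starts` k-means
runs per K. A practical note encoded in the tests: this BIC has a clear
interior minimum when the feature dimension is comparable to the sample
count (the genotype-PC regime); in low dimension the curve can keep
creeping downward past the true K. DAPC fits an LDA on the leading PCs,
with the retained-PC count chosen by cross-validation that withholds
whole sampling locations (20% of locations, 10 replicates) — withholding
random individuals would leak location identity. Membership
probabilities are the LDA posterior.

## Resistance surfaces and distances

Cell conductance equals habitat probability (the identity transform; the
suitability-to-conductance mapping is otherwise unknowable and is
config-exposed). Edge conductance is the arithmetic mean of the two cell
conductances (geometric available), edge cost = inter-center distance
(1 or √2 cell units) / edge conductance; nodata and zero habitat are
impassable. Least-cost distances are exact Dijkstra shortest paths.
"Commute" distances are circuit-theoretic effective resistances from the
Laplacian on edge conductances, solved per location pair via a grounded
sparse factorization; effective resistance (rather than raw expected
commute time, which is volume-scaled) is returned so that a single edge
of resistance r yields distance ∝ r. Point-to-cell lookup is by
containing cell, no interpolation; a point on an interior cell boundary
belongs to the right/upper cell and outer-edge points are clamped in.

## Mantel causal modeling

Mantel r is the Pearson correlation over vectorized upper triangles; the
permutation null relabels rows and columns jointly, one-tailed upper by
default, `p = (1 + #{r* ≥ r}) / (n_perm + 1)`, 999 permutations by
default. The partial statistic correlates residuals of A-on-C and
B-on-C and permutes the residualized A matrix. Residuals below 1e-9 of
the original scale (A affine in C) are declared degenerate with r = 0
rather than correlating float noise. The nine-test battery is evaluated
on r magnitudes: IBR is called when r(gen × resistance | geographic)
stays ≥ 0.1 while r(gen × geographic | resistance) collapses to ≤ 0,
IBD the mirror image, IBE when the adaptive-loci environmental partials
both stay ≥ 0.1. Both the 0.1 "remains positive" level and the ≤ 0
"collapse" level are arguments, since the underlying logic is
qualitative; a landscape where resistance is strongly geography-aligned
can show the IBR pattern in r values yet leave the geographic partial
slightly above zero, in which case no verdict is returned.

## RDA genome scan

Predictors are standardized and VIF-screened (drop the worst until all
VIF < 10). The response is individual-level dosage, mean-imputed,
centered, and — by default — scaled to unit variance per SNP
(correlation-scale RDA). The scaling matters: dosage variance depends on
allele frequency, so without it the pooled distribution of axis loadings
across loci is a variance mixture whose heavy tails make the 3-SD rule
flag several times the nominal fraction of neutral loci; with scaling
the null flag rate sits near the two-sided 3σ tail (≈ 0.27% per axis).
Axis significance is a sequential conditional permutation test: axis k
is tested after removing the previously fitted axes from the response,
permuting those residuals and comparing the reduced leading eigenvalue
(`p = (1+c)/(n_perm+1)`, α = 0.05). A plain marginal eigenvalue test
gives trailing axes a ~5% false-extra-axis rate even under a strong
single gradient, and a marginal pseudo-F variant is over-liberal because
permutation moves the leading signal into its residual denominator; the
sequential test is calibrated under the null and conservative for
trailing axes. Outliers are loci with |loading z| > 3 on any significant
axis, annotated with the environmental variable most correlated with
their dosage column. Candidate lists from external methods are merged as
set unions with per-method tags; nothing Bayesian is re-implemented
here.

## Generalized dissimilarity modeling

The response is Bray–Curtis dissimilarity between population
allele-frequency vectors at the candidate loci (a pre-computed genetic
distance matrix can be substituted). Each predictor gets three order-2
I-spline basis functions with knots at min/median/max of its observed
values; matrix predictors (geographic distance, habitat resistance)
enter through splines evaluated on the raw pairwise distance. The model

    d̂ = 1 − exp(−η),  η = α + Σ_j Σ_k β_jk |I_jk(x1) − I_jk(x2)|,
    α ≥ 0, β ≥ 0

is fitted by IRLS with an inner non-negative least squares on the
working response (working weights (1−μ)/μ), binomial deviance,
convergence at relative deviance change < 1e-6 or 100 iterations. The
percent deviance explained is 100·(1 − D/D₀) against the intercept-only
fit. Noise-free self-recovery of spline heights is within 5% at 60
sites. Predictors with all-zero coefficients are reported "not
selected". `transform_predictors` maps rasters through
f_j(x) = Σ_k β_jk I_jk(x); genomic offset excludes the intercept so an
unchanged climate gives exactly zero offset — whether the intercept
belongs in the offset is genuinely open, and the zero-identity decided
it here. Knot evaluation clamps x to the observed range (turnover
saturates beyond the data) and basis values are clipped to [0, 1]
against float overshoot; knots closer than 1e-9 of the span are nudged
apart.

## Turnover forests

Per SNP, a random-forest regression on the predictors
(`n_trees = 2000`, `max_features = p/3`, `min_samples_leaf = 2`); SNPs
with positive out-of-bag R² are retained. Per-predictor importance is
the mean over retained SNPs of R² × normalized permutation importance,
where predictors correlated above 0.7 with another predictor are
permuted *within quantile bins of their strongest correlate* (a
conditional-permutation approximation that avoids crediting shared
signal twice). Split improvements (impurity decrease, R²-weighted and
tree-averaged) are binned at their threshold values along each gradient,
divided by the binned data density, cumulatively summed, and rescaled so
the plateau equals the predictor's importance. Importance saturates for
strong effects — two predictors that both drive near-perfectly-predicted
SNPs are hard to rank — so rank comparisons are meaningful only when
effect strengths differ substantially.

## Seed transfer zones

Locations are clustered by Ward linkage (scipy's Ward-D2-style update)
on the GDM-predicted dissimilarity matrix; the silhouette (computed
directly from the dissimilarity, singleton clusters scoring 0) chooses
k, with an override argument because a management-driven k is a
first-class use case; perMANOVA R² (= 1 − SS_within/SS_total from the
squared-distance partition, p by pseudo-F label permutation) is reported
per k. For assignment, each location contributes an accumulated
least-cost surface over the habitat graph and a Euclidean-distance
surface in GDM-transformed space; both components are min–max normalized
to [0, 1] over all (location, cell) values before the weighted
combination 0.6/0.4 — the units of accumulated cost and transformed-env
distance are not commensurable, and this global normalization is the
package's explicit reconciliation (it is the largest free choice in the
module and is config-exposed). Cells below the habitat clip (0.2) are
nodata; unreachable cells are nodata and counted; cost ties resolve to
the lowest location index and are logged. Future projection is the same
algorithm on future inputs, plus a same/changed/lost/gained summary
raster whose first three classes partition the current suitable area.

## Problem sizes

The test suite and the acceptance script run on desk-scale landscapes:
40×40 to 60×60 grids, 20–60 locations, 300–2700 SNPs, 99–199
permutations, 50–300 trees per forest, 10–20 seeds per stochastic
property. These sizes keep every experiment reproducible in minutes on a
single core while leaving each statistic enough resolution for the
tolerances asserted; the algorithms themselves have no scale-specific
shortcuts.

## Known limitations

- The frequency model is non-genealogical; F_ST-like structure is
  controlled directly rather than emerging from drift, so estimator
  behavior under complex demography is untested.
- The RDA is unconditioned (no latent-factor correction for population
  structure); with strong structure whose gradients parallel selection,
  trailing significant axes carry genuine structure-environment
  association and contribute neutral flags at roughly the nominal
  3σ rate per axis.
- Commute distances use a dense-enough grounded solve per component;
  grids far beyond ~10⁴ cells would need an iterative solver.
- CRS handling is a tag, not a projection engine: all inputs must share
  one projected CRS.
- GDM bootstrap confidence bands and Mantel-based spline significance
  are not implemented.
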