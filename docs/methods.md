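# Methods

`mycoecon` re-implements, as a tested pipeline, the statistical machinery
behind a "fungal economics space": the derivation of orthogonal trait axes
from a matrix of soil saprobic fungal isolates, the alignment of all traits
along the primary dense–fast continuum, and skew-normal models of each
isolate's fundamental niche along three environmental gradients. Every
stage can be exercised against synthetic data with planted ground truth,
so the whole stack is verifiable without any external download.

## Trait preprocessing

Raw trait variables (possibly replicated across assays, with a few missing
cells) become one standardized matrix of isolates × traits:

- **Normality gate.** Each trait is Shapiro–Wilk tested (α = 0.05, a
  conventional and testable cut for a step often described only as
  "checked for normality"); failing traits are log-transformed as
  log(x + shift), with shift = 0 for strictly positive traits and
  |min| + 10⁻⁶ otherwise (log-response-ratio–like traits are legitimately
  negative). All traits are then z-scored (ddof = 1).
- **Repeated measurements** of one trait are z-scored per variable and
  averaged per isolate, so assays with different units contribute equally.
- **Trait syndromes** (e.g. leaf + wood decomposition, the three stress
  log-response ratios) are collapsed to one axis by a correlation-matrix
  PCA of the block; the requested component is sign-oriented so that its
  correlation with a named representative variable is positive, and its
  percent variance is reported.
- **Derived traits.** Carbon-use efficiency CUE = C_biomass /
  (C_biomass + C_respired) ∈ [0, 1]; stoichiometric flexibility 1/H as
  the OLS slope of log(tissue C:N) on log(resource C:N) (0 = strict
  homeostasis, 1 = fully tracking the resource); complexity-weighted
  carbon use as the weighted mean of z-scored biomass on glucose,
  cellobiose, xylan, cellulose and litter with weights 1…5 (the exact
  weights are not fixed by the underlying idea — "weighted by degree of
  complexity" — so they are a documented, configurable default);
  stress tolerance as ln(growth_stress / growth_control).
- **Imputation.** Missing cells get either the column mean of observed
  values or, for traits with phylogenetic signal, the mean of the k = 3
  nearest relatives (patristic distance) with observed values. Imputation
  operates on standardized values and the table is re-standardized
  afterwards, so the downstream PCA contract (mean 0, SD 1) holds exactly.
  Observed cells are never modified and every imputed cell is logged.
- **UPGMA** (average linkage on a symmetric distance matrix) provides the
  ultrametric tree used for neighbor lookups; it is scipy's average
  linkage, serialized to Newick with heights = merge distance / 2.

## Trait-space ordination

PCA is computed on the trait correlation matrix; "loadings" are
trait–score correlations (eigenvector × √eigenvalue), bounded in [−1, 1],
which matches their use as a correlation heatmap and keeps eigenvalues
summing to the number of traits.

**Axis significance** uses a column-permutation null: each of n_perm
(default 1000) permutations shuffles every trait column independently,
destroying inter-trait correlation while preserving each trait's marginal
distribution. An axis is significant when its observed percent variance
exceeds the (1 − α) null quantile at the same axis rank;
p = (1 + #{null ≥ obs}) / (n_perm + 1). Loading significance is judged the
same way against each trait's null |loading| distribution at matched axis
rank. Axes beyond the numerical rank of the data (eigenvalue ≈ 0) are
never flagged. The broken-stick expectation b_i = (1/n)·Σ_{j≥i} 1/j is
provided for comparison but the permutation test is the retention
criterion.

**Varimax rotation** of the significant axes (however many there are; 3 on
planted 3-factor data) uses the SVD form of the varimax iteration with
Kaiser row-normalization on by default (each trait weighted equally during
rotation; switchable). Rotation is orthogonal, so RC scores stay
uncorrelated and per-trait communalities are preserved; RCs are reordered
by rotated variance and sign-anchored on request (axis polarity is
arbitrary, so e.g. the fast pole can be fixed positive). Unit-variance
standardized scores are rotated by the same matrix.

**Loading clusters** (the trait groups visible in a loadings heatmap) come
from average-linkage clustering of Euclidean distances between loading
rows.

## Randomized anchored PCA (trait alignment)

A single PCA's axes shift when traits are added or removed, so the
alignment of each trait with the dense–fast continuum is instead averaged
over many random trait subsets:

- *plain variant*: n_repeats (default 10,000) PCAs on 10 randomly drawn
  traits; runs whose PC1 eigenvalue falls below a quantile of the run
  distribution (default: keep the top half — the "strong PC1" restriction
  is a tunable, reported with the output) are discarded; each trait's mean
  |PC1 loading| is averaged over retained runs containing it.
- *anchored variant*: every subset additionally contains the two anchor
  traits (extension rate and density, the two poles of the continuum).
  PC1's sign is fixed so extension loads positively; runs where **either**
  anchor's |PC1 loading| falls below `anchor_min_loading` (default 0.4 —
  the axis did not capture the continuum) are excluded. A calibration
  utility inverts this: given a target exclusion fraction (e.g. 2%), it
  returns the threshold that achieves it on the supplied table. Traits are
  sorted by signed mean loading, density side to extension side.

Sampling is without replacement within a run and independent across runs;
one seed drives the whole sequence, and an optional run log allows
brute-force re-averaging as an oracle.

## Fundamental-niche models

Biomass along each gradient (C:N 5–200, temperature 12–33 °C, water
potential −1.91 to −0.49 MPa, ~8 levels, 3 replicates per level by
default — replicate count is a study-design placeholder) is fitted per
isolate with an amplitude-scaled skew-normal curve

b(x) = A · (2/ω) · φ((x−ξ)/ω) · Φ(α(x−ξ)/ω),

four parameters (location ξ, scale ω > 0, shape α, amplitude A > 0): a
density-only skew-normal cannot match absolute biomass, so the amplitude
multiplier is required. Fitting is nonlinear least squares (ω and A on log
scale) from moment-based starts with seven shape starts
α₀ ∈ {−4, −2, −1, 0, 1, 2, 4}, keeping the lowest-RSS solution.

- **Optimum**: argmax of the fitted curve within the tested range (bounded
  1-D maximization; boundary optima allowed for monotone-truncated
  curves).
- **Breadth**: the interval where b(x) ≥ 25% of the isolate's own maximum,
  found by root-finding (tolerance 10⁻¹⁰ in gradient units) on each side
  of the optimum and clipped to the tested range — extrapolated breadth
  beyond tested conditions would be unverifiable. In the Gaussian limit
  (α = 0) the unclipped breadth is 2σ√(2 ln 4), used as a closed-form
  check.
- **Niche volume**: cuboid approximation, the product over the three
  gradients of breadth / max breadth across isolates; in (0, 1], with 1
  attained only by an isolate that is widest on every gradient.
- **Relative abundance** along a gradient: fitted curves normalized
  pointwise across isolates on a 201-point grid (a raw-mean mode uses
  per-level mean biomass instead; fitted curves are the default).
  Grid points where every curve is numerically zero are dropped and
  reported.
- **Community-weighted RC profiles**: abundance-weighted mean RC score per
  grid point. The water-potential profile is evaluated only down to
  −1.2 MPa: beyond that, too few isolates grow for a community mean to be
  meaningful. Profiles are displayed through a penalized cubic smoothing
  spline with GCV-chosen penalty (a single-smooth GAM equivalent; the
  smoother affects presentation only, never statistics).

### Identifiability of the location parameter

At 5% observation noise (SD = 5% of each curve's peak growth) the curve,
its optimum and its breadth are recovered well, but the *location
parameter* ξ itself is not always: for near-symmetric truths (|α| ≲ 2) the
mirror-image solution — opposite skew sign, ξ reflected across the mode —
can genuinely fit a noisy draw better, displacing ξ by ~2ω·δ(α) even
though the fitted curve is nearly identical. On the default generator
(α ~ U(−4, 4)) roughly three quarters of ξ estimates land within 5% of the
gradient range and the median |ξ̂ − ξ| is ~1–2% of the range, while the
optimum (the quantity with ecological meaning) is recovered within 5% of
the range for ~90% of isolates. Conclusions should therefore be drawn from
curve-level summaries (optimum, breadth, volume), not from raw skew-normal
parameters.

## Association statistics

- **Correlations** between RC axes / traits and niche traits: Pearson by
  default; `auto` mode switches to Spearman when either variable fails the
  Shapiro–Wilk gate (the convention used for the non-normal
  water-potential optimum). Raw p-values are reported; the all-pairs trait
  correlation matrix adds Benjamini–Hochberg q-values as an extra column
  and never filters silently.
- **PERMANOVA** of the 3-D niche-optimum matrix on one continuous RC axis
  (per-axis tests by default; a joint multi-axis mode would generalize the
  hat matrix). Response columns are z-scored and converted to Euclidean
  distances; pseudo-F = tr(HGH) / (tr[(I−H)G(I−H)]/(n−2)) with G the
  Gower-centered matrix and H the hat matrix of intercept + predictor.
  With Euclidean distances this equals the classical multivariate
  regression F, which the tests exploit as an independent oracle.
  Significance by permuting predictor rows; exact enumeration of all n!
  permutations is available for small n.
- **RDA forward selection** of trait predictors: at each step the
  candidate maximizing the adjusted R² of the multivariate OLS fit is
  admitted if it increases adjusted R², its marginal pseudo-F clears a
  permutation test at α, and all VIFs in the augmented model stay ≤ 10
  (the cap is configurable; an exact duplicate has infinite VIF and is
  always rejected). Note that with k > 1 null candidates the selection
  rate of the *best* candidate exceeds α (≈ 1 − (1−α)^k) — the usual
  optimism of unprotected forward selection; the type-I calibration is
  exact for a single candidate, which is what the tests assert.

## Synthetic data: what it does and does not emulate

The generator plants a known truth at the study's scale: 28 isolates × 35
standardized traits in three blocks (dense–fast 14, flexibility 11,
C acquisition 10; block loadings 0.8/0.75/0.75 with alternating signs so
each axis has two poles), latent scores QR-orthogonalized so axis
orthogonality is exact at n = 28, iid trait noise (default SD 0.3,
roughly two-thirds signal), columns affinely de-standardized so
preprocessing has real work, ~3% missing cells, skew-normal niche curves
with parameters drawn uniformly per gradient (locations spanning the
tested ranges, scales 12–29% of the range, shapes U(−4, 4), amplitudes
20–80), observation noise 5% of each curve's peak, and a random
ultrametric coalescent-style phylogeny with Brownian traits for
imputation benchmarks.

It does **not** emulate: correlated noise between traits measured in the
same assay, phylogenetic signal in the economics-space traits themselves
(the study found none), trait–niche correlations (planted traits and
niche parameters are independent — association tests should come up
empty on synthetic data, and do), non-Gaussian measurement error, or
level-dependent replicate noise. Passing tests therefore demonstrate
correctness of the machinery and calibration of its tests, not ecological
conclusions about real fungi.

## Numerical choices

- Eigendecomposition via `eigh` on the explicit correlation matrix;
  eigenvalues clipped at 0; ties broken by stable original-axis order.
- Varimax convergence: relative criterion gain < 10⁻⁸, max 1000
  iterations.
- Curve fitting: `least_squares` with xtol = ftol = gtol = 10⁻¹²,
  ω ∈ [10⁻³, 10]·range, ξ within ± one range-width of the tested interval.
- Degenerate inputs raise (constant trait columns, all-zero biomass,
  asymmetric distance matrices, zero-variance correlation inputs) rather
  than propagating NaN; non-converged fits are flagged and their
  summaries reported as missing.
- Pipeline stage seeds are SHA-256-derived from one master seed, so a
  rerun with the same config is byte-identical.

## Problem sizes

Defaults used by the analysis drivers and the verification scripts: 999
permutations for significance tests (199 inside replicated calibration
loops), 10,000 randomized-PCA repeats (2,000 in recovery benchmarks), 100
synthetic isolate-curves for fit benchmarks, 50 seeds for power estimates,
200 replicates for type-I calibration. These sizes give binomial /
Monte-Carlo error well inside the asserted margins.
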