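# Methods

## Surface metrology

A scan is a rectangular grid of heights (nm) with a per-pixel validity mask
and a pixel pitch (µm). Invalid pixels carry NaN and never enter any sum.

**Form correction.** Eggshell fragments present a near-spherical cap to the
profilometer, so a bivariate polynomial of total degree ≤ 2 (six terms) is
fitted by ordinary least squares to the valid pixels and subtracted; the
basis is evaluated on coordinates centred and scaled to [−1, 1]² purely for
conditioning. The corrected surface is then shifted so its lowest valid
height is exactly 0 nm (the shift subtracts the minimum, so the floor is
exact in floating point, not approximate). Fewer valid pixels than basis
terms, or a rank-deficient design (e.g. all valid pixels on one scan line),
is an error rather than a silent bad fit.

**Texture parameters.** Sa, Sq, Ssk, Sku use the population (1/n) moment
convention over valid pixels; the convention is recorded with the outputs
since instrument software does not always state its own. A perfectly flat
surface (Sq = 0) raises a degenerate-surface error for the standardized
moments; the error object carries Sa = Sq = 0. Computing texture on an
uncorrected map warns (raw curvature dominates the moments) but is allowed,
because the warning is sometimes exactly what a user diagnosing a pipeline
wants to see.

**Coverage QC.** Scans at ≥ 40% pixel coverage pass unchanged (the
threshold is configurable). Below it, border rows/columns whose own valid
fraction is below the threshold are trimmed iteratively, worst line first —
missing pixels concentrate at scan edges and corners, which fall outside
the interferometer's focal plane on a curved shell. The crop is accepted if
it reaches the coverage threshold and a minimum area (default 10 000 px;
no instrument-derived default exists, so it is configuration, not science);
otherwise a rejection report is returned with the reason. Rejection is data,
not an exception, so a batch run can tabulate it. "Extensive pixelation" is
operationalized purely as this coverage/area test; no texture-based noise
heuristic is attempted, since the original inspection such a rule would
mimic was manual.

## QC and aggregation

**Repeatability.** One-way random-effects model with specimen as the
grouping factor; R = σ²_b/(σ²_b + σ²_w). Balanced designs use the ANOVA
moment estimator (negative between-group components truncated at 0);
unbalanced designs use REML via a random-intercept mixed model. The CI is a
parametric bootstrap (default 1000 replicates, seeded) that re-estimates
with the unbalanced ANOVA moment estimator regardless of how the point
estimate was obtained — REML inside a 1000-replicate loop costs three
orders of magnitude more for no change in coverage at these sizes.
Specimens with a single scan are dropped with a logged warning; an
all-identical dataset returns R = 1 flagged degenerate.

**Aggregation** is strictly two-stage — scans averaged per specimen, then
specimen means per species — so a specimen with many surviving scans does
not outweigh its cage-mates. A pooled single-stage mean would.

**Influence filtering.** Cook's distance is computed for each specimen
value under the intercept-only linear model across all specimens for that
response (the regression design is not dictated by any instrument
convention; intercept-only is the minimal model consistent with "influence
on the specimen mean"). Default cutoff 4/n, configurable and logged.
Species rules, applied after flagging: a single-egg species loses its egg
if flagged; a multi-egg species with all eggs flagged keeps them all (an
entirely 'influential' species is more plausibly a genuinely extreme
species than a stack of errors); otherwise only flagged eggs are dropped.
Filtering runs once per response, independently — a specimen may be
excluded for Sa but kept for Ssk — and the pipeline does not re-iterate the
filter on its own output.

**Transforms.** log₁₀ Sa and log₁₀ Sku (their cross-species distributions
are right-skewed); Ssk is left untransformed. Non-positive Sa/Sku at this
stage is an error naming the species.

## Phylogenetic comparative stack

**Covariance.** C(i,j) is the root-to-MRCA depth of tips i and j; the
λ transform scales off-diagonals only. When normalized, C is divided by the
maximum root-to-tip depth so variance components are comparable across
trees; inside the mixed model the matrix is further converted to a
correlation matrix (unit diagonal), which is exact for ultrametric trees
and a deliberate standardization for non-ultrametric ones.

**Pagel's λ.** For fixed λ the MVN mean and variance have closed-form MLEs
(GLS mean; mean squared Mahalanobis residual, ML 1/n convention — ML rather
than REML because the two likelihood-ratio tests require comparable full
likelihoods). λ̂ comes from a 21-point grid followed by bounded 1-D
minimization (tolerance 1e-6); the optimizer's result is never allowed to
fall below the best grid point, and boundary optima are snapped to 0 or 1.
LR statistics against λ=0 and λ=1 are referred to χ²(1); at the λ=1
boundary this reference is conservative, which is accepted and documented
rather than corrected, matching standard practice for these tests. On a
star tree the likelihood is constant in λ; the fit is returned with a
flat-likelihood flag instead of an arbitrary confident estimate.

**PGLS.** GLS by Cholesky whitening; σ̂² = RSS/(n−p); t tests with n−p df.
R² is defined in whitened space against the GLS intercept-only fit — with
an identity correlation everything (coefficients, SEs, p-values, R²)
reduces exactly to OLS, which the tests assert at 1e-12. Rank-deficient
designs raise an error listing the aliased columns (found by pivoted QR).

**Collinearity screen.** Categoricals enter as indicator columns (first
sorted level as reference). Pass 1: while any pair of columns from
different predictors has |r| ≥ 0.75, drop the whole predictor whose columns
have the larger mean absolute correlation to everything else. Pass 2: drop
the predictor with the largest generalized VIF (Fox–Monette determinant
form) until all pass; GVIFs are compared on the GVIF^(1/df) scale so a
single-column predictor faces exactly the plain VIF < 10 rule. Constant
predictors are dropped with a warning before either pass.

## Phylogenetic mixed model

Gaussian animal model on individual-level rows: y = Xβ + a + b + e with
a ~ N(0, σ²_p A) (A = phylogenetic correlation at λ=1 — signal flexibility
is carried by the σ²_p/σ²_s split, not by estimating λ inside the sampler),
b ~ N(0, σ²_s I) per species, e ~ N(0, σ²_e I). Priors: inverse-gamma
(0.001, 0.001) on each variance and N(0, 10⁸) on fixed effects — weakly
informative defaults, configurable, and worth varying in any real analysis.

All full conditionals are conjugate, so the sampler is plain Gibbs: β and
the phylogenetic effect vector are multivariate normal draws via the
Cholesky of their precision (the latter involves A⁻¹, computed once);
species effects are independent normals; variances are inverse gamma.
Draws are bit-reproducible under the seed. Each conditional is unit-tested
against its closed-form moments, and parameter recovery is checked end to
end: over 50 seeded replicates at 40 species × 3 eggs with 20 000
iterations, the generating fixed effects fall inside their own 95% HPDs in
≥ 90% of (replicate, effect) pairs. The 40 × 3 size keeps one replicate
near four seconds while leaving the posterior informative; effective sample
sizes (Geyer initial-positive-sequence estimator) are reported per
parameter.

pMCMC = 2·min(P(draw > 0), P(draw < 0)) floored at 1/n_draws. HPD intervals
are the shortest contiguous window of sorted draws containing ⌈mass·n⌉
draws, verified against full window enumeration. Posterior prediction over
a factorial grid (continuous predictors at 3 equally spaced values from min
to max; categoricals at every level; rows in lexicographic predictor order)
multiplies the grid design matrix with the fixed-effect draws in batches of
500 rows — batching is memory control only and the output is bitwise
independent of batch size; random effects are marginalized at zero, so the
predictions describe an average species at each predictor combination.

## Synthetic data

**Height maps.** Spherical-cap base form (radius in µm, ∞ = flat) + a
correlated Gaussian field built by convolving seeded white noise with a
Gaussian kernel truncated at 4 correlation lengths (convolution, not
spectral synthesis, for exact cross-platform reproducibility), rescaled to
the target sd — defaults 50 nm sd, 3 px correlation length, at the
instrument's 768 × 576 px geometry. Pores are smooth radial-cosine pits
with per-pore depth |N(200, 50²)| nm and 4 px radius, subtracted; peaks are
the same shape added. Smooth pits survive second-order form correction
essentially intact, emulating pore openings rather than single-pixel
noise. Missing pixels: each pixel is scored by its distance to the nearest
edge plus seeded exponential jitter and the lowest-scoring fraction is
invalidated, concentrating dropouts at edges and corners as on a real
curved shell.

**Trees.** Yule process, waiting times Exponential(k·rate), tips labelled
in birth order; ultrametric by construction.

**Traits and responses.** Species means follow Xβ + u_phylo + u_species
with u_phylo ~ MVN(0, σ_p² C_λ) and scans adding N(0, σ_e²). Defaults:
λ = 0.6, σ_p = 0.3, σ_s = 0.2, σ_e = 0.1 on the log₁₀ Sa scale, intercept
3.0 (≈1000 nm), effects +0.5 for maculate eggs and −0.3 for semi-enclosed
nests, 1–10 specimens per species, 3 scans per specimen. No field data
exist to calibrate the within- vs between-species variances, so these are
chosen for testability — large enough signal to recover, small enough noise
that recovery failures indicate bugs rather than bad luck. The 15 predictor
values themselves are drawn independently per species (uniform categorical
levels, plausible continuous ranges) — they deliberately carry no
phylogenetic signal of their own, and no attempt is made to match absolute
empirical roughness ranges of real eggshells.

**What passing tests do and do not show.** The generators reproduce the
statistical structure the analysis assumes — Gaussian fields, smooth pits,
λ-structured species effects, balanced scan designs. Real scans add what
they omit: non-Gaussian instrument noise, spatially structured dropout from
dirt or gloss, pigment-dependent roughness within one egg, and predictors
that are themselves phylogenetically structured. Green tests therefore
validate the estimators and the pipeline's plumbing, not any biological
claim about real eggs.

## Problem sizes and determinism

Simulation-based checks run at: one 768 × 576 px surface for the Gaussian
moment check; 100 surfaces at 192 × 256 px for the pore-skewness rate; 200
replicates per true λ on 200-tip trees; 50 Gibbs fits of 20 000 iterations
at 40 species × 3 eggs. These sizes put every Monte-Carlo estimate's
sampling error well inside its asserted tolerance while keeping the full
suite runnable on a laptop in a few minutes. All randomness flows from
explicit integer seeds (numpy Generator); one shared seed expands to
per-component substreams by fixed offsets.

## Known limitations

- No ISO spatial/hybrid parameters (Sz, Sdr, ...) and no S-/L-filter
  wavelength separation; the four height-distribution moments only.
- The λ=1 LR test keeps the plain χ²(1) reference at the boundary.
- The Gibbs sampler covers the Gaussian family only, with inverse-gamma
  variance priors; no parameter expansion, no multi-response models.
- The repeatability module covers the Gaussian case only (responses here
  are Gaussian after transform).
- Posterior predictions marginalize random effects at zero; they are
  statements about predictor combinations, not about particular species.
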