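# Methods

`lhspectra` quantifies the functional diversity of life-history strategies
across a clade and simulates how extinctions of threatened species erode
it.  It was built around chelonian (turtle/tortoise) and crocodilian
life-history compilations, but nothing ties it to those taxa: any
species-level phylogeny plus a trait table and IUCN-style metadata fit
the pipeline.  This note records the models, the defaults and why they
are what they are, the numerical choices, and the limits of what the
synthetic tests demonstrate.

## Data model

Three inputs, matched by species label (exact string match after
space/underscore normalisation):

- a rooted phylogeny with branch lengths (Newick);
- a trait table with six focal life-history traits — adult survival `Sa`
  and juvenile survival `Sj` (probabilities per year), maximum lifespan
  `ML` (years), age at sexual maturity `La` (years), clutches per year
  `CN`, clutch size `CS` (eggs) — plus three imputation auxiliaries:
  adult body mass (g), body size, and incubation time (days).  Mass and
  size must be complete; everything else may have gaps (empty CSV cells);
- species metadata: IUCN category (CR/EN/VU/NT/LC/DD), six dichotomous
  threat flags (habitat degradation, local consumption, global trade,
  climate change, invasive species & disease, pollution), continent.

## Phylogenetic comparative layer

The Brownian-motion covariance `C` has `C[i,j]` = depth of the MRCA of
tips *i*, *j* and root-to-tip distances on the diagonal; trees need not
be ultrametric.  Pagel's lambda multiplies the off-diagonals.  Lambda is
estimated per trait by profiling the mean and rate out of the
multivariate-normal likelihood and running bounded Brent search on
[0, 1] (tolerance 1e-6), with a curvature-based standard error; the
estimates match `phytools::phylosig` to four decimals on shared fixtures
(see `tests/test_r_crosscheck.py`).  All solves go through Cholesky
factorisations; if a factorisation fails (duplicate tips from zero-length
branches are the usual cause) a jitter of 1e-10 times the mean diagonal
is added and logged.

Body-mass correction uses per-trait bivariate PGLS of each (log- or
logit-transformed) trait on log mass, with lambda fixed at that trait's
own ML estimate — the default behaviour of the standard comparative
toolkits when "phylogenetic residuals" are requested.

## Imputation

Missing traits are filled by chained-equations predictive mean matching.
Each incomplete variable is regressed (Bayesian linear regression with a
posterior parameter draw) on all other traits plus phylogenetic
covariates; each missing cell takes the observed value of one of five
nearest donors in predicted-mean space.  Choices:

- **Phylogenetic covariates**: the top `min(15, n/10)` eigenvectors of
  the double-centred Brownian covariance (phylogenetic eigenvector
  regression).  Mask-and-recover experiments in the test suite confirm
  they reduce recovery error when the generating signal is strong
  (lambda >= 0.8).
- **Scales**: traits are modelled on log scale (logit for survivals) and
  z-scored inside the chain, so PMM distances are comparable across
  variables; donors guarantee imputed values stay inside the observed
  range on the natural scale.
- **Schedule**: 15 sweeps per chain, variables visited in order of
  increasing missingness; no convergence diagnostic is applied (fixed
  maxit by design).
- **Replication**: 40 independent single-imputation chains (seeds
  master+1 … master+40).  Observed cells are bit-identical across the 40
  completed datasets; only imputed cells vary, and that variation is the
  imputation uncertainty carried downstream.
- A single PMM draw deliberately carries matching noise, so recovery is
  assessed on the across-dataset mean, which is the multiple-imputation
  point estimate.

Diagnostics: per-trait overlap coefficients between observed-value and
imputed-value kernel densities, and a Procrustes statistic comparing
functional-space configurations.

## Phylogenetic PCA

The six focal traits are transformed, mass-corrected, and z-scored, then
decomposed by a pPCA that estimates one joint lambda by maximum
likelihood under a matrix-normal model, centres with the GLS phylogenetic
mean, forms the evolutionary covariance
`E = (X - 1a')' C(lambda)^-1 (X - 1a') / (n - 1)`, converts it to
correlation scale, and eigendecomposes.  With a star phylogeny this
reduces exactly to ordinary correlation PCA (tested to 1e-8).  Axis signs
are arbitrary, so a convention is imposed: `ML` loads positively on PC1
(the fast–slow continuum runs left-to-right) and `CS` positively on PC2
(the reproductive-strategy axis).  The Kaiser criterion (eigenvalue > 1)
after varimax rotation reports how many axes carry substantial structure,
but the functional space itself always uses the first two *unrotated*
principal axes: the published variance-explained percentages for such
spectra refer to unrotated axes, and the rotated solution is reported
alongside rather than substituted.

The 40 per-imputation results are pooled after aligning axis order and
sign to the first result (greedy matching on absolute loading
correlation, ties broken by original order); pooled scores/loadings are
element-wise means, with SD/sqrt(40) kept as pooling uncertainty, and the
pooled axes re-sorted by pooled variance.

## Trait probability density

Each species contributes a bivariate normal kernel at its (PC1, PC2)
coordinates; the mean of kernels is evaluated at the centres of a
200x200-cell grid (midpoint rule) and renormalised to integrate to
exactly 1, compensating tail truncation.  Numerical choices:

- **Bandwidth** is an unconstrained plug-in matrix: data are sphered with
  the sample covariance, the curvature functional R(laplacian f) is
  estimated from a normal-scale pilot via the exact Gaussian convolution
  identity, the AMISE-optimal scalar bandwidth is computed on the sphered
  scale, and the result is mapped back through the covariance, giving a
  full (non-diagonal) matrix that is affine-equivariant.  Collinear
  scatters fall back to Silverman's diagonal rule with a warning.
- **Grid extent** is the data range padded by 3 kernel SDs per side, and
  both bandwidth and grid are estimated once on the full species pool and
  reused for every subset, so "cells that become empty" is meaningful
  cell-by-cell.
- **Thresholding**: the 99% highest-density region (smallest set of cells
  holding 99% of mass) defines occupancy; remaining mass is renormalised
  to 1.  Density ties break by row-major cell index for determinism.
- **Summaries**: functional richness is occupied-cell count times cell
  area; quantile contours at 50–99% are nested HDR masks; the "hotspot"
  summary reports the fraction of species inside the 50% HDR and its area
  relative to the 99% spectrum.

## Extinction scenarios and nulls

IUCN scenarios remove species cumulatively (-CR, then -EN = CR+EN,
-VU = all threatened, -NT adds Near Threatened); DD species are never
removed.  Threat scenarios remove either all flagged species or only the
threatened flagged ones.  Scenario pools follow the analysis design:
IUCN scenarios run on the IUCN-assessed species (category != DD), threat
scenarios on species with known threat flags.  Loss is the percentage of
baseline-occupied cells left empty after rebuilding and re-thresholding
the TPD for the surviving set (the thresholded baseline is the default;
`q` is exposed).

Each scenario is compared with a 999-iteration null in which the same
number of species is removed uniformly at random (no phylogenetic
weighting — the null randomises species identity only); the 5th/50th/95th
percentiles (linear interpolation) form the envelope and a loss above the
95th percentile flags a greater-than-chance erosion.  The null loop is
vectorised: per-species kernels are precomputed once and subset densities
obtained by subtracting removed rows from the total; the HDR is applied
through its density cutoff, which coincides with the stable-order mask
whenever the cutoff value is unique (generic for kernel mixtures).

## Risk surfaces

The probability that a species is high-risk (CR or EN vs the rest, DD
excluded) — or affected by a given threat — is modelled as a binomial
GAM with a single 2-D smooth of (PC1, PC2): a tensor product of cubic
B-splines (8 basis functions per margin), second-order difference
penalties on both margins, a sum-to-zero constraint absorbing the
intercept, and penalized IRLS with the smoothing parameter chosen by GCV
over a 21-point log-spaced grid.  A tiny fixed ridge (1e-7) keeps the
penalty null space identified on sparse data.  The smooth is tested
against the constant model with a Wald-type statistic on the smooth part
of the linear predictor, using a rank-truncated pseudo-inverse of its
penalized covariance with the rounded effective degrees of freedom as
reference chi-square df.  Under label–position independence the p-values
are approximately uniform (checked over 200 replicate fits); this is a
documented variant, not a replication of mgcv's approximations, whose
exact chi-square/p values are out of scope by design.  Confidence bands
are formed on the link scale and mapped through the logistic, so they
always contain the point estimate; grid cells outside the data bounding
box are flagged as extrapolation.

## Synthetic worlds

The generator produces the study conditions end-to-end: a birth–death
tree conditioned on the tip count (defaults: 259 species, birth 1.0,
death 0.3, up to 1000 retries on extinction); traits evolved on the
log/logit scale as lambda-scaled Brownian motion (default lambda 0.8,
rate 0.35 per unit tree height) around means chosen for a ~30-year
lifespan, ~3 kg reptile with ~1.6 clutches of ~10 eggs per year; an
allometric term on centred log mass per trait; and two shared latent
Brownian factors — pace of life (loading on survivals, lifespan,
maturity) and a clutch-frequency vs clutch-size trade-off — that induce
the cross-trait correlation real life-history compilations show.
Survival traits are built on the logit scale so they stay in (0, 1).

Missingness hits every trait except mass and size independently at a 38%
base rate, with an additive log-odds bias (default 0.4) for threatened
species — missing-at-random given threat status, the association the
real compilation exhibits.  IUCN categories come from a logistic model on
the species' position in trait space; high-risk draws split into
CR/EN/VU/NT at odds 46:36:49:25 (the category balance of the real
dataset), the rest are LC, and a ~2.7% fraction is relabelled DD.
Threat flags are independent logistic draws with per-threat coefficients;
continents are uniform labels.

What the generator does **not** emulate: non-random taxonomic sampling,
measurement error, correlated threat flags, geographic structure in
traits or threats, and the real data's specific trait distributions.
Passing tests therefore demonstrate the *machinery* — estimator
correctness, calibration of nulls and tests, invariants — not that the
published effect sizes would be recovered from the real compilation,
whose supplementary files are the input the pipeline expects for that.

## Problem sizes used in checks

The acceptance script runs the full study scale: 259 species, 38% gaps,
40 imputations, 200x200 grid, 999 null iterations (about half a minute).
The test suite uses smaller worlds (5–300 species, 3–5 imputations,
40–150 grid cells, 9–999 null iterations) chosen per test so each check
is decisive for the property it probes.

## Known limitations

- Lambda estimation at intermediate signal is intrinsically noisy: at
  n = 300 the ML estimator's sampling SD near lambda = 0.5 is ~0.09, so
  no implementation can pin intermediate lambda to ±0.1 with high
  probability at that sample size.
- The smooth-term test is a Wald-type approximation; its chi-square
  reference is approximate for penalized fits, and only calibration-level
  agreement (not value-level agreement with mgcv) should be expected.
- Lambda > 1, OU/EB models, multivariate lambda, >2-D TPD spaces,
  probabilistic extinction weighting, and threat-interaction models are
  out of scope.
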