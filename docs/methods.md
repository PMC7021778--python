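# Methods

This note documents the statistical models implemented in `divsignal`, the
choices made where the design was genuinely open, and what the synthetic
data generator does and does not emulate.

## Data model

The unit of analysis is the taxonomic family. Input is a binary site ×
species matrix (nonzero abundances are coerced to presence, with a warning),
a species → family map, and per-site metadata: projected coordinates in one
consistent unit, elevation in metres, and habitat cover proportions in
[0, 1]. Cover proportions are *not* required to sum to 1 per site — only the
[0, 1] range is validated, since surveys often record non-exhaustive habitat
categories. Families enter the analysis when they occupy at least
`min_plots` sites (default 50) and contain at least `min_species` species
(default 5); both thresholds are inclusive. Species traits aggregate to
family level as means and standard errors over member species (body size on
the natural-log scale; the base is configurable), and binary features as
incidences. A single-species family gets SE = 0 with a warning rather than
an error, so synthetic edge cases do not abort a run.

## Phylogeny

Trees are ultrametric with branch lengths in Ma. A patristic matrix can be
built directly from pairwise divergence-node ages (distance = 2 × age) and
turned into a tree by UPGMA (scipy average-linkage; node height = half the
merge distance), which reproduces an ultrametric input matrix exactly. The
Brownian covariance C has C[i,j] = shared root-to-MRCA path length, computed
as (d_root(i) + d_root(j) − patristic(i,j))/2, valid for any rooted tree.
Multifurcations are allowed; ultrametricity is checked to a relative
tolerance of 1e-6. Subsetting a tree to fewer families goes through
UPGMA on the sub-patristic matrix — exact for ultrametric trees and immune
to pruning-library edge cases.

## α responses

**Edf-α.** ln(richness) is smoothed on elevation with a rank-10 cubic
B-spline basis (quantile knots) and the exact integrated-squared-second-
derivative penalty. That penalty's null space is the linear functions, so
as λ → ∞ the smooth collapses to a straight line (Edf → 1) and as λ → 0 it
approaches the unpenalized rank (Edf → 9); a coefficient-difference penalty
was rejected because with unequal knot spacing its null space is not
linear-in-x and the smoother then cannot represent a linear cline at high
penalty. λ minimizes GCV = n·RSS/(n − tr H)² on an 81-point log grid spanning
14 decades around a scale-matched reference; Edf is tr H minus the number of
unpenalized columns (intercept, screened coordinates). The smooth's p-value
is an approximate F-test of the penalized fit against the covariate-only
model on (Edf, n − tr H) degrees of freedom. The "corrected" Edf variant
zeroes Edf when that p ≥ 0.05; both variants are carried through the signal
suite in parallel. Coordinates enter as linear terms when a pre-screen
(simple regression of ln richness on x or y) is significant at 0.05.

Calibration conditions (used by the tests and the acceptance script):
a linear cline (slope 0.003 per m, noise sd 0.3, 200 sites) should give
median Edf ≈ 1, and a hump-shaped quartic −(1−u²)² spanning 0.5 log units
with noise sd 0.1 should give median Edf ≈ 5. The quartic's *shape* matters:
for a W-shaped quartic (u⁴ − u²) at low noise, GCV selects Edf ≈ 8 — we
verified the same value with an independent penalized-spline implementation
(R mgcv, cubic regression splines under GCV) — so the hump, the shape a
richness–elevation curve actually takes, is the meaningful reference signal.

**Peak-α.** The two-segment model ln r = β₀ + β₁·elev + β₂·max(0, elev − ψ)
(+ screened coordinates) is profiled over candidate breakpoints: the union
of a 200-point uniform grid between the 5th and 95th elevation percentiles
and the observed elevations in that band (so an exact change point on a
site is hit exactly). A deterministic grid was preferred over iterative
linearization to avoid convergence failures on small families. The 95% CI
inverts the profile F statistic, (SSE(ψ) − SSE_min)/(SSE_min/(n − p)) ≤
F₀.₉₅(1, n − p), with the crossing points linearly interpolated between
candidates; SE = (hi − lo)/3.92 assumes approximate normality. If the
two-segment model does not beat the single line (F test with 2 numerator df,
counting ψ as a parameter; p ≥ 0.05) — including the degenerate case where
the line already fits perfectly — the estimate falls back to the elevation
of maximum smoothed richness, the SE spans the occupied range, and the
result is flagged `fallback`. The flag matters: the automated rule replaces
a manual curve-inspection step, and flagged peaks should be treated as
order-of-magnitude summaries. Under correct specification (break at 1500 m,
slopes ±0.002, n = 300, sd 0.2) the CI covers the true break in ≈ 95% of
replicates.

## β responses

Sørensen dissimilarity uses scipy's `dice` metric, which is the same
(b+c)/(2a+b+c) formula on binary vectors. Environmental distances are
Euclidean on (x, y), |Δelevation|, and Euclidean on arcsin √cover. MRM
regresses the vectorized lower triangle of the response on the predictors'
triangles by OLS; the permutation null jointly permutes rows and columns of
the *response* matrix only (the standard MRM scheme) and compares |t| per
slope (two-sided) and R² for the whole fit, with p = (1 + #{perm ≥ obs})/
(n_perm + 1); with ≤ 5 sites all permutations are enumerated exactly.
Slopes and their SEs come from the one joint three-predictor MRM; the three
R² variables come from three single-predictor MRMs and are reported as 0
when the permutation p ≥ 0.05. Whether the per-gradient R² should come from
single-predictor or joint fits is ambiguous in principle; both are computed
internally and the single-predictor values are exported.

## Evolutionary models and Monte-Carlo comparison

WN: y ~ N(μ, σ² + se²) iid. BM: y ~ MVN(μ·1, σ²C + diag(se²)). Without
measurement error both MLs are closed-form; with error a bounded 1-D search
profiles σ² (μ profiled analytically inside). δ = 2(lnL_BM − lnL_WN); the
sign convention makes positive δ favour BM. Because the models are not
nested in the usual sense, preference uses the parametric Monte-Carlo null:
simulate n_sim = 1000 datasets from each fitted model (simulated tips get
extra N(0, se²) noise when SEs are in play, and refits reuse the same SEs),
refit both models to each, and call BM preferred when the observed δ exceeds
the 95th percentile of the WN-generated distribution. Power is the fraction
of BM-generated δ above that same cutoff. On a star tree (C ∝ I) the two
models are one model in different parameterizations, so δ ≡ 0 and the two
distributions coincide — a structural self-check in the tests. Replicates
whose refit fails are dropped and counted.

## Signal statistics

**Blomberg's K** = (MSE₀/MSE) / E[MSE₀/MSE], with MSE₀ the mean squared tip
deviation from the phylogenetic GLS mean, MSE = (y−μ̂)ᵀC⁻¹(y−μ̂)/(n−1), and
E[·] = (tr C − n/(1ᵀC⁻¹1))/(n−1). With SEs, the BM rate is first estimated
by ML under σ²C + diag(se²) and K is computed on C + diag(se²)/σ̂² — the
error-inflated covariance — which preserves E[K] = 1 under BM with zero
error. The permutation p is the proportion of tip-shuffled datasets with a
variance ratio at least as large as observed (the standard one-tailed signal
test; "departure from independence" has no sign). The implementation is
cross-checked in the test suite against R phytools::phylosig, with and
without SEs.

**Fritz–Purvis D** sums |sister-clade differences| of downpass-averaged
node values and scales the observed sum between the mean under 1000 tip
shuffles (D = 1) and 1000 thresholded-BM simulations at the observed
prevalence (D = 0). It is applied to the widespread-vs-rare flag to ask
whether the families entering the analysis are a phylogenetically random
subset of the regional pool.

**Distance regressions.** Pairwise response dissimilarities — Cohen's d
|xᵢ−xⱼ|/√((seᵢ²+seⱼ²)/2) when SEs exist (the two SEs serve as the dispersion
estimates; no per-family sample sizes are available at this level), raw
absolute differences otherwise — are regressed on patristic distances.
The null permutes family labels of the dissimilarity matrix (one-matrix
permutation; the patristic matrix stays fixed), two-sided on the slope,
exhaustive below six families.

**C-score** = (Rᵢ−S)(Rⱼ−S)/(RᵢRⱼ) on family-level occupancy vectors (OR over
member species). This is the reading under which the endpoints are exact:
0 for nested/sympatric occupancies, 1 for disjoint ones.

## PGLS and model selection

Residual covariance σ²·W^{1/2}VW^{1/2}, V the BM correlation (C scaled to
unit diagonal) or identity, W the relative variance weights normalized to
mean 1 (zeros floored at 1e-8 × mean with a warning). Estimation is ML, not
REML, so AICc is comparable across fixed-effect structures. k counts the
coefficients plus σ²; the BM correlation adds no parameter (it is fixed by
the tree). AICc = −2lnL + 2k + 2k(k+1)/(n−k−1); candidates with n ≤ k+1 are
dropped with a note. All predictor subsets × {none, BM} are enumerated
(deterministic, and equivalent to forward/backward search at ≤ 3
predictors); Akaike weights are reported and models within 3 AICc of the
best are flagged as equally supported.

## Synthetic data

The generator emulates the statistical structure the pipeline estimates.
A Yule tree is rescaled to exact depth (default 300 Ma). Family peaks evolve
under BM with rate σ² = peak_sd²/depth (default marginal sd 400 m around a
1200 m root), clipped to the central 90% of the elevation range (the
invariant that a peak lies inside the gradient outranks exact BM marginals
in the tail). Defaults: 12 families × 300 sites × 12 species per family,
elevations uniform on 0–2300 m, coordinates uniform on a 100-unit square,
species-optimum scatter (width) 250 m, amplitude 0.9, per-species
elevational tolerance lognormal around 300 m, geographic decay lognormal
around 0.03 per unit. Habitat covers are a softmax of logits drifting with
elevation, so habitat and elevational distances correlate (adjustable to
zero). Occupancy is Bernoulli: amplitude × Gaussian(elevation; optimum,
tolerance) × exp(−rate × distance to a species range center). All stages
draw from named substreams of one master seed.

What it does **not** emulate — and hence what green tests do not establish
about field data: spatially autocorrelated sampling designs, abundance
structure, detection error, richness differences among families' regional
pools, and trait–response couplings. Recovery tests show the estimators
track their own generating model, not that any particular field system
satisfies it.

## Problem sizes and numerical choices

The test suite and the acceptance script use deliberately modest replicate
counts chosen to make the Monte-Carlo error comfortably smaller than the
tolerance being checked: 500 replicates for the K calibration and the
type-I-error checks (binomial sd ≈ 0.01 at p = 0.05), 100 replicates for
Edf medians and peak-CI coverage, 500 simulations per arm for the
Monte-Carlo model comparison. Permutation counts follow the analysis
defaults (999 MRM / 1000 signal) in production code and drop to 49–199 in
tests where only calibration, not fine p-resolution, is at stake.
Matrix solves use Cholesky factorization where symmetry allows; the BM
Cholesky adds a 1e-12-scaled ridge to tolerate zero-length cherry branches;
permutation comparisons use a 1e-12 slack so exact ties count as "as
extreme". Known limitations: the GCV criterion can undersmooth on small
presence-only samples (the corrected-Edf variant exists for exactly that
reason); the profile-grid breakpoint CI is approximate near the percentile
clamps; and D is computed for bifurcating or multifurcating trees but its
thresholded-BM endpoint assumes the observed prevalence is not extreme.
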