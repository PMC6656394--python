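# Methods

This note records the statistical model implemented by `kpsize`, the
choices made where the design was genuinely open, what the synthetic-data
generator does and does not emulate, and the numerical details a
maintainer would need.

## Direct estimation

The RDS-II (Volz–Heckathorn) estimator weights each respondent by the
inverse of their reported network size, correcting the
degree-proportional inclusion probabilities of chain-referral sampling.
It is implemented as the plain ratio `Σ bᵢ/dᵢ / Σ 1/dᵢ`, which is
invariant to rescaling all degrees by a constant and reduces to the
sample proportion under equal degrees.  Zero-degree respondents are
rejected at parse time rather than imputed.

Uncertainty for the proportion uses a seeded nonparametric bootstrap over
respondents (default 1,000 resamples, percentile interval).  A
recruitment-tree-aware bootstrap would be preferable in principle, but
requires chain topology that the downstream analysis never uses;
resampling respondents is assumption-light and reproducible.  Resamples
in which every indicator is zero are discarded (the multiplier would be
undefined) with a warning and a retry cap; this slightly truncates the
lower tail when source coverage is very rare.  The multiplier CI is the
proportion CI inverted, bounds flipped.  A source with total count zero
yields a degenerate all-zero estimate with a warning rather than an
error, since program logs can legitimately be empty.

## Regression preparation

Responses are natural-log fractions `y_ij = log(n_ij/N_i)`.  The log (not
logit) scale is kept because observed fractions are small and the log
scale gives `β₁` a direct reading as the relative growth rate of the key
population with area size.  The variance multiplier is the squared width
of the 95% CI on the log scale, `w_ij = (log(u_ij/l_ij))²`, which depends
only on the CI ratio; the proportionality constant is absorbed by the
free scale `τ²`.  Multiple direct estimates in one area are treated as
independent given the area covariates — with five areas there is no
information to estimate within-area correlation, and area random effects
are deliberately omitted for the same reason.

Prevalence enters in percent units (a coefficient per percentage point).
The male 18–29 population is derived from total male counts with a
constant 55% age fraction by default; the fraction is an explicit
parameter because published commune-level pairs for Abidjan imply ≈0.44,
and no department-level age structure exists to resolve the discrepancy.

## Spatial model

Prevalence is a stationary GP with constant mean and exponential
covariance `σ² exp(−φ d)`, `d` the Euclidean distance on (lon, lat) in
decimal degrees.  No great-circle correction is applied: the country
spans a few degrees and the decay prior `Unif(0, 10)` is calibrated to
the degree scale.  There is no nugget; a fixed relative jitter of
`1e−8·σ²` stabilizes Cholesky factorizations.

The empirical variogram is the per-bin average of squared pairwise
differences **without** the conventional ½ factor, and the fitted curve
is `σ²(1 − exp(−φ m))`.  These two conventions are individually standard
but jointly inconsistent: the no-half variogram saturates at `2σ²`, so
the fitted sill estimates twice the GP variance on GP-simulated data.
Both are implemented exactly as stated in the source analysis; the
self-consistency test compares the fitted sill against `2σ²`.  The curve
fit (count-weighted least squares) is used only for diagnostics and to
initialize maximum likelihood.

MLE uses the profile likelihood: for fixed `φ` the mean is the GLS
solution and the variance its plug-in estimate, leaving a 1-D bounded
search over `φ ∈ [1e−3, 100]`.  Kriging uses the mean-corrected
conditional-normal form `μ + v'Σ⁻¹(H − μ1)`; a variant that omits the
mean correction is only valid for a centred field and is not offered.  A
prediction at an observed site returns that site's value with variance
zero.

A caution on spatial signal: at the fitted decay (≈7.7 per degree) the
correlation length is ~0.13°, so sites placed uniformly over the whole
country are nearly uncorrelated.  The real departments cluster far more
densely than uniform placement; tests of spatial-signal properties
therefore place sites on a ~1° window, where nearest-neighbour
correlations reach ~0.5 and kriging demonstrably beats mean imputation.

## Hierarchical model and sampler

The joint posterior combines (a) the heteroscedastic regression
likelihood over all direct estimates, (b) the GP likelihood of observed
prevalences, and (c) priors `β ~ N(0, 10⁶I)`, `μ ~ N(0, 10⁶)`,
`φ ~ Unif(0, 10)`, `1/τ² ~ Gamma(0.01, 0.01)`, `1/σ² ~ Gamma(2, 1)`
(shape–rate).  Prior hyperparameters are configurable (`PriorSpec`); the
defaults above are the model of record.

The sampler is Metropolis-within-Gibbs:

- `β` is drawn **jointly** from its exact conjugate normal conditional.
  This matters: the training areas are the largest ones, so `log N`
  spans little range and the `β` posterior is extremely correlated —
  under componentwise random-walk updates the effective sample size
  collapses to single digits even at 50,000 iterations and interval
  coverage fails badly.  The exact block draw removes the problem
  entirely.
- `1/τ²` has its conjugate Gamma Gibbs update,
  `Gamma(a + n/2, b + S/2)` with `S = Σ (y−x'β)²/w`.
- `μ`, `log σ²` and `logit(φ/10)` get componentwise Gaussian random
  walks (Jacobians included) whose scales adapt toward a 0.44 acceptance
  rate in batches of 50 during burn-in only, leaving the post-burn-in
  chain a fixed-kernel sampler.

Defaults are 30,000 iterations with 15,000 burn-in; testing and examples
use shorter chains, which the exact `β`/`τ²` draws make adequate (ESS for
`β` is roughly half the retained draws).  Acceptance rates outside
(0.05, 0.8) after adaptation and ESS below 100 (arviz bulk ESS) raise
warnings.  With no data the chain samples the prior exactly for `β` and
`1/τ²` and by Metropolis for the rest — the basis of the prior-recovery
test.  GP correlation Cholesky factors are cached per `φ` value so the
per-iteration cost is one factorization.

## Prediction

Composition sampling: for each retained draw, an area with observed
prevalence uses it directly; otherwise prevalence is drawn from the
kriging conditional under that draw's `(μ, σ², φ)`, negative draws
truncated at zero (the GP has unbounded support; prevalence does not).
Missing-area draws are independent across areas by default, conditioning
only on observed areas; a joint draw across all missing areas is
available (`joint=True`) but off by default, as the per-area marginal
intervals it changes little do not justify the extra factorizations.

The log-population covariate is floored at the 10% linear-interpolation
quantile of all 61 populations.  The truncation reflects a judgment that
the fitted negative slope flattens below the range the training data
cover; it applies to the covariate only, and the fraction→count
conversion uses the true `N` (configurable, since flooring `N` in the
conversion too is an equally defensible reading).  Point estimates are
posterior medians; intervals are central 95% quantiles; the scale-free
uncertainty measure is the relative width `(q97.5 − q2.5)/median`,
appropriate for roughly log-normal count draws.  Leverage
`x'(X'X)⁻¹x` against the training design uses each area's truncated log
population and its observed (or posterior-median imputed) prevalence.

## Model selection

Candidates always include prevalence plus at most one more covariate.
Each fold drops all of one area's estimates, fits weighted least squares
(weights `1/w_ij`) on the rest, and predicts the held-out area's
fraction `exp(x'β̂)` against the mean of its observed fractions.  The
score is the mean squared error on the **fraction** scale — the
count-scale reading of the selection formula yields values inconsistent
with the magnitudes (~10⁻³) the comparison is known to produce — with a
count-scale option retained.  WLS (not the full MCMC) is used per fold:
selection precedes the hierarchical model and must run 25 fits in a
blink.  A fold whose linear predictor explodes is capped at `exp(700)`
so a wildly extrapolating candidate receives a huge finite penalty
rather than a float overflow.

## Synthetic-data generator

The generator emulates the study design: 61 areas with coordinates
uniform on the Côte d'Ivoire bounding box (lon −8.6..−2.5, lat
4.4..10.7); male 18–29 populations log-normal (meanlog 9.6, sdlog 1.0,
median ≈ 15k men); prevalence drawn jointly from the exponential GP at
the published estimates (μ=2.55, σ²=0.86, φ=7.68) and floored at zero;
half the areas (non-training only) masked as missing.  The five training
areas are the **largest** by population, deliberately reproducing the
extrapolation pathology that motivates population truncation.  Direct
estimates per training area (3–5 of them) are generated from the
regression model at the published coefficient medians (β = (2.62, −0.79,
0.63), τ² = 0.65): a log-scale CI half-width `h ~ Unif(0.15, 0.6)` —
reproducing the published CI ratios of ~1.3–3.2 — sets `w = (2h)²`, the
response is sampled, and the estimate and CI are emitted on the count
scale.  Fractions ≥ 1 are resampled with a cap.  The RDS generator gives
members shifted-Poisson degrees (mean 8), assigns source membership
uniformly (independent of degree), and samples respondents
degree-proportionally without replacement — exactly the design RDS-II
corrects.

What the generator does **not** emulate: real department geography and
population sizes (coordinates are uniform, not clustered; the true
spatial density of areas is higher, making real kriging more informative
than on uniform layouts); recruitment-tree dependence in RDS;
correlation among the multiple sources in one area; any systematic
violation of the multiplier independence assumption.  Passing tests
therefore certify the statistical machinery under the model's own
assumptions, not robustness to their failure.

## Problem sizes and numerical choices

Tests and the acceptance script use scaled-down chains (2,000–6,000
iterations) and replicate counts of 20–50, sizes at which the exact
conjugate draws keep Monte Carlo error well below the tolerances being
checked.  Simulation-based calibration runs on a reduced design (10
areas, 2 estimates each) with narrow proper priors, since generating
data from the diffuse defaults produces astronomically overflowing
fractions; SBC checks the sampler against whatever prior it is given, so
this choice tests correctness without touching the shipped defaults.
Quantiles everywhere are linear-interpolation empirical quantiles.
Degenerate inputs (empty respondent lists, all-zero indicators,
zero-width CIs, flat variograms, rank-deficient designs, missing
prevalence where it is required) raise `ValueError`/`RuntimeError` with
the offending record named.

## Known limitations

- The intercept `β₀` is weakly identified by five areas whose log
  populations span ~1 unit; its posterior (and occasionally the whole
  predictive distribution) is extremely wide in replicates where the
  training populations happen to be nearly tied.  This is faithful to
  the design's information content, not a sampler artifact.
- Euclidean distance on degrees distorts east–west distances by the
  cosine of latitude (~0.5% over this latitude band).
- The two-stage treatment of direct estimates as data ignores their
  sampling correlation within areas.
- Truncation of negative prevalence draws introduces a slight upward
  bias in imputed prevalence for areas far from data.
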