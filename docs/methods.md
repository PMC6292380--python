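# Methods

## Model

Each of m features has a p-value Pᵢ and a covariate vector xᵢ. The feature
is null with prior probability π₀(xᵢ) = Pr(θᵢ = 0 | xᵢ), where θᵢ indicates
a true alternative. The central modeling assumption is that **conditional on
the null, p-values are Uniform(0,1) and independent of the covariates**;
only the prior probability of being null, and possibly the alternative
p-value distribution, may depend on xᵢ.

For a threshold λ, the exceedance indicator Yᵢ = 1(Pᵢ > λ) has

E(Yᵢ | xᵢ) = π₀(xᵢ)(1 − λ) + Pr(Pᵢ > λ | θᵢ = 1, xᵢ)·(1 − π₀(xᵢ))
           ≈ π₀(xᵢ)(1 − λ)

for λ large enough that alternatives rarely exceed it. Regressing Y on the
design **Z** and dividing by 1 − λ therefore gives a (conservatively biased
upward) estimate of π₀(xᵢ) at each λ; smoothing over the λ-grid and reading
off the largest λ trades the small-λ bias against the large-λ variance, the
same device used by the classical scalar estimator.

The logistic link is the default: π₀ regressions target means in (0, 1) and
a linear model would amplify small differences between large π₀ values. The
linear method is kept because it reduces *exactly* to the scalar threshold
estimator (m − R)/((1 − λ)m) under an intercept-only design, an identity the
test suite asserts to machine precision.

The plug-in F̂DR(xᵢ) = π̂₀(xᵢ) · BHᵢ is deliberately **not re-monotonized**
in p: because π̂₀ varies with x, a feature with a larger p-value but smaller
π̂₀(x) may legitimately receive a smaller estimated FDR. Since π̂₀ ≤ 1 the
BH discovery set is always contained in the plug-in discovery set at the
same nominal level.

## Tunable parameters

| parameter | default | meaning / rationale |
|---|---|---|
| λ grid | 0.05, 0.10, …, 0.95 | unitless thresholds; 19 points spanning (0,1), the grid used by the q-value tradition |
| smoothing df | 3 effective df | cubic smoothing spline over the λ profile; enough to capture curvature without chasing noise on 19 points |
| method | logistic | `linear` available (exact scalar reduction; can leave [0,1] before clipping) |
| bootstrap B | 100 | feature resamples for percentile CIs; α defaults to 0.05 |
| nominal FDR | 0.05 | discovery cutoff applied to the plug-in estimates |
| spline df (design) | 3 | natural cubic spline for continuous covariates (e.g. per-SNP sample size); interior knots at equispaced quantiles, boundary knots at the extremes |

## Numerical choices

- **λ-smoothing as a fixed linear map.** The penalized cubic smoothing
  spline on the fixed λ-grid is a linear smoother; its penalty is solved
  once (Brent root-finding on trace(S) = df) and the evaluation row of the
  hat matrix at λ = 0.95 is cached and applied to all m profiles. This makes
  smoothing O(m·n_λ), and makes "smooth the mean profile = mean of smoothed
  profiles" an exact identity (tested).
- **Logistic fitting.** Newton/IRLS with step-halving on the deviance;
  non-convergence (e.g. perfect separation when almost all Yᵢ = 1 at an
  extreme λ) falls back to the linear fit for that λ with a logged warning,
  keeping the profile complete for smoothing. All-zero or all-one indicator
  vectors bypass regression: the constant is the MLE. The IRLS is
  cross-checked against statsmodels' binomial GLM in the tests.
- **Clipping.** Per-λ estimates are thresholded into [0, 1]; the final
  smoothed value and bootstrap percentile bounds are clipped the same way.
- **Scalar estimator floor.** (m − R)/((1 − λ)m) can be 0, which would zero
  every plug-in FDR; the scalar estimate is floored at 1/m with a warning.
- **Ties and degeneracies.** Exceedance uses the strict inequality P > λ.
  BH uses a stable sort so tied p-values receive equal adjusted values.
  Quantile-category boundaries assign ties to the lower category.
- **Bootstrap.** Features are resampled with replacement, p-value and
  covariate row jointly (preserving the dependence the method models); the
  full smoothed pipeline is re-run per resample and predictions are made at
  the original covariate rows. Resamples that fail to fit are skipped; fewer
  than 90% successes raises rather than returning quantiles from too few
  draws.
- **Rank checks.** Design rank is the SVD numerical rank with tolerance
  max(m,p)·eps·σ_max; rank-deficient designs warn with the column names, and
  estimation refuses designs whose rank reaches m.

## Simulation engine: what it emulates

The generator reproduces the validation study design: per feature a
covariate x₁ ~ Uniform(0,1) (and, in the category scenarios, x₂ uniform on
3 levels), a Bernoulli(π₀(x)) null indicator, and test statistics from one
of: Beta(1,20) alternative p-values against Uniform(0,1) nulls; z-statistics
with alternative means drawn ±N(3,1) (fair-coin sign) and two-sided p
against N(0,1); location-shifted t(10) statistics with two-sided p against
t(10); noncentral χ² statistics (1 or 4 df) with noncentrality the square of
a N(3,1) draw and upper-tail p against the central χ². Scenario families for
π₀(x): flat 0.9; a smooth decreasing curve; that curve vertically offset
within categories (and ×0.6); the identity π₀(x₁) = x₁ and its powers x₁^k;
and the global null π₀ ≡ 1. Block dependence multiplies nothing into the
truth layer: equicorrelated Gaussian blocks (shared-factor construction)
replace the independent noise, and the multivariate t divides each
replicate's block-normal vector by a single χ²(10)/10 draw.

Defaults are the study's stated world: m = 1,000 or 10,000, 200 replicates
per cell (1,000 for the global-null calibration), nominal FDR 5%. Where the
study leaves a choice open we fixed: x₁ ~ U(0,1) (forced for the scenarios
where π₀(x₁) = x₁^k must be a probability), fair-coin effect signs, and
independent per-replicate child seeds spawned from one master seed.

What the generator does **not** emulate: realistic LD-style short-range
correlation (blocks are an idealization), covariate-dependent alternative
effect sizes, publication-bias truncation, or composite-null misspecification.
A green simulation test therefore establishes calibration and power under
the stated sampling models only.

The exact curves for the "smooth" and "category-offset" π₀ scenarios are
package choices (logistic-shaped decrease from ≈0.95 to ≈0.70, category
offsets 0/−0.075/−0.15): they are pluggable, and no quantitative validation
target depends on those two families.

## Known limitations

- The per-feature π₀ regression is conservative on average but can be
  anti-conservative for small m with flexible (spline) designs — the
  realized FDR in the m = 1,000 spline cells runs slightly above nominal,
  matching the study this package validates against. Prefer simpler designs
  when m is small.
- The linear-logistic fit cannot represent a linear π₀(x) exactly; the
  fitted curve is compressed at the extremes (upward bias ≈0.05–0.12 where
  π₀ is small). The spline design reduces but does not remove this bias.
- The t(10) statistic family realizes substantially lower power than the
  normal family at the same |mean| (heavy tails inflate the step-up
  threshold); see the tests for the measured values.
- Strong within-block correlation (ρ = 0.9, large blocks) degrades FDR
  control, more so for spline designs; this mirrors the effective-sample
  -size argument: accuracy scales with the number of (effectively
  independent) features, not with per-test sample sizes.
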