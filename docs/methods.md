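# Methods

This note records the statistical models implemented in `tenurematch`,
the choices made where the design was genuinely open, and what the
synthetic-data experiments do and do not demonstrate.

## Estimand and matching estimator

The unit of analysis is a 30 m forest pixel with a binary 2000–2014
forest-loss outcome Y. For a comparison (treated definition, control
definition, biome), the estimand is the average treatment effect on the
treated, ATT = E[Y(1) − Y(0) | treated], identified under selection on
observables: conditional on the biophysical and socio-economic
covariates (distances to water, urban areas, three road classes and
ports; temperature; precipitation; elevation; slope; year-2000 forest
cover; population density; woody biomass), treatment assignment is
assumed independent of potential outcomes. Matching is always within
forest biome (dry vs moist broadleaf), and a control may never come
from the treated pixel's own cadastral property — within-property
spillovers would otherwise contaminate the counterfactual.

The estimator is 1-nearest-neighbor matching with replacement
(`k` configurable) under one of two metrics:

- **Mahalanobis with propensity trimming** — distance
  √((u−v)ᵀS⁻¹(u−v)) with S the pooled covariance of treated plus
  control pool within the stratum;
- **propensity-score augmented** — the same, with the linearized score
  ℓ = log(p̂/(1−p̂)) appended as one extra standardized coordinate.

The propensity p̂ comes from an unregularized maximum-likelihood logit
of treatment on the covariates (linear in all of them; the true
specification is unknowable, and a linear index is the conventional
default). Separation is surfaced as an error rather than silently
penalized. Trimming removes treated units whose ℓ lies outside the
control [min, max], plus (default caliper 0.25 SD of ℓ) treated units
with no control score nearby. Controls are never trimmed. The exact
trimming rule is this package's choice; min–max support with a modest
caliper is the least surprising implementation of score-based trimming.

Between the two metrics, the pipeline keeps whichever yields the
smaller maximum absolute post-matching normalized difference
(mean absolute as tie-break, then declaration order). The normalized
difference is (mean_t − mean_c)/√((var_t + var_c)/2) with unbiased
(n−1) variances and reuse-count frequency weights on the matched
control moments; |nd| > 0.25 flags a covariate as imbalanced. A
comparison where every covariate remains flagged after matching, or
where the treated pool is tiny (default < 25), is reported NA rather
than estimated.

Distance ties break to the lowest control id, making reruns
deterministic. Near-singular pooled covariances are regularized by
adding 1e−8 × trace(S) to the diagonal.

### Bias adjustment

Post-matching, residual covariate gaps within pairs are absorbed by the
standard regression correction: a linear outcome model is fit on the
matched controls (frequency-weighted by reuse counts) and
μ̂(x_treated) − μ̂(x_control) is subtracted from each pair effect. Two
numerical guards apply: a rank-deficient design falls back to
minimum-norm least squares (with a warning), and when the number of
*distinct* matched controls is below the covariate count + 5 the
adjustment is skipped in favour of the raw effects — an outcome model
fit on a handful of support points extrapolates wildly at the treated
covariates, and a noisy "correction" is worse than none.

### Variance

Two modes, selected per comparison:

- **plain** — SE = sd(tt)/√n × √(ΣK_j²/ΣK_j), where K_j counts how
  often control j is reused; the inflation factor is 1 without reuse,
  recovering the classical matched-pair form.
- **heteroscedasticity-corrected** — unit-level conditional variances
  σ̂²_i = (Y_i − Y_nn(i))²/2 from each unit's nearest same-group
  neighbor in the whitened covariate space, combined as
  n⁻²[Σ_treated σ̂² + Σ_controls K² σ̂²].

Confidence intervals at 90/95/99% are normal-theory. The intervals for
the bias-adjusted ATT recenter on the adjusted pair effects.

## Partial linear model

Heterogeneity along woody biomass z is estimated on the matched pairs:
tt_i = α + x_i'β + f(z_i) + ε_i, with x the linear controls (all
covariates except biomass) taken from the treated pixel. Estimation is
the Robinson double-residual scheme with a Gaussian-kernel local-linear
smoother: tt and each column of x are smoothed on z
(leave-one-out in the residualization step, which removes the
own-observation attenuation of β); β is the OLS coefficient of the
residualized tt on the residualized x; f̂ is the local-linear smooth of
tt − xβ̂, centered to mean zero over the sample z (the identification
constraint, held to 1e−8); α is the mean of the remaining partial
residual. The default bandwidth is Silverman's rule on z — the right
order for a single smooth covariate and overridable where the curve is
sharper.

Pointwise 95% bands for f̂ come from a wild bootstrap: tt* = fitted +
v·ε̂ with two-point Mammen weights v, a full refit per replicate
(the smoother matrices depend only on z and are reused), and
*symmetric* percentile-t calibration, f̂ ± q₀.₉₅(|t*|)·ŝ(z), with
ŝ(z) the heteroscedasticity-robust SE of the linear smoother. The
symmetric form was chosen over the asymmetric percentile-t because it
contains the point estimate by construction; both are asymptotically
equivalent at interior points. The default replication is B = 50 —
adequate for a symmetric 95% quantile and cheap on matched samples of a
few thousand pairs — and tests use larger B. Bands are pointwise, not
simultaneous: reading "the interval excludes zero over this biomass
range" from the significance profile carries the usual multiplicity
caveat.

Pairs are unweighted by default; a reuse-weighted variant can be had by
expanding pairs before the fit.

## Impact accounting

Percent of forest cleared is 100 × deforested/forested area, rounded
half-away-from-zero to 2 decimals; the annualised rate divides by the
14-year window. A significant ATT converts to avoided deforestation as
|ATT| × n_mc × 0.09 ha × 100 — matched-control pixel count, 30 m pixel
area, and the reciprocal of the 1% sampling fraction — signed positive
when protection avoided loss and negative when leakage induced it; the
product with the matched-control mean biomass (tC/ha) gives avoided
carbon. An alternative "literal" mode additionally multiplies by the
matched-control deforestation rate; it is retained as an option but the
operative formula above is the one whose outputs are internally
consistent with the hectare bookkeeping of the rest of the pipeline.
Net effects sum signed avoided areas over the entries significant at
the 10% level.

## Synthetic landscapes

The generator emulates the statistical structure the analysis assumes:

- **Covariate fields** — white noise smoothed by a Gaussian kernel
  (σ = half the stated correlation range), rescaled to the configured
  mean/SD and clipped to physical ranges. Defaults are loosely
  calibrated to a Yucatán-like landscape (e.g. biomass 55 ± 25 tC/ha,
  clearing-relevant distances tens of km); they set plausible
  magnitudes, not a calibrated reproduction of any particular region.
- **Properties** — nearest-seed (Voronoi) tessellation of uniformly
  placed seeds; tenure assigned to whole properties with default
  shares 0.5/0.3/0.2 (ejido/private/parceled).
- **Protection** — assigned at property granularity, favouring remote,
  high-biomass properties (a noisy score on property-mean standardized
  remoteness and biomass), until the target coverage (default 10% of
  pixels) is reached. Each selected property draws a protected fraction
  from U(0.5, 1), grown as a contiguous core around a random anchor, so
  partially protected properties — the spillover treated group — always
  exist.
- **Outcomes** — a logistic baseline on standardized covariates
  (intercept ≈ logit(0.13), the order of a 14-year unprotected clearing
  rate; accessible, populated, low-biomass pixels clear more). The
  protection effect τ(z) acts additively on the clearing *probability*,
  p₁ = clip(p₀ + τ(z), ·, ·), so the ground-truth ATT equals τ wherever
  clipping is inactive; the default curve is a Gaussian dip of −0.08
  centered at 45 tC/ha (width 30), vanishing in high-biomass forest.
  Y and the stored counterfactual Y₀ share one uniform draw per pixel
  (common random numbers), making Y − Y₀ a low-variance oracle.
- **Leakage** — each protection-suppressed clearing (Y₀=1, Y=0 under
  protection) is displaced, with probability `leakage_rate`, onto a
  random still-forested unprotected pixel of the same property.

What the generator does **not** emulate: real geography (roads as
networks, towns as points), yearly loss dynamics, spatial correlation
of the outcome beyond what the covariates induce, property-size
heterogeneity by tenure, or any behavioural response beyond the
mechanical within-property displacement. Passing recovery tests
therefore shows the estimators are correct under selection on
observables with smooth confounding — not that the design identifies
effects under unobserved confounding in real cadastral data.

## Study-frame conventions

Forest in 2000 means tree cover strictly greater than the cutoff (10%
default; 25% as a sensitivity setting). Sampling retains each forested
pixel independently with the configured fraction (default 1%); the
draw is keyed to the pixel id where possible, so a stricter forest
definition yields a nested sample. Spatial thinning then removes
pixels within 30 m of a retained one (Chebyshev distance on the grid,
i.e. the 8-neighborhood), greedily in a seeded random order — the
ordering rule is this package's choice. Exclusion rules (urban, water,
mangrove, post-2000 protection, comunidades, named properties) apply in
declared order with full count reconciliation; pixels in unprotected
parts of protected properties are routed to a separate pool rather
than discarded, because they are the treated units of the spillover
analysis. Sampling precedes thinning; the reverse order would change
only the effective sampling rate.

## Problem sizes in the test-suite experiments

The recovery experiments run at sizes chosen to give Monte-Carlo
standard errors well below the effects being recovered: ATT recovery
uses 100 landscapes of 300×300 pixels with a 5% research sample (the
denser-than-1% sample tightens the per-replicate estimate without
changing the estimand); spillover recovery uses 20 landscapes of
250×250 at 8%; matching is verified against exhaustive search on
random instances up to n = 500; the PLM is checked on 3,000 pairs and
its bands on 60 replicates of n = 800 with B = 120. The acceptance
script uses the same designs at moderately reduced replication.

## Known limitations

- Unregularized logits can fail on small, highly separable comparison
  cells; such cells are reported NA rather than estimated.
- The bias-adjustment outcome model is linear; with strong nonlinear
  confounding it reduces but does not remove matching bias.
- The heteroscedastic variance uses a single same-group neighbor per
  unit (configurable), the coarsest consistent choice.
- Wild-bootstrap bands inherit local-linear smoothing bias: at
  curvature peaks, pointwise coverage dips a few points below nominal
  at the default bandwidth.
- GeoJSON property polygons are convex hulls of pixel footprints —
  adequate as an interchange artifact, not an exact tessellation
  boundary; TIFF rasters carry no CRS metadata (a local 30 m grid is
  implied).
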