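# Methods

## The prediction problem

The package estimates region-level prevalences (binary indicators) or
average ratings (real-valued responses) for nested administrative
geographies — neighborhood ⊂ district ⊂ municipality — from a survey of a
small fraction of the population plus registry features known for
everyone. The estimator is unit-level: a supervised model
f: ℝᵈ → [0,1] or ℝ is fitted on respondents, every non-respondent is
scored, and the combined response y* (observed value for respondents,
model mean otherwise) is averaged within each region. This keeps the
estimates self-consistent by construction: a parent region's estimate is
exactly the population-weighted mean of its children's, and the national
estimate is the mean of y*.

The key assumption is that the registry features and location carry the
systematic variation of the outcome, so that a model fitted on respondents
transfers to non-respondents. Under informative survey inclusion
(respondents differing from the population on a registry feature, e.g.
income), the estimator remains consistent as long as that feature is in
the model — the respondent-only (direct) estimator does not.

## Prediction intervals

Intervals reflect two sources of uncertainty:

* **model uncertainty** — respondents are resampled with replacement B
  times and the model refitted, giving f⁽¹⁾ … f⁽ᴮ⁾;
* **outcome uncertainty** — outcomes are independent given their means;
  per replicate, each non-respondent's outcome is simulated as
  Bernoulli(f⁽ᵇ⁾(xᵢ)) (binary) or Normal(f⁽ᵇ⁾(xᵢ), σ²) (ratings), with
  σ² = (1/|I|) Σᵢ (yᵢ − f̄(xᵢ))² computed once from the across-replicate
  mean prediction f̄ on respondents.

Respondents' observed outcomes are held fixed in every replicate (the
finite-sample correction), so the interval width shrinks to exactly zero
as the survey approaches a census. Bounds are empirical percentiles of the
replicate region means, with linear interpolation between order
statistics. The inferential target is the *realized finite-population*
region mean — the average of the actual outcomes of the region's
residents — which is what the finite-sample correction implies, and what
the coverage simulation measures against.

Choices where the procedure is under-determined: B defaults to 200
(percentile stability at the 95% level with tractable runtime; it is a
plain argument); resampling is uniform over respondents, without survey
weights; σ² is computed once from f̄ rather than per replicate; normal
outcome draws for bounded rating scales are not truncated, so a
pathological region mean may exceed the scale and is reported as computed
with a warning. Binary predictions from library adapters that overshoot
[0,1] are clamped and logged.

## Predictors

Any object with fit(X, y) / predict(X) → mean response plugs in. Shipped:

* **Null model** — the survey mean everywhere; the baseline.
* **Reference gradient boosted trees** (`saeboost.boosting`) —
  Friedman-style boosting written in this package: constant start at the
  loss argmin, CART fitted to the negative gradient each round, terminal
  node values from the loss's leaf rule (exact mean for squared error; a
  one-step Newton update Σ(y−p)/Σp(1−p) for logistic loss — the standard
  approximation of the printed argmin, chosen over exact line search for
  cost), update scaled by the learning rate α, no shrinkage on f₀.
  Missing values are a splitting criterion: every candidate split is
  scored with the missing block routed left and right and the node keeps
  the winning default direction, so no imputation is needed. Continuous
  splits consider midpoints of consecutive sorted unique values;
  categorical features enter as level codes with one-vs-rest subsets (full
  subset search rejected for cost). Gain ties break toward the lowest
  feature index, then the lowest threshold, then routing missing left.
  Defaults α=0.3, T=50 (they work well); the optimized variant uses α=0.1
  with early stopping by five-fold cross-validation on the training data —
  folds are a seeded uniform shuffle, growth stops after 10 rounds without
  improvement of the mean held-out loss (patience and the 500-round cap
  are package choices; the stopping criterion is the training loss
  family's own value), and the final model is refitted on all respondents
  at the selected round count. max_depth=6 and min_leaf_size=20 mirror
  common booster defaults; a row with every feature missing is scored at
  the linked constant f₀. Models serialize to JSON and round-trip
  bit-exactly.
* **xgboost adapter** — the same contract over the production library;
  regularization details differ from the reference implementation, so the
  two agree approximately (a 10% held-out-MSE band is asserted in tests),
  not exactly.

## Spatial features

Location enters as raw coordinates (`xy`) or as oblique geographic
coordinates (`ogc`): the K projections x·cosθₖ + y·sinθₖ with
θₖ = π(k−1)/K equally spaced over [0, π), K=24 by default. The
implementation evaluates the polar form √(x²+y²)·cos(θₖ − atan2(y, x)),
which is algebraically identical but quadrant-safe: the single-argument
arctangent form is undefined at x = 0, while registry coordinates are
strictly positive, so the two coincide in range. The origin maps to the
all-zero projection (the limit of the form) and is logged. By default the
oblique features replace the raw coordinates rather than augmenting them.

## Sequential imputation

For predictors that cannot accept missing values, features are imputed in
ascending order of missing fraction (ties by column position): for each
incomplete feature, a 100-tree random forest (scikit-learn) is fitted on
the currently complete columns — originally complete features, the
coordinates, and features imputed earlier — over the rows where the target
feature is observed, and predicts the missing entries (classification for
categorical targets, regression for continuous). One sequential sweep, no
iteration to convergence; observed entries are never altered, so the
operation is idempotent. Coordinates are never imputed (they are complete
by construction) and never treated as categorical. A feature that is 100%
missing is an error — there is nothing to learn from.

## Synthetic populations

Real registry microdata are restricted, so the generator emulates their
structure with exact ground truth attached:

* **Geography** — municipalities × districts × neighborhoods (default
  5 × 2 × 10 = 100 neighborhoods over a 100 km square). Neighborhoods
  occupy cells of a near-square grid in row-major order, so the regions of
  one parent are spatially contiguous; individuals draw uniform
  coordinates inside their neighborhood's tile, guaranteeing the
  location–region correlation the spatial features rely on. Every
  neighborhood is inhabited; sizes vary via Dirichlet-multinomial weights
  (concentration 3), giving the small-respondent-count regions that small
  area estimation exists for.
* **Features** — a reduced-cardinality mirror of a person registry: age,
  sex, 7-level ethnicity, marital status, 8-level education, household
  type/size/income source/ownership, income and asset percentiles, and a
  neighborhood-level address density. Missingness is masked in per feature
  at registry-like rates (education 37.8%, household economics ~2%),
  missing completely at random by default; the truth is computed on the
  complete latent values before masking.
* **Outcome surface** — a known linear predictor with curvature (quadratic
  age), categorical offsets, a sex-by-income interaction and a smooth
  spatial sinusoid (amplitude 0.6 on the logit scale, 60 km wavelength),
  through a logistic link (prevalence ≈ 0.30 at the defaults) or identity
  link with Gaussian noise for ratings.
* **Survey** — Bernoulli inclusion at a configurable fraction; optional
  monotone inclusion bias through a logit shift proportional to a named
  standardized feature. The stratified designs of real surveys are not
  replicated (their strata are unpublished); per-municipality fractions
  can approximate them.

What passing tests on these populations do **not** show: robustness to
informative missingness, household clustering, real geography's irregular
region shapes, or survey weighting — none of which the generator emulates.

## Reference study conditions and problem sizes

The simulation studies (`saeboost.experiments`) use a 20,000-person
population in 100 neighborhoods with a 10% simple random survey (~2,000
respondents; ~20 per neighborhood) — deliberately small-area conditions.
The study classifier is the boosted-tree adapter at 30 rounds, depth 3,
on oblique coordinates (the package's reference spatial representation);
coverage is measured over 10 simulation replicates × 100 neighborhoods
with B=200. At this scale the model's neighborhood-level estimation error
is a non-trivial fraction of the interval width, so measured coverage sits
slightly below nominal (92–95% across seeds against the 95% target) —
the residual shortfall comes from regularization bias shared across
bootstrap refits, which percentile intervals cannot see. The
bias-correction study uses 20 replicates of a 10,000-person population
with inclusion bias strength 1.0 on the income percentile.

## Numerical details

* Metrics: MSE (the Brier score for binary outcomes) and NLL are
  normalized by sample size; NLL clips predictions 10⁻¹² from the
  boundary; accuracy thresholds at 0.5; AUC is the exact pairwise
  count (ties ½) via the Mann–Whitney rank statistic, while the
  100-threshold ROC curve is for visualization. Calibration uses
  equal-count quantile bins of the predictions with tie groups kept
  together (a constant prediction collapses to one bin).
* Cross-validation folds are a seeded uniform shuffle (sizes differ by at
  most one), not stratified.
* Region-estimate comparisons bin absolute differences at 2.5-point edges
  [0, 0.025), …, [0.1, 0.125), report Pearson correlation, and can
  stratify out-of-sample squared error by region-size quantile.
* One global seed is split into named substreams (simulation, survey,
  model, cv, bootstrap, imputation) by hashing, so stages are reproducible
  independently; all derived seeds are below 2³¹. Estimates files are
  written at 6 significant digits, sorted by level then region code, for
  byte-stable diffs.

## Known limitations

Design-based variance estimation, post-stratification weighting and
multiple imputation with uncertainty propagation are out of scope. The
percentile intervals inherit the bootstrap's blind spot for refit-invariant
model bias; with very small training surveys or misspecified predictors
they undercover. Rating-scale simulation assumes homoscedastic Gaussian
outcome noise.
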