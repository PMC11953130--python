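# Methods

## Model

`penfactreg` fits a factorial regression with genotype-specific linear
reaction norms to genotype-by-environment (G×E) trial means:

    Y[i,j] = mu + g_i + e_j + sum_t v[i,j,t] * beta[i,t] + eps[i,j],
    eps[i,j] ~ N(0, sigma^2) i.i.d.

`Y[i,j]` is the trait mean of genotype `i` in environment `j`; `g_i` and
`e_j` are genotype and environment main effects; `v[i,j,t]` is the value of
environmental covariate (EC) `t`, either constant within an environment or
genotype-specific (e.g. a temperature summed over a genotype's own flowering
window); and `beta[i,t]` is genotype `i`'s sensitivity (slope) on EC `t`.
Identifiability uses treatment coding: `g_1 = e_1 = 0`, with the first
genotype and first environment in first-appearance order as references.

The model has `n_g + n_e - 1 + n_g*n_c` parameters — `n_c + 1` per genotype —
so with more than a handful of ECs it is near or beyond the number of
observations and must be penalized.  Only the sensitivities are shrunk:

    (1/(2N)) * RSS + lambda * sum_k pf_k * (alpha*|theta_k| + (1-alpha)/2 * theta_k^2)

with penalty factor `pf_k = 0` for the intercept and main effects and
`pf_k = 1` (or a positive per-genotype weight) for sensitivity columns.
Environment main effects are typically much larger than the G×E signal;
penalizing them equally would over-shrink the main effects and under-shrink
the interactions.  `alpha = 0` is ridge, `alpha = 1` the lasso, and the
elastic-net default is `alpha = 0.5` (equal weight on both parts).

Prediction for a *new* environment (the GoEn scenario: observed genotypes,
new environments) transfers `mu + g_i` and the slopes to the new
environment's EC values; the environment main effect is unknowable and
omitted, so predictions are *environment-centred*.  Accuracy is therefore
measured within environment: the Pearson correlation `r_j` between predicted
and observed values in each environment, and their unweighted average over
environments, APCOR_Env.

## Identifiability with environment-level ECs

When every genotype shares the same EC value within an environment, the
genotype-summed sensitivity columns are constant within environment and lie
in the span of the environment main effects: the unpenalized (`lambda = 0`)
design is structurally rank deficient.  Any positive penalty resolves this.
The unpenalized "Full" model is only well-posed with genotype-specific ECs,
which is also the natural data-generating regime for phenology-adapted
covariates; the simulator therefore defaults to genotype-specific ECs.

## Solvers

* `lambda = 0`: dense least squares with an explicit rank check.
* Ridge (`alpha = 0`): exact closed form.  The unpenalized columns are
  profiled out by orthogonal projection and the penalized block solved via a
  single eigendecomposition of its Gram matrix, after which every lambda on
  the grid costs only matrix–vector work.  Penalty-factor weights are folded
  in by column scaling.
* `alpha > 0`: a monotone hybrid in covariance (Gram) space.  Each outer
  iteration does an exact least-squares update of the unpenalized block, one
  coordinate-descent sweep over the penalized coordinates (numba-compiled;
  this discovers active-set and sign changes), and a Newton step that solves
  the stationarity system restricted to the current support exactly,
  accepted only when it lowers the objective.  The sensitivity Gram is
  exactly block-diagonal by genotype (sensitivity columns of different
  genotypes share no rows), so the Newton step reduces to one batched
  genotype-block solve plus a Schur complement on the unpenalized columns —
  a few milliseconds even with ~1000 penalized columns.

  The hybrid matters because genotype-specific ECs are env-level ECs plus
  small genotype deviations, leaving near-collinear directions whose
  conditioning makes plain coordinate descent converge impractically slowly
  near `lambda -> 0`.  Solutions satisfy the KKT conditions to ~1e-8
  (checked in tests against a 1e-5 contract).  A fully sparse
  coordinate-descent kernel (tolerance 1e-7 on the maximum relative
  coefficient change, at most 1e5 sweeps) remains as the fallback for
  problems too large for a dense Gram.

## Lambda grid and cross-validation

`lambda_max` is computed after profiling out the unpenalized columns:
`max_k |x_k' r0| / (N * alpha * pf_k)` with `r0` the residuals of the
main-effects-only fit — the smallest lambda at which all sensitivities are
zero and the fit equals the additive model.  The auto grid is 100 log-spaced
values from `lambda_max` down to `lambda_max * 1e-4`; ridge, having no finite
`lambda_max`, anchors its grid at the lasso-equivalent value times `1e3`.

Lambda is selected by k-fold cross-validation (default k = 10), minimizing
mean held-out squared error (`lambda_cv.min`; a one-standard-error rule is
available as an option).  Two fold layouts:

* **random** — partitions the G×E observations, ignoring environments;
* **stratified** — partitions whole environments, mimicking prediction for
  unseen environments.  Held-out environments have no estimable main effect:
  their `e_j` coefficients are set to zero in the held-out predictions and
  the squared error is computed after centring residuals within each
  held-out environment.  Without this centring the irreducible environment
  mean dominates the CV curve and carries no information about lambda.

ECs are centred/scaled to sample mean 0 and sd 1 (ddof = 1) using training
records only; test ECs use the stored training statistics.  This makes one
lambda comparable across ECs of different units and can be switched off.
CV folds reuse the full-training-set standardization rather than
re-standardizing per fold; the difference is second-order for the fold sizes
involved and keeps the fold problems on a common grid.  Fitted sensitivities
are reported back on the original EC scale (with the centring absorbed into
`mu` and `g`), so prediction uses raw EC values.

Genotype-specific penalty weights are supported (`genotype_weights` in
`build_design` / `fit_gne`) but off by default: with few training
observations per genotype, per-genotype tuning tends to hurt.

`sigma2_hat` is RSS divided by N minus the number of nonzero coefficients
(floored at 1) — a plug-in estimate, not an unbiased one under selection.

## Baselines and the two-stage marker extension

The additive model `Y = mu + g_i + e_j + eps` is the large-lambda limit of
the penalized fit and the reference point for judging whether the ECs add
predictive value.  The "Full" model is the factorial regression at
`lambda = 0`.

For new genotypes (GnEn) the stage-1 genotype intercepts and slopes are
regressed on centred marker dosages with independent univariate ridge per
response (1 + n_c responses), shrinkage selected per response by
leave-one-out generalized cross-validation (`sklearn.linear_model.RidgeCV`).
Predicted intercepts/slopes for unseen genotypes then feed the same
environment-centred prediction arithmetic.  Genotype-specific ECs are
rejected here: phenology-adapted covariates do not exist for unobserved
genotypes.  Univariate ridge was chosen over a multivariate BLUP for speed
and simplicity; with noiseless marker-determined slopes its held-out
accuracy behaves like sqrt(n / (n + M)) for M markers, so slope prediction
is only strong when training genotypes outnumber effective marker segments.

## Simulator

`simulate.simulate_met` generates balanced multi-environment trials as a
test bed:

* Environments belong to discrete envirotypes (default 4, equal
  frequencies), assigned by largest-remainder proportional allocation in
  both the training and test blocks so every test scenario is represented in
  training — the regime where transferring reaction norms can work at all.
* ECs are Gaussian around envirotype-specific means (mean spread sd 1.0,
  within-envirotype sd 0.5, independent ECs by default; an EC correlation
  matrix can be supplied).  Genotype-specific mode adds Gaussian jitter
  (sd 0.1) per genotype cell, a proxy for phenology-driven covariate
  differences.
* True sensitivities: `n_active` of the `n_c` ECs get slopes drawn
  independently per genotype, N(0, 0.5^2); the rest are exactly zero.  An
  optional marker-determined mode builds g and B from a sparse set of causal
  marker effects for two-stage tests.
* Scales: environment main effects sd 2.0, genotype main effects sd 1.0,
  overall mean 10 — environment effects dominating the G×E signal, as in
  typical yield trials.
* Noise is calibrated per environment: `sigma2_j = Var_i(genetic_j) * (1-h2)/h2`
  so the expected within-environment heritability equals the target
  (default h2 = 0.5, a medium-heritability trait).

Reference conditions used by the behavioural tests and the acceptance
script: 50 genotypes, 60 training and 20 test environments, 20 ECs with 3
active, h2 = 0.5 — large enough for the overfitting-vs-regularization
contrast to be stable, small enough that a replicate fits in seconds.  The
stratified CV in those runs uses k = 5 over the 60 training environments;
the acceptance script averages over 5 replicate METs.

What the simulator does **not** emulate: spatial/plot-level error structure
(inputs are G×E means), EC measurement error, linkage disequilibrium between
markers, envirotype-specific error variances beyond the heritability
calibration, and non-linear reaction norms.  Passing tests therefore show
the machinery is correct and the method behaves as designed under its own
assumptions — not that a particular accuracy level will be reached on any
real trial series.

## Numerical choices and degenerate inputs

* Tie-breaks in CV: with equal CV error the largest lambda wins; a flat CV
  curve returns the largest lambda with a warning.
* Environments with fewer than 3 observations or zero variance in either
  vector get an undefined (`None`) correlation and are excluded from
  APCOR_Env, with the exclusion count reported; APCOR_Env is unweighted by
  default (a size-weighted variant is an option).
* Single-genotype or single-environment designs, zero-sd ECs under
  standardization, unknown genotypes at prediction time, and genotype-
  specific ECs in GnEn prediction all raise typed errors rather than
  degrading silently.
* Missing marker dosages are imputed to the column mean before stage 2.
* All randomness (simulator, CV folds) flows through explicit integer seeds;
  there is no global RNG state, and repeated runs are bit-identical.

## Known limitations

* The CV objective (squared error) is not APCOR_Env itself; the
  near-optimality of `lambda_cv.min` for correlation-based accuracy is an
  empirical property (verified on simulations), not a guarantee.
* Extrapolation beyond the training envirotypes is unsupported in spirit:
  nothing prevents it numerically, but accuracy claims do not transfer.
* The dense-Gram solver path assumes `n_g * n_c` columns fit in memory
  (~2e8 entries); beyond that the sparse fallback is slow at small lambda.
* No group-lasso coupling of an EC across genotypes, no non-linear EC
  transforms, and no plot-level data handling.
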