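# Methods

## Observation model and latent structure

For areas `i = 1..I` and consecutive years `t = 1..T`, counts are
`Y_it | mu_it ~ Poisson(N_it * mu_it)` with population `N_it` as the
offset. Cells with `N_it = 0` are structurally excluded from the
likelihood (they carry no information and may not contain events).
Three decompositions of `log mu_it` are implemented:

1. `alpha_i + S(t) + eta_t`: exchangeable area intercepts
   `alpha_i = alpha + a_i`, `a_i ~ N(0, 1/tau_a)`, a marginal trend
   `S(t)` (linear by default for this variant), and a stationary AR(1)
   year effect `eta_t` with its own precision `tau_e` and lag-one
   correlation `rho_T`.
2. `alpha + S(t) + omega_it`, `omega ~ GMRF(tau * Q_AR(1) (x) I)`.
3. `alpha + S(t) + omega_it`, `omega ~ GMRF(tau * Q_AR(1) (x) Q_CAR)`.

Variants 2–3 default to `S(t) = none`: their interaction field absorbs
temporal structure, so a separate marginal trend is redundant (and, for
the intrinsic CAR with per-year sum-to-zero constraints, the overall
level is carried by `alpha` while all time variation in aggregates
comes from the population-weighted, nonlinearly transformed field).
Covariates and the urban/rural indicator enter as extra columns of the
fixed-effect design in any variant, on the standardized (z-score)
scale; the transform is recorded so future-year covariates can reuse it.

### Conventions that matter

* **AR(1) scaling.** `Q_AR` is the precision of the *unit-marginal-
  variance* stationary AR(1) (inverse of the correlation matrix
  `rho^|i-j|`). This keeps `tau` as the single scale parameter of an
  interaction field and prevents `rho_T` from leaking into its
  variance.
* **Vectorization.** Space-time vectors stack areas fastest, years
  slowest (`cell = t*I + i`), so the interaction precision is exactly
  `Q_T (x) Q_S`. All modules honour this order.
* **Intrinsic CAR.** `Q_S = D - W` (Besag), rank-deficient by one per
  connected component; identifiability is restored by sum-to-zero
  constraints over the areas of each component at each year, enforced
  exactly by conditioning by kriging. Areas with no neighbours
  ("islands") instead receive a unit diagonal entry — a proper standard-
  normal block — and are dropped from the constraint set; this is a
  common disease-mapping convention for maps with offshore units. A
  proper-CAR variant `Q_S = D - rho_S * W` is available behind a flag.
* **Generalized densities.** Log-densities of intrinsic fields use the
  product of nonzero eigenvalues; for the Kronecker interaction this is
  assembled from the factor spectra (eigenvalues multiply), never from
  the full matrix.

### Priors (all overridable)

Gamma(shape = 1, rate = 5e-5) on every precision; Normal(0, sd = 31.6)
on the intercept, trend, and regression coefficients; Normal(0,
sd = 2.6) on the Fisher-z transform of `rho_T` (and on the logit of
`rho_S`). These mirror the vague defaults of widely used latent-
Gaussian-model software; the data dominate them at the panel sizes
targeted here.

## Posterior computation

A Metropolis-within-Gibbs sampler with two move types.

**Latent Gaussian block.** The intercept, regression/trend
coefficients, and the random field are one joint block `u` with sparse
prior precision `Q_u(theta)` and design map `A` onto cells. The
proposal is a preconditioned Langevin (MALA) step
`u* = u + (eps^2/2) P^{-1} grad log pi(u) + eps * P^{-1/2} z` with
preconditioner `P = Q_u(theta) + A' diag(c_hat) A`, where
`c_hat = Y + 1/2` is a data-based surrogate for the Poisson curvature
`N exp(eta)` evaluated near the cellwise maximum-likelihood point.
Because `P` depends on the hyperparameters but never on `u`, it is a
valid fixed preconditioner for the conditional update and is
refactorized only periodically (every 20 sweeps) with a sparse
Cholesky; the Metropolis–Hastings correction uses the exact current
`Q_u`, so the kernel targets the posterior exactly regardless of how
stale `P` is. Proposal noise with covariance exactly `P` is drawn by
perturbation (a prior draw plus `A'(sqrt(c_hat) * z)`), avoiding
triangular solves. Sum-to-zero constraints are imposed on every
proposal by kriging, with the matching conditional-density correction
in the acceptance ratio. If a factorization fails numerically (extreme
transient hyperparameters), the diagonal is jittered — with a matching
extra noise term so proposal density and sampler agree — or the
previous preconditioner is kept.

The sparse Cholesky itself is SuperLU in symmetric mode (no numerical
pivoting, symmetric permutation), which yields an exact `L D L'`
factorization for SPD matrices; it is validated against dense
Cholesky/eigendecompositions in the test suite.

**Hyperparameters.** Each log-precision moves by an adaptive random
walk that *jointly rescales its field* (`omega -> omega *
sqrt(tau/tau*)`), i.e. a walk on the standardized field's scale; this
removes the strong posterior coupling between a field and its
precision. The transformed correlations (`z = atanh(rho_T)`, logit
`rho_S`) move by plain adaptive random walks whose acceptance ratio
needs only the factor spectra (AR(1) determinant in closed form, CAR
spectrum precomputed once). Step sizes adapt by Robbins–Monro toward
0.574 (latent) and 0.44 (scalars) during burn-in only.

**Initialization and schedule.** `alpha` starts at the log of the
pooled observed rate (with a +0.5 continuity correction), fields at
zero, precisions at 1, correlations at 0. Hyperparameter moves start
only after a short latent-only warmup (50 sweeps or half the burn-in):
with the fields still at zero, the correlation conditionals are
monotone toward `|rho| = 1` (log-determinant grows while the quadratic
form is zero), and the warmup removes that start-up artifact. The
correlation is also clipped away from `+-1` by 1e-9 for numerical
safety. Default schedule is 60,000 iterations, 10,000 burn-in,
thinning 10; the analysis scripts and validation experiments use
3,000/1,000/4 (study-scale panels, ~100 areas x 15 years) and
1,200/400/4 (ranking-scale panels, 36 areas x 10 years), at which the
latent block accepts at ~0.55–0.65 and scalar moves at ~0.4.

## Forecasting

Future years are treated as missing. Per retained draw: the AR(1)
recursion extends the temporal process (`omega_{t+1} = rho * omega_t +
e`, `e ~ N(0, ((1-rho^2)/tau) * Q_S^+)` sampled in the spatial
eigenbasis, restricted to the constraint subspace for the intrinsic
CAR), covariates and populations carry forward from the last observed
year unless supplied, and `Y ~ Poisson(N * exp(eta))`. Summaries are
medians and 90% equal-tail intervals; displayed counts are rounded to
integers; rates are reported per 100,000 for display. State-level
totals are summarized from *summed draws* — quantiles are not additive,
so summing per-area medians would be wrong, and a test enforces the
draw-level route.

## Evaluation protocol

Strict rolling origin: for each test year, the model is re-fitted on
all earlier years and the held-out year is scored. Point predictions
are posterior(-predictive) medians. Metrics: RMSE, MAE, the signed mean
error (reported alongside MAE because the two answer different
questions and are easily conflated), and the rank difference — areas
are assigned to quintiles of predicted and of observed values
independently (average ranks, right-closed quantile cuts, so ties —
ubiquitous among rural zeros — share a group), and the statistic is the
fraction of areas whose groups agree. With 10 distinct values and their
reversal, the two central ranks share the middle quintile, so the
statistic is 0.2, not 0; with fewer than 5 areas in a stratum it is
reported as NaN. Rank difference is invariant to strictly monotone
transforms of both vectors.

## Synthetic study generator

The generator reproduces the statistical structure the models assume a
real state-wide panel has: a contiguous urban block covering 73% of
areas (grown by BFS from a random seed area); log-normal populations
with urban log-mean 9.6 (~15k adults) vs rural 7.2 (~1.3k), giving
urban areas the vast majority of person-years and events; a baseline
rate of 30 per 100,000; proportion covariates from spatially smoothed
logistic-transformed Gaussian fields, constant within 5-year windows
(ACS-style); and latent fields drawn from the chosen model's own prior
at fixed hyperparameters (`tau = 4`, `rho_T = 0.7`,
`beta = (0.3, -0.2, 0.1)` in the standard scenario) so that recovery
experiments have exact ground truth. The standard scenario's truth uses
no deterministic trend: the recovery experiment fits exactly the
generating model, and a trend absent from the fitted model would
confound the hyperparameter coverage being measured. A `trend_slope`
knob exists for generic scenarios.

What the generator does *not* emulate: real geographic irregularity
(it uses lattice maps by default, though any polygon map or edge list
works), covariate-outcome confounding structures beyond log-linear
effects, reporting lags, and abrupt shocks to the trend (e.g. a
pandemic year). Passing tests therefore demonstrate correctness of the
machinery and calibration *under the model's own assumptions*, not
robustness to structural breaks — a real deployment should expect
under-coverage in years whose dynamics break with the training period.

## Validation experiments and problem sizes

* GMRF algebra: >= 20 random instances per run (dimension <= 25, plus
  small Kronecker interactions) against dense eigendecomposition
  oracles at 1e-8; constraint satisfaction at 1e-10; 20,000-draw moment
  checks against dense covariances.
* Conjugate check: one area, one year, `Y=20, N=100`; with the default
  near-flat priors the rate posterior is Gamma(20, 100) to excellent
  approximation, and the MCMC mean must agree within 3 Monte-Carlo
  standard errors (ESS-based).
* Recovery: 25 replicates of the standard scenario, 3,000 iterations
  each; 90% intervals must cover each generating hyperparameter in
  75–100% of replicates (binomial tolerance at 25 replicates), with
  mean absolute bias of the AR(1) coefficient below 0.15.
* Ranking: 20 replicates on 36-area, 10-year panels generated from the
  CAR-interaction model with real covariate effects; the spatial model
  must beat the temporal-only model on one-year-ahead count RMSE in
  >= 70% of replicates, and covariates must improve the temporal-only
  model in >= 60%.
* Forecast intervals must widen from horizon 1 to horizon 2 in every
  seed tested, and zero-count areas must receive strictly positive
  predicted rates (smoothing positivity).

These sizes were chosen so each experiment is statistically meaningful
while the whole suite remains routinely runnable on a laptop core.

## Known limitations

* Single-chain MCMC with split-chain diagnostics; for publication-grade
  inference run several seeds and compare.
* The proper-CAR spectrum is recomputed densely per `rho_S` proposal —
  fine to a few hundred areas, slow beyond.
* Covariate standardization uses the full panel's moments (also inside
  the rolling-origin loop); with slowly varying ACS-style covariates
  the leakage is negligible, but a strictly prospective deployment
  should re-standardize per training window.
* No negative-binomial/zero-inflated observation models, no spatially
  varying coefficients, no ensembling across models.
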