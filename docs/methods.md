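# Methods

## Problem setting

The package estimates individualized treatment effects (ITE) from
longitudinal observational data in which the covariates recorded at each
encounter are *proxies* of hidden confounders rather than the confounders
themselves.  Units are patients; at steps t = 1..T we observe time-varying
covariates x_t ∈ R^p, a binary treatment indicator a_t, per-step outcome
targets y_t, static covariates c, and the elapsed time Δt since the previous
encounter.  The estimand is the contrast between the potential outcomes at
the horizon under a sustained-treatment regime versus no treatment,
conditional on the observed history.  The usual sequential-ignorability
assumption is deliberately *not* made: instead, a latent substitute for the
hidden confounders is learned from the proxy sequence.

## Model

The deconfounder is a variational recurrent autoencoder with treatment and
outcome heads, trained jointly:

1. **Sequence encoder.**  Tokens u_t = [x_t, c, embed(Δt_t)] pass through a
   causally masked multi-head self-attention encoder (pre-norm, 2 layers, 4
   heads by default).  Layer outputs o_t are folded into a time-decayed
   residual recursion h_t = o_t + H(Δt_t)·h_{t−1} with h_0 = 0, so that long
   gaps between encounters shrink the carried-over state.  The default decay
   is H(Δt) = 1/log(e + Δt) (H(0) = 1, monotone); an exponential
   alternative exp(−λΔt) is available.  Causal masking is enforced so no
   state at t depends on inputs after t (verified by perturbation and
   gradient tests).
2. **Variational head.**  A feed-forward map φ_enc([h_{t−1}, h_t]) produces
   a diagonal-Gaussian posterior over the latent z_t (16 dims by default); a
   *separate* network produces a state-dependent prior from [h_t, h_{t−1}]
   (a `previous_state_only` option conditions the prior on h_{t−1} alone,
   removing the current step's information from the prior).  Sampling is
   reparameterized; log-variances are tanh-bounded to [−10, 10] for
   numerical safety.
3. **Decoder.**  z_t (with h_{t−1}) maps to diagonal-Gaussian reconstruction
   parameters over x_t.
4. **ITE block.**  A propensity head a′_t = σ(f_a(z_t)) and an outcome head
   y′_t = f_y([z_t, a_t]).  Evaluating the outcome head at a = 1 and a = 0
   on the same latent path gives the two potential-outcome predictions;
   their difference at the horizon step is the ITE estimate.

### Objective

The joint loss is L = L_s − α·L_ELBO + w_a·L_prop with α = 1 and w_a = 1 by
default:

* **L_s** — IPTW-weighted outcome loss.  Weights follow the convex form
  w′_t = Pr(A)·a′_t + (1 − Pr(A))·(1 − a′_t), where Pr(A) is the empirical
  treated-unit fraction of the training split (Laplace-smoothed so it stays
  inside (0, 1)); weights are bounded between Pr(A) and 1 − Pr(A) by
  construction.  A conventional stabilized form (Pr(A)·a/a′ + (1 −
  Pr(A))·(1 − a)/(1 − a′), clipped at 10) is available behind
  `iptw_kind="stabilized"`.  The default residual is squared,
  E[w′(y′ − y)²]; the literal signed form E[w′(y′ − y)] exists behind
  `supervised_form="as_printed"` but is unbounded below and unusable as a
  training loss.  The weights are recomputed from the current propensities
  every batch but treated as constants in the gradient (standard practice
  for weighted objectives — otherwise the outcome loss would push the
  propensity head toward whichever arm shrinks its weight); the propensity
  head is trained by the cross-entropy term below.
* **L_ELBO** — timestep-wise evidence lower bound: masked sum over steps of
  the Gaussian reconstruction log-likelihood minus the closed-form KL
  between posterior and prior, averaged over units, with a single latent
  sample per position.  Inside the training loop the ELBO is additionally
  normalized per observed step and per proxy dimension.  Without this
  normalization the ELBO scales with p·T (≈10³ for the default benchmark)
  and its gradient swamps the supervised loss in the shared encoder — in
  our experiments the outcome head then never learns (validation RMSE stays
  at the outcome standard deviation).  With the normalization, α = 1 trades
  off quantities of comparable magnitude.  The `elbo()` function itself
  keeps the plain summed form used by the oracle-loop tests.
* **L_prop** — binary cross-entropy between a′_t and a_t.  The propensity
  head needs its own supervision for the IPTW weights to be meaningful, so
  this term is on by default (weight 1.0; weight 0 recovers the bare
  two-term objective).

Optimization is Adam (lr 1e−3, batch 64) with early stopping on validation
factual RMSE (patience 10, at most 200 epochs by default).  Inference uses
posterior means (no sampling), making predictions deterministic.

Because no deep-learning framework is a dependency, the package carries a
small numpy reverse-mode autodiff core (`vtdeconf.autodiff`, `vtdeconf.nn`)
implementing exactly the operations the model needs; all gradients are
verified against central finite differences in the test suite.

### Input standardization

Proxy covariates, statics and outcomes are standardized with training-split
statistics inside `VTDRegressor` and predictions are mapped back.  This
matters for the synthetic benchmark, whose covariates are O(0.01) while
outcomes are O(1); reported metrics are always on the original scale.

## Synthetic benchmark and counterfactual oracle

Proxies and hidden confounders evolve through coupled autoregressions (see
the `vtdeconf.simulate` docstring for the equations): lag weights α_{r,j},
μ_{r,j} ~ N(1 − r/p, (1/p)²), treatment weights β_r, v_r ~ N(0, 0.02²),
scalar noises η_t, ε_t ~ N(0, 0.01²) drawn per unit and step, lags running
to r = p with out-of-range history contributing zero.  The confounder
summary q_t = γ·mean(z_{1..t}) + (1 − γ)·g([x_t, c]) mixes the hidden
process with a fixed linear feature map of the observables, and outcomes
are y_t = wᵀq_t + b with w ~ U(−1, 1), b ~ N(0, 0.1).  The default design
is 1,000 treated + 3,000 control units, p = 100 proxies, T = 10 steps,
γ = 0.1.  Treated units switch on at a uniformly random step and stay on;
control units are never treated.

Choices the generator's description left open, fixed once here:

* Noise subscripts carry only a time index, so η_t and ε_t are drawn as one
  scalar per (unit, step), shared across the p columns.  Consequently all
  columns coincide at t = 1 (there is no history yet).
* The hidden dimension r defaults to p; statics are c ~ N(0, 1) with d = 5.
* g is a fixed seeded linear map with entries N(0, 1/(p + d)) — the
  random-feature normalization keeps each component of g([x, c]) at O(1)
  and the outcome standard deviation near 1.  No nonlinearity, which keeps
  every outcome analytically replayable.
* The outcome horizon offset τ defaults to 0 (outcome read at the final
  observed step); τ > 0 simply runs the autoregression τ extra steps.
* Per-step targets y_t use the same linear map at every step, so the
  per-timestep outcome head has supervision; headline metrics always use
  the horizon outcome.
* Elapsed times are all 1; a `thin_prob` option drops interior steps at
  random to exercise irregular Δt.

All noise draws are cached.  Counterfactual outcomes replay the generator
with the cached noise under an alternative treatment row (common random
numbers), which defines the unit-level ground-truth ITE as the
always-treated minus never-treated contrast.  Because the generator is
linear and treatment enters additively with shared weights, this true ITE
is *identical across units* — PEHE against the oracle therefore measures
the error around a homogeneous effect.  A second consequence, verified
analytically and empirically: the outcome is a nearly deterministic linear
function of the *observed* quantities (x_T, c, treatment history), with the
unexplained part limited to the γ-weighted noise accumulation of the hidden
process (standard deviation of order 10⁻²).  Correctly specified linear
regression therefore attains near-zero test RMSE on this benchmark, and
assignment — being randomized — is not actually confounded by q_t.  Passing
tests on this generator show that the pipeline recovers the signal it
contains; they do not demonstrate deconfounding under assignment
confounding, which the generator as defined does not produce.

## Baselines

* **G-formula** (`GFormula`): ridge regression (penalty 1e−6, effectively
  OLS with a fallback for singular designs) of the horizon outcome on the
  flattened covariate history, statics and treatment history, truncated to
  `history_window` steps (full history by default); ITE by standardization
  — predict under all-ones and all-zeros treatment history and difference.
  Without treatment–covariate interactions the implied effect is the same
  for every unit; `interactions=True` adds horizon-treatment × covariate
  products.
* **No-latent ablation** (`VTDRegressor(use_latent=False)`): identical
  encoder and heads, but the heads read a deterministic projection of h_t
  and the variational terms are dropped — the "deep but latent-free"
  comparator.

## Evaluation

* **RMSE** of factual horizon-outcome predictions.
* **PEHE**: mean squared difference between true and predicted ITE, no
  square root by default (`root=True` for the rooted convention).
* **IF-PEHE** for data without counterfactuals: cross-fitted two-arm
  outcome regressions (ridge by default, gradient boosting optional) give a
  plug-in effect; a first-order influence-function correction reweights the
  factual residual by (a − e)/(e(1 − e)) with propensities from a logistic
  model clipped to [0.01, 0.99].  Cross-fitting folds are assigned by a
  content hash of each unit's row, making the estimate exactly invariant to
  unit ordering.  The estimator is validated against the synthetic oracle
  (concentration near true PEHE with oracle nuisances, near-zero under a
  null effect, positive rank correlation across perturbed predictors); like
  all first-order corrected estimators it can go slightly negative near
  zero.

## Problem sizes used by the shipped experiments

The acceptance script runs the full published design (4,000 units, p = 100,
T = 10) once per confounding level with a shortened schedule (25 epochs,
patience 6, one replicate per γ) that is converged for this benchmark's
nearly linear outcome surface.  The test suite exercises the same pattern
at a reduced design (hundreds of units, p ≤ 20) chosen so that the entire
suite runs in minutes on one CPU.

## Known limitations

* The synthetic generator does not confound treatment *assignment* (it is
  randomized); it confounds the outcome only.  Conclusions about
  deconfounding strength under assignment confounding require a different
  generator.
* True ITE in the benchmark is homogeneous (see above).
* The autodiff core is minimal by design: no GPU, float64 only, and only
  the operations the model uses.
* IF-PEHE depends on nuisance quality; with high-dimensional flattened
  histories and few units the ridge default can be far from the oracle
  value even when its ranking of candidate models is correct.
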