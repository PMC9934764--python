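# vtdeconf

Individualized treatment effect (ITE) estimation from longitudinal
observational data when the recorded covariates are only *proxies* of
hidden confounders.

Most longitudinal causal-inference methods assume sequential ignorability:
every variable that drives both treatment and outcome is measured.  In
electronic-health-record data that assumption routinely fails —
socioeconomic status, frailty, or preferences influence care and outcomes
but appear in the record only through surrogates (lab patterns, visit
frequency, assessments).  `vtdeconf` implements a variational temporal
deconfounder for this setting: a causally masked self-attention encoder
with an elapsed-time–decayed state, h_t = o_t + H(Δt)·h_{t−1}, feeds a
sequence variational autoencoder whose latent path z_t acts as a learned
substitute for the hidden confounders; a propensity head σ(f_a(z_t)) and an
outcome head f_y([z_t, a_t]) are trained jointly with the objective

    L = E[w′_t (y′_t − y_t)²] − α·L_ELBO + L_propensity,
    w′_t = Pr(A)·a′_t + (1 − Pr(A))·(1 − a′_t),

where L_ELBO is a timestep-wise evidence lower bound with a learned
state-dependent Gaussian prior.  The ITE estimate for a unit is
f_y([z_T, 1]) − f_y([z_T, 0]).  The package also ships:

* a confounded longitudinal benchmark generator with a **counterfactual
  oracle** (autoregressive proxies and hidden confounders driven by the
  treatment history, cached noise for common-random-number replay, hence
  exact ground-truth ITE);
* a parametric **g-formula** baseline and a no-latent ablation;
* **PEHE** and cross-fitted influence-function **IF-PEHE** evaluation;
* CSV readers/writers for long-format clinical tables and a CLI.

The model is trained with a small numpy reverse-mode autodiff core included
in the package (no deep-learning framework required); every gradient is
checked against finite differences in the test suite.  See
`docs/methods.md` for the full model description and design choices.

## Worked example

```python
import vtdeconf as v

# 200 treated + 600 control units, 20 proxies, 10 steps, confounding 0.2
ds = v.simulate_dataset(v.SimulationConfig(
    n_treated=200, n_control=600, p=20, T=10, gamma=0.2, seed=5))
parts = v.split_dataset(ds, fractions=(0.8, 0.1, 0.1), seed=5)

model = v.VTDRegressor(epochs=15, random_state=0)
model.fit(parts.train, val_dataset=parts.val)

print("test RMSE :", v.rmse(model.predict(parts.test), parts.test.Y))
est = model.predict_ite(parts.test)
print("PEHE      :", v.pehe(est.ite_hat, parts.test.ite_true))
print("true ITE  :", parts.test.ite_true[0])
```

Output from this exact script:

```
test RMSE : 0.0497665153930894
PEHE      : 0.00013095335806897384
true ITE  : 0.0004197208841327793
```

The test RMSE is small relative to the outcome standard deviation
(≈1.11 here): the model has recovered the outcome surface.  PEHE is
the mean squared error of the per-unit effect estimates against the
generator's counterfactual oracle; the true effect in this benchmark is the
same for every unit (the generator is linear and treatment enters
additively), and its magnitude is small because treatment weights are drawn
with standard deviation 0.02.

The same pipeline is available from the shell:

```bash
vtdeconf simulate --gamma 0.1 --seed 1 --out data/
vtdeconf train --data data/ --seed 1 --out run/
vtdeconf evaluate --data data/ --model run/checkpoint.npz
vtdeconf sweep-gamma --gammas 0,0.2,0.4,0.6 --out sweep/
```

Every command writes a `manifest.json` recording the full configuration and
seeds.

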