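"""Generator correctness: stated weight distributions, treatment design,
autoregressive dynamics, counterfactual oracle, and equivalence with an
independently coded brute-force generator on a small instance."""

import numpy as np
import pytest

from vtdeconf.simulate import (ARWeights, OutcomeWeights, SimulationConfig,
                               assign_treatments, compute_confounder_and_outcome,
                               counterfactual_outcome, draw_weights,
                               simulate_dataset, simulate_trajectories)


# --------------------------------------------------------------------- config
@pytest.mark.parametrize("bad", [
    {"n_treated": 0}, {"p": 0}, {"T": 0}, {"gamma": -0.1}, {"gamma": 1.5},
    {"noise_sd_eta": 0.0}, {"tau": -1},
])
def test_config_rejects_invalid_values(bad):
    with pytest.raises(ValueError):
        SimulationConfig(**bad)


# -------------------------------------------------------------------- weights
def test_ar_weight_distributions_match_their_means_and_scales():
    """alpha_{r,j} centers on 1 - r/p; beta has sd treat_weight_sd."""
    p = 40
    cfg = SimulationConfig(n_treated=2, n_control=2, p=p, T=3, seed=0)
    alphas, betas = [], []
    for seed in range(300):
        ar, _ = draw_weights(cfg, rng=np.random.default_rng(seed))
        alphas.append(ar.alpha)
        betas.append(ar.beta)
    alphas = np.stack(alphas)          # (draws, lag, j)
    lag_means = alphas.mean(axis=(0, 2))
    expected = 1.0 - np.arange(1, p + 1) / p
    # sd of each mean is (1/p)/sqrt(300*p)
    np.testing.assert_allclose(lag_means, expected, atol=4 * (1 / p) / np.sqrt(300 * p))
    assert abs(np.std(np.stack(betas)) - 0.02) < 0.002


def test_outcome_weights_bounded_and_feature_map_seeded():
    cfg = SimulationConfig(n_treated=2, n_control=2, p=7, T=3, seed=5)
    _, ow1 = draw_weights(cfg)
    _, ow2 = draw_weights(cfg)
    assert np.abs(ow1.w).max() <= 1.0
    np.testing.assert_array_equal(ow1.W_g, ow2.W_g)
    assert ow1.W_g.shape == (cfg.r, cfg.p + cfg.d_static)


def test_draw_weights_deterministic_given_seed():
    cfg = SimulationConfig(n_treated=2, n_control=2, p=5, T=3, seed=9)
    ar1, ow1 = draw_weights(cfg)
    ar2, ow2 = draw_weights(cfg)
    for a, b in [(ar1.alpha, ar2.alpha), (ar1.mu, ar2.mu), (ar1.beta, ar2.beta),
                 (ar1.v, ar2.v), (ow1.w, ow2.w), (ow1.W_g, ow2.W_g)]:
        np.testing.assert_array_equal(a, b)


# ------------------------------------------------------------------ treatment
def test_treatment_assignment_counts_and_persistence():
    cfg = SimulationConfig(n_treated=1000, n_control=3000, p=3, T=10, seed=2)
    A = assign_treatments(cfg)
    treated = (A == 1).any(axis=1)
    assert treated.sum() == 1000
    assert (~treated).sum() == 3000
    assert treated.mean() == pytest.approx(0.25)
    # once on, stays on
    assert (np.diff(A, axis=1) >= 0).all()
    # every treated row switches on within the observed window
    assert (A[treated].max(axis=1) == 1).all()


# ----------------------------------------------------------------- dynamics
def test_first_step_is_pure_noise():
    """With no history, x_1 = eta_1, so sd(X[:, 0, :]) ~ noise_sd_eta."""
    cfg = SimulationConfig(n_treated=5000, n_control=5000, p=4, T=3, seed=3)
    ds = simulate_dataset(cfg)
    assert ds.X[:, 0, :].std() == pytest.approx(0.01, rel=0.05)
    # the scalar noise is shared across columns at t=1
    assert np.ptp(ds.X[:, 0, :], axis=1).max() == 0.0


def test_zero_noise_and_no_treatment_give_zero_trajectories():
    cfg = SimulationConfig(n_treated=3, n_control=5, p=4, T=5, seed=4)
    ar, _ = draw_weights(cfg)
    A = np.zeros((8, cfg.horizon), dtype=int)
    zeros = np.zeros((8, cfg.horizon))
    X, Z, _ = simulate_trajectories(cfg, ar, A, noise=(zeros, zeros))
    assert not X.any() and not Z.any()


def test_trajectories_deterministic_given_seed():
    cfg = SimulationConfig(n_treated=5, n_control=5, p=4, T=5, seed=8)
    d1 = simulate_dataset(cfg)
    d2 = simulate_dataset(cfg)
    np.testing.assert_array_equal(d1.X, d2.X)
    np.testing.assert_array_equal(d1.Z, d2.Z)
    np.testing.assert_array_equal(d1.Y, d2.Y)
    np.testing.assert_array_equal(d1.ite_true, d2.ite_true)


# ---------------------------------------------------------- confounder & Y
def _tiny(gamma, seed=6, **kw):
    return SimulationConfig(n_treated=4, n_control=8, p=3, T=4, gamma=gamma,
                            seed=seed, **kw)


def test_gamma_zero_outcome_ignores_hidden_process():
    cfg = _tiny(0.0)
    ds = simulate_dataset(cfg)
    feats = np.concatenate([ds.X, np.broadcast_to(
        ds.C[:, None, :], (ds.n_units, cfg.T, cfg.d_static))], axis=2)
    expected = feats @ ds.outcome_weights.W_g.T
    np.testing.assert_allclose(ds.Q, expected, atol=1e-12)


def test_gamma_one_confounder_is_running_mean_of_z():
    cfg = _tiny(1.0)
    ds = simulate_dataset(cfg)
    running = np.cumsum(ds.Z, axis=1) / np.arange(1, cfg.T + 1)[None, :, None]
    np.testing.assert_allclose(ds.Q, running, atol=1e-12)


def test_outcome_linear_in_confounder_summary():
    cfg = _tiny(0.5)
    ds = simulate_dataset(cfg)
    w, b = ds.outcome_weights.w, ds.outcome_weights.b
    q_T = ds.Q[:, -1, :]
    np.testing.assert_allclose(ds.Y, q_T @ w + b, atol=1e-12)
    np.testing.assert_allclose((2 * q_T) @ w + b - b, 2 * (ds.Y - b), atol=1e-12)


# --------------------------------------------------------------- oracle
def test_counterfactual_consistency_with_factual_row():
    ds = simulate_dataset(_tiny(0.4))
    for i in [0, 3, 7]:
        uid = int(ds.unit_ids[i])
        y = counterfactual_outcome(ds, uid, ds.A[i])
        assert y == pytest.approx(ds.Y[i], abs=1e-12)


def test_counterfactual_rejects_bad_inputs():
    ds = simulate_dataset(_tiny(0.4))
    with pytest.raises(KeyError):
        counterfactual_outcome(ds, 10_000, ds.A[0])
    with pytest.raises(ValueError):
        counterfactual_outcome(ds, int(ds.unit_ids[0]), np.full(ds.n_steps, 2))


def test_null_treatment_weights_give_zero_ite():
    cfg = _tiny(0.4, seed=12)
    ds = simulate_dataset(cfg)
    ds.ar_weights.beta[:] = 0.0
    ds.ar_weights.v[:] = 0.0
    uid = int(ds.unit_ids[2])
    y_on = counterfactual_outcome(ds, uid, np.ones(cfg.T, dtype=int))
    y_off = counterfactual_outcome(ds, uid, np.zeros(cfg.T, dtype=int))
    assert y_on == pytest.approx(y_off, abs=1e-14)


def test_null_effect_dataset_has_identically_zero_ite():
    cfg = SimulationConfig(n_treated=6, n_control=10, p=3, T=4,
                           treat_weight_sd=1e-12, seed=13)
    ds = simulate_dataset(cfg)
    assert np.abs(ds.ite_true).max() < 1e-10


def test_mean_ite_magnitude_grows_with_treatment_weight_scale():
    sizes = []
    for sd in [0.02, 0.2, 2.0]:
        ds = simulate_dataset(SimulationConfig(
            n_treated=30, n_control=30, p=4, T=5, treat_weight_sd=sd, seed=21))
        sizes.append(np.abs(ds.ite_true).mean())
    assert sizes[0] < sizes[1] < sizes[2]


# ----------------------------------------------- brute-force equivalence
def brute_force_generate(cfg, ar, ow, A, C, eta, eps):
    """Independent scalar-loop transcription of the generator equations."""
    n, t_all = A.shape
    p, r = cfg.p, cfg.r
    X = np.zeros((n, t_all, p))
    Z = np.zeros((n, t_all, r))
    for i in range(n):
        for t in range(t_all):
            for j in range(p):
                s = 0.0
                for lag in range(1, p + 1):
                    if t - lag >= 0:
                        s += ar.alpha[lag - 1, j] * X[i, t - lag, j]
                        s += ar.beta[lag - 1] * A[i, t - lag]
                X[i, t, j] = s / p + eta[i, t]
            for j in range(r):
                s = 0.0
                for lag in range(1, p + 1):
                    if t - lag >= 0:
                        s += ar.mu[lag - 1, j] * Z[i, t - lag, j]
                        s += ar.v[lag - 1] * A[i, t - lag]
                Z[i, t, j] = s / p + eps[i, t]
    Q = np.zeros((n, t_all, r))
    y = np.zeros((n, t_all))
    for i in range(n):
        for t in range(t_all):
            zbar = Z[i, :t + 1].mean(axis=0)
            g = ow.W_g @ np.concatenate([X[i, t], C[i]])
            Q[i, t] = cfg.gamma * zbar + (1 - cfg.gamma) * g
            y[i, t] = ow.w @ Q[i, t] + ow.b
    return X, Z, Q, y


def test_generator_matches_independent_brute_force():
    cfg = SimulationConfig(n_treated=3, n_control=5, p=3, T=4, gamma=0.3,
                           seed=31)
    ds = simulate_dataset(cfg)
    X, Z, Q, y = brute_force_generate(
        cfg, ds.ar_weights, ds.outcome_weights, ds.A_full, ds.C,
        ds.noise_cache["eta"], ds.noise_cache["eps"])
    np.testing.assert_allclose(ds.X, X, atol=1e-12)
    np.testing.assert_allclose(ds.Z, Z, atol=1e-12)
    np.testing.assert_allclose(ds.Q, Q, atol=1e-12)
    np.testing.assert_allclose(ds.Y, y[:, -1], atol=1e-12)
    # and the oracle contrast agrees with brute-force re-simulation
    ones = np.ones_like(ds.A_full)
    zeros = np.zeros_like(ds.A_full)
    _, _, _, y1 = brute_force_generate(cfg, ds.ar_weights, ds.outcome_weights,
                                       ones, ds.C, ds.noise_cache["eta"],
                                       ds.noise_cache["eps"])
    _, _, _, y0 = brute_force_generate(cfg, ds.ar_weights, ds.outcome_weights,
                                       zeros, ds.C, ds.noise_cache["eta"],
                                       ds.noise_cache["eps"])
    np.testing.assert_allclose(ds.ite_true, y1[:, -1] - y0[:, -1], atol=1e-12)


def test_defaults_match_stated_design():
    cfg = SimulationConfig()
    assert (cfg.n_units, cfg.T, cfg.p, cfg.gamma) == (4000, 10, 100, 0.1)


def test_thinning_produces_irregular_elapsed_times():
    cfg = SimulationConfig(n_treated=10, n_control=10, p=3, T=8,
                           thin_prob=0.4, seed=17)
    ds = simulate_dataset(cfg)
    assert (ds.dt[ds.mask] >= 1).all()
    assert (ds.dt[ds.mask] > 1).any()
    assert not ds.mask.all()
    # outcome is still read at the (kept) final step
    np.testing.assert_allclose(
        ds.Y, ds.y_seq[np.arange(ds.n_units), ds.horizon_index()])
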