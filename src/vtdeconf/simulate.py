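"""Confounded longitudinal benchmark generator with a counterfactual oracle.

Covariates (proxies) x and hidden confounders z evolve through parallel
autoregressive processes driven by the treatment history:

    x_{t,j} = (1/p) * sum_{r=1..p} ( alpha_{r,j} x_{t-r,j} + beta_r a_{t-r} ) + eta_t
    z_{t,j} = (1/p) * sum_{r=1..p} ( mu_{r,j}    z_{t-r,j} + v_r    a_{t-r} ) + eps_t

with alpha_{r,j}, mu_{r,j} ~ N(1 - r/p, (1/p)^2) (more recent lags carry more
weight), beta_r, v_r ~ N(0, 0.02^2) (treatment influence) and scalar noises
eta_t, eps_t ~ N(0, 0.01^2) drawn per unit and step.  Lags reaching before the
first step contribute zero.  A confounder summary mixes the running mean of
the hidden process with a fixed linear feature map g of the current
observables, with mixing weight gamma (the confounding factor):

    q_t = gamma * mean(z_1..z_t) + (1 - gamma) * g([x_t, c])
    y_t = w^T q_t + b

The factual outcome is read at the horizon step.  All noise draws are cached
so that counterfactual outcomes under alternative treatment rows can be
replayed with common random numbers, which defines a unit-level ground-truth
individualized treatment effect (always-treated minus never-treated).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datasets import LongitudinalDataset

__all__ = [
    "SimulationConfig",
    "ARWeights",
    "OutcomeWeights",
    "SyntheticDataset",
    "draw_weights",
    "assign_treatments",
    "simulate_trajectories",
    "compute_confounder_and_outcome",
    "counterfactual_outcome",
    "simulate_dataset",
]


@dataclass
class SimulationConfig:
    n_treated: int = 1000
    n_control: int = 3000
    p: int = 100                 # proxy dimension
    r: int | None = None         # hidden-confounder dimension, defaults to p
    T: int = 10                  # observed timesteps
    gamma: float = 0.1           # confounding factor in [0, 1]
    tau: int = 0                 # extra steps before the outcome is read
    d_static: int = 5
    noise_sd_eta: float = 0.01
    noise_sd_eps: float = 0.01
    treat_weight_sd: float = 0.02
    thin_prob: float = 0.0       # probability of dropping an interior step
    seed: int = 0

    def __post_init__(self):
        if self.r is None:
            self.r = self.p
        for name in ("n_treated", "n_control", "p", "r", "T"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0.0 <= self.gamma <= 1.0:
            raise ValueError("gamma must lie in [0, 1]")
        if self.tau < 0:
            raise ValueError("tau must be >= 0")
        for name in ("noise_sd_eta", "noise_sd_eps", "treat_weight_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not 0.0 <= self.thin_prob < 1.0:
            raise ValueError("thin_prob must lie in [0, 1)")

    @property
    def n_units(self) -> int:
        return self.n_treated + self.n_control

    @property
    def horizon(self) -> int:
        """Total simulated steps; the outcome is read at the last one."""
        return self.T + self.tau


@dataclass
class ARWeights:
    alpha: np.ndarray  # (p, p): [lag r-1, column j]
    mu: np.ndarray     # (p, r)
    beta: np.ndarray   # (p,)
    v: np.ndarray      # (p,)


@dataclass
class OutcomeWeights:
    w: np.ndarray      # (r,) ~ Uniform(-1, 1)
    b: float           # ~ N(0, 0.1)
    W_g: np.ndarray    # (r, p + d_static), fixed seeded linear feature map g


@dataclass
class SyntheticDataset(LongitudinalDataset):
    Z: np.ndarray = None            # (N, T, r) hidden confounders
    Q: np.ndarray = None            # (N, T, r) confounder summary
    ite_true: np.ndarray = None     # (N,) oracle individualized effect
    config: SimulationConfig = None
    ar_weights: ARWeights = None
    outcome_weights: OutcomeWeights = None
    noise_cache: dict = field(default_factory=dict)   # eta, eps over horizon steps
    permutation: np.ndarray = None  # row shuffle applied after assignment
    A_full: np.ndarray = None       # (N, T+tau) treatment over all simulated steps
    kept_steps: np.ndarray = None   # (N, T) original step index per compacted slot

    def subset(self, idx) -> "SyntheticDataset":
        idx = np.asarray(idx)
        return SyntheticDataset(
            X=self.X[idx], A=self.A[idx], y_seq=self.y_seq[idx], Y=self.Y[idx],
            C=self.C[idx], dt=self.dt[idx], mask=self.mask[idx],
            unit_ids=self.unit_ids[idx],
            Z=self.Z[idx], Q=self.Q[idx], ite_true=self.ite_true[idx],
            config=self.config, ar_weights=self.ar_weights,
            outcome_weights=self.outcome_weights,
            noise_cache={k: v[idx] for k, v in self.noise_cache.items()},
            permutation=None,
            A_full=self.A_full[idx] if self.A_full is not None else None,
            kept_steps=self.kept_steps[idx] if self.kept_steps is not None else None,
        )


def _rngs(config: SimulationConfig, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(config.seed).spawn(n)]


def draw_weights(config: SimulationConfig,
                 rng: np.random.Generator | None = None) -> tuple[ARWeights, OutcomeWeights]:
    """Draw the per-dataset autoregressive and outcome weights."""
    if rng is None:
        rng = _rngs(config, 1)[0]
    p, r, d = config.p, config.r, config.d_static
    lag = np.arange(1, p + 1)
    lag_mean = 1.0 - lag / p
    alpha = rng.normal(lag_mean[:, None], 1.0 / p, size=(p, p))
    mu = rng.normal(lag_mean[:, None], 1.0 / p, size=(p, r))
    beta = rng.normal(0.0, config.treat_weight_sd, size=p)
    v = rng.normal(0.0, config.treat_weight_sd, size=p)
    w = rng.uniform(-1.0, 1.0, size=r)
    b = rng.normal(0.0, np.sqrt(0.1))
    # random-feature normalization keeps each component of g([x, c]) at O(1)
    W_g = rng.normal(0.0, 1.0 / np.sqrt(p + d), size=(r, p + d))
    return ARWeights(alpha, mu, beta, v), OutcomeWeights(w, float(b), W_g)


def assign_treatments(config: SimulationConfig,
                      rng: np.random.Generator | None = None,
                      return_permutation: bool = False):
    """Treatment rows over all simulated steps.

    The first ``n_treated`` rows switch on at a uniformly random step within
    the observed window and stay on (sustained-treatment regime); control
    rows are all zero.  Rows are then shuffled and the permutation recorded.
    """
    if rng is None:
        rng = _rngs(config, 2)[1]
    n, t_all = config.n_units, config.horizon
    A = np.zeros((n, t_all), dtype=np.int64)
    starts = rng.integers(0, config.T, size=config.n_treated)
    for i, s in enumerate(starts):
        A[i, s:] = 1
    perm = rng.permutation(n)
    A = A[perm]
    if return_permutation:
        return A, perm
    return A


def _ar_step(history: np.ndarray, coeff: np.ndarray, a_hist: np.ndarray,
             treat_w: np.ndarray, noise_t: np.ndarray, p: int) -> np.ndarray:
    """One autoregressive update. history: (N, L, d) most-recent-first."""
    L = history.shape[1]
    acc = np.einsum("nld,ld->nd", history, coeff[:L])
    acc_a = a_hist @ treat_w[:L]
    return (acc + acc_a[:, None]) / p + noise_t[:, None]


def simulate_trajectories(config: SimulationConfig, weights: ARWeights,
                          A: np.ndarray,
                          noise: tuple[np.ndarray, np.ndarray] | None = None,
                          rng: np.random.Generator | None = None):
    """Run the coupled autoregressions for x and z over all simulated steps.

    Returns (X, Z, noise_cache); pass `noise=(eta, eps)` to replay with
    common random numbers.
    """
    n, t_all = A.shape
    if n != config.n_units and noise is None:
        raise ValueError("A row count does not match the configured unit count")
    if t_all != config.horizon:
        raise ValueError("A column count does not match T + tau")
    p, r = config.p, config.r
    if noise is None:
        if rng is None:
            rng = _rngs(config, 3)[2]
        eta = rng.normal(0.0, config.noise_sd_eta, size=(n, t_all))
        eps = rng.normal(0.0, config.noise_sd_eps, size=(n, t_all))
    else:
        eta, eps = noise
    X = np.zeros((n, t_all, p))
    Z = np.zeros((n, t_all, r))
    for t in range(t_all):
        L = min(t, p)
        if L == 0:
            X[:, 0] = eta[:, 0][:, None]
            Z[:, 0] = eps[:, 0][:, None]
            continue
        # lag r=1..L maps to step t-1 .. t-L (most recent first)
        hist_idx = np.arange(t - 1, t - L - 1, -1)
        a_hist = A[:, hist_idx].astype(np.float64)
        X[:, t] = _ar_step(X[:, hist_idx], weights.alpha, a_hist,
                           weights.beta, eta[:, t], p)
        Z[:, t] = _ar_step(Z[:, hist_idx], weights.mu, a_hist,
                           weights.v, eps[:, t], p)
    return X, Z, {"eta": eta, "eps": eps}


def compute_confounder_and_outcome(config: SimulationConfig, X: np.ndarray,
                                   Z: np.ndarray, C: np.ndarray,
                                   weights: OutcomeWeights):
    """Confounder summary q_t and per-step outcomes; horizon outcome is last.

    Returns (Q, y_all) with Q of shape (N, T_all, r) and y_all of (N, T_all).
    """
    gamma = config.gamma
    if not 0.0 <= gamma <= 1.0:
        raise ValueError("gamma must lie in [0, 1]")
    n, t_all, _ = X.shape
    running = np.cumsum(Z, axis=1) / np.arange(1, t_all + 1)[None, :, None]
    feats = np.concatenate(
        [X, np.broadcast_to(C[:, None, :], (n, t_all, C.shape[1]))], axis=2)
    g_val = feats @ weights.W_g.T
    Q = gamma * running + (1.0 - gamma) * g_val
    y_all = Q @ weights.w + weights.b
    return Q, y_all


def _replay_outcome(config: SimulationConfig, weights: ARWeights,
                    oweights: OutcomeWeights, A: np.ndarray, C: np.ndarray,
                    eta: np.ndarray, eps: np.ndarray) -> np.ndarray:
    X, Z, _ = simulate_trajectories(config, weights, A, noise=(eta, eps))
    _, y_all = compute_confounder_and_outcome(config, X, Z, C, oweights)
    return y_all[:, -1]


def counterfactual_outcome(dataset: "SyntheticDataset", unit: int,
                           alt_treatment_row: np.ndarray) -> float:
    """Outcome for one unit under an alternative treatment row.

    Replays the generator with the unit's cached noise draws (common random
    numbers).  `alt_treatment_row` covers the observed window; when the
    simulation runs past it (tau > 0) the final assignment persists.
    """
    cfg = dataset.config
    ids = np.flatnonzero(dataset.unit_ids == unit)
    if ids.size != 1:
        raise KeyError(f"unknown unit id {unit!r}")
    i = int(ids[0])
    row = np.asarray(alt_treatment_row)
    if row.shape != (cfg.T,) or not np.isin(row, (0, 1)).all():
        raise ValueError("alt_treatment_row must be a binary vector of length T")
    full = np.concatenate([row, np.full(cfg.tau, row[-1], dtype=row.dtype)])
    y = _replay_outcome(
        cfg, dataset.ar_weights, dataset.outcome_weights,
        full[None, :], dataset.C[i:i + 1],
        dataset.noise_cache["eta"][i:i + 1], dataset.noise_cache["eps"][i:i + 1])
    return float(y[0])


def _thin(config: SimulationConfig, rng: np.random.Generator, n: int):
    """Random step thinning for irregular-visit experiments.

    Returns (kept, dt, mask): kept[i, s] is the original step index stored in
    compacted slot s (first and last steps are always kept); mask flags the
    valid slots; dt holds the gaps between consecutive kept steps.
    """
    T = config.T
    kept = np.tile(np.arange(T), (n, 1))
    mask = np.ones((n, T), dtype=bool)
    dt = np.ones((n, T))
    if config.thin_prob <= 0:
        return kept, dt, mask
    for i in range(n):
        keep = rng.random(T) >= config.thin_prob
        keep[0] = True
        keep[-1] = True
        idx = np.flatnonzero(keep)
        k = idx.size
        kept[i, :k] = idx
        kept[i, k:] = T - 1
        mask[i] = False
        mask[i, :k] = True
        dt[i, :k] = np.diff(idx, prepend=idx[0] - 1)
        dt[i, k:] = 1.0
    return kept, dt, mask


def simulate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Generate a complete confounded dataset with its counterfactual oracle.

    The returned dataset is a pure function of the configuration (including
    its seed).  ``ite_true`` is the always-treated minus never-treated
    outcome contrast replayed with the cached noise.
    """
    rng_w, rng_a, rng_n, rng_c, rng_thin = _rngs(config, 5)
    ar_w, out_w = draw_weights(config, rng_w)
    A_full, perm = assign_treatments(config, rng_a, return_permutation=True)
    X, Z, cache = simulate_trajectories(config, ar_w, A_full, rng=rng_n)
    C = rng_c.normal(0.0, 1.0, size=(config.n_units, config.d_static))
    Q, y_all = compute_confounder_and_outcome(config, X, Z, C, out_w)

    n, T = config.n_units, config.T
    ones = np.ones_like(A_full)
    zeros = np.zeros_like(A_full)
    y1 = _replay_outcome(config, ar_w, out_w, ones, C, cache["eta"], cache["eps"])
    y0 = _replay_outcome(config, ar_w, out_w, zeros, C, cache["eta"], cache["eps"])
    ite_true = y1 - y0

    kept, dt, mask = _thin(config, rng_thin, n)
    rows = np.arange(n)[:, None]
    ds = SyntheticDataset(
        X=X[rows, kept], A=A_full[rows, kept], y_seq=y_all[rows, kept],
        Y=y_all[:, -1], C=C, dt=dt, mask=mask,
        Z=Z[rows, kept], Q=Q[rows, kept], ite_true=ite_true,
        config=config, ar_weights=ar_w, outcome_weights=out_w,
        noise_cache=cache, permutation=perm, A_full=A_full, kept_steps=kept,
    )
    return ds
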