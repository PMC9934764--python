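"""The variational temporal deconfounder network.

A causally masked self-attention encoder reads tokens ``u_t = [x_t, c,
embed(dt_t)]`` and its layer outputs are folded into a time-decayed residual
recursion ``h_t = o_t + H(dt_t) * h_{t-1}`` so that long gaps between
encounters shrink the carried-over state.  A variational head places a
diagonal-Gaussian posterior over a latent substitute ``z_t`` for the hidden
confounders (with a learned, state-dependent prior), a decoder reconstructs
the proxies from ``z_t``, and two heads predict the propensity of treatment
and the outcome under either treatment arm.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .autodiff import Tensor, concat, stack
from .nn import Module, Linear, MLP, LayerNorm, TransformerLayer

__all__ = ["VTDConfig", "GaussianSeqParams", "time_decay", "sample_latent", "VTDNetwork"]

_LOGVAR_BOUND = 10.0  # soft bound on log-variances via tanh squashing


@dataclass
class VTDConfig:
    latent_dim: int = 16
    hidden_dim: int = 64
    n_heads: int = 4
    n_layers: int = 2
    dt_embed_dim: int = 8
    decay_kind: str = "reciprocal_log"   # or "exponential", "zero"
    decay_rate: float = 1.0              # for the exponential form
    prior_inputs: str = "both_states"    # or "previous_state_only"
    alpha: float = 1.0                   # ELBO weight in the joint loss
    propensity_loss_weight: float = 1.0
    iptw_kind: str = "as_printed"        # or "stabilized"
    supervised_form: str = "squared"     # or "as_printed"
    learning_rate: float = 1e-3
    epochs: int = 200
    batch_size: int = 64
    patience: int = 10
    val_fraction: float = 0.1
    use_latent: bool = True              # False: no-latent ablation (head on h)
    seed: int = 0

    def __post_init__(self):
        for name in ("latent_dim", "hidden_dim", "n_heads", "n_layers",
                     "dt_embed_dim", "epochs", "batch_size"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.decay_kind not in ("reciprocal_log", "exponential", "zero"):
            raise ValueError(f"unknown decay_kind {self.decay_kind!r}")
        if self.prior_inputs not in ("both_states", "previous_state_only"):
            raise ValueError(f"unknown prior_inputs {self.prior_inputs!r}")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class GaussianSeqParams:
    """Per-timestep diagonal Gaussian parameters (as Tensors or arrays)."""
    mu: Tensor
    log_var: Tensor


def time_decay(delta_t, kind: str = "reciprocal_log", rate: float = 1.0) -> np.ndarray:
    """Elapsed-time decay H(dt) in (0, 1], monotone nonincreasing, H(0) = 1.

    Default form 1 / log(e + dt); `exponential` gives exp(-rate * dt);
    `zero` switches the recurrence off (used by ablation tests).
    """
    dt = np.asarray(delta_t, dtype=np.float64)
    if (dt < 0).any():
        raise ValueError("elapsed times must be nonnegative")
    if kind == "reciprocal_log":
        return 1.0 / np.log(np.e + dt)
    if kind == "exponential":
        return np.exp(-rate * dt)
    if kind == "zero":
        return np.zeros_like(dt)
    raise ValueError(f"unknown decay kind {kind!r}")


def sample_latent(params: GaussianSeqParams, seed=None, eps=None) -> Tensor:
    """Reparameterized draw z = mu + sigma * eps, differentiable in (mu, sigma)."""
    if eps is None:
        rng = np.random.default_rng(seed)
        eps = rng.standard_normal(params.mu.shape)
    sigma = (params.log_var * 0.5).exp()
    return params.mu + sigma * Tensor(eps)


def _bounded_logvar(raw: Tensor) -> Tensor:
    return (raw * (1.0 / _LOGVAR_BOUND)).tanh() * _LOGVAR_BOUND


class VTDNetwork(Module):
    """All trainable components; built from dimensions and a VTDConfig."""

    def __init__(self, p: int, d_static: int, config: VTDConfig,
                 rng: np.random.Generator):
        self.p = p
        self.d_static = d_static
        self.config = config
        h, r = config.hidden_dim, config.latent_dim
        self.dt_embed = Linear(1, config.dt_embed_dim, rng)
        self.input_proj = Linear(p + d_static + config.dt_embed_dim, h, rng)
        self.encoder_layers = [TransformerLayer(h, config.n_heads, rng)
                               for _ in range(config.n_layers)]
        self.encoder_norm = LayerNorm(h)
        self.phi_enc = MLP(2 * h, [h], 2 * r, rng)       # posterior head
        prior_in = 2 * h if config.prior_inputs == "both_states" else h
        self.prior_net = MLP(prior_in, [h], 2 * r, rng)  # distinct parameter set
        self.dec_g = MLP(r + h, [h], h, rng)
        self.dec_mu = Linear(h, p, rng)
        self.dec_logvar = Linear(h, p, rng)
        self.f_a = MLP(r, [h], 1, rng)
        self.f_y = MLP(r + 1, [h], 1, rng)
        self.no_latent_proj = Linear(h, r, rng)          # ablation path

    # ------------------------------------------------------------ encoder
    def embed_history(self, X, C, dt) -> Tensor:
        """Hidden states h (N, T, hidden): decayed residual recursion over
        causally masked attention outputs."""
        X = np.asarray(X, dtype=np.float64)
        C = np.asarray(C, dtype=np.float64)
        dt = np.asarray(dt, dtype=np.float64)
        if not (np.isfinite(X).all() and np.isfinite(C).all()):
            raise ValueError("non-finite inputs")
        n, t, _ = X.shape
        temb = self.dt_embed(Tensor(dt[..., None])).tanh()
        c_rep = Tensor(np.broadcast_to(C[:, None, :], (n, t, C.shape[1])).copy())
        tokens = concat([Tensor(X), c_rep, temb], axis=2)
        o = self.input_proj(tokens)
        for layer in self.encoder_layers:
            o = layer(o)
        o = self.encoder_norm(o)
        decay = time_decay(dt, self.config.decay_kind, self.config.decay_rate)
        states = []
        h_prev = Tensor(np.zeros((n, o.shape[2])))
        for step in range(t):
            h_t = o[:, step] + Tensor(decay[:, step][:, None]) * h_prev
            states.append(h_t)
            h_prev = h_t
        return stack(states, axis=1)

    @staticmethod
    def _shift(h: Tensor) -> Tensor:
        """h_{t-1} sequence with h_0 = 0."""
        n, t, d = h.shape
        zeros = Tensor(np.zeros((n, 1, d)))
        return concat([zeros, h[:, :-1]], axis=1)

    def posterior_params(self, h: Tensor) -> GaussianSeqParams:
        """Variational posterior parameters from [h_{t-1}, h_t]."""
        out = self.phi_enc(concat([self._shift(h), h], axis=2))
        r = self.config.latent_dim
        return GaussianSeqParams(out[:, :, :r], _bounded_logvar(out[:, :, r:]))

    def prior_params(self, h: Tensor) -> GaussianSeqParams:
        """Learned state-dependent prior; optionally blind to the current step."""
        h_prev = self._shift(h)
        if self.config.prior_inputs == "both_states":
            inp = concat([h, h_prev], axis=2)
        else:
            inp = h_prev
        out = self.prior_net(inp)
        r = self.config.latent_dim
        return GaussianSeqParams(out[:, :, :r], _bounded_logvar(out[:, :, r:]))

    # ------------------------------------------------------------ decoder
    def decode_proxies(self, z: Tensor, h_prev: Tensor) -> GaussianSeqParams:
        """Diagonal-Gaussian reconstruction parameters over x_t."""
        hidden = self.dec_g(concat([z, h_prev], axis=2)).tanh()
        return GaussianSeqParams(self.dec_mu(hidden),
                                 _bounded_logvar(self.dec_logvar(hidden)))

    # -------------------------------------------------------------- heads
    def predict_propensity(self, z: Tensor) -> Tensor:
        """Per-step treatment probability a'_t, strictly inside (0, 1)."""
        n, t, _ = z.shape
        return self.f_a(z).sigmoid().reshape(n, t)

    def predict_outcome(self, z: Tensor, a) -> Tensor:
        """Outcome prediction from [z_t, a_t]; evaluate at a=1 and a=0 for
        the two potential-outcome predictions."""
        a = np.asarray(a, dtype=np.float64)
        n, t, _ = z.shape
        inp = concat([z, Tensor(a[..., None])], axis=2)
        return self.f_y(inp).reshape(n, t)

    # ------------------------------------------------------------ forward
    def forward(self, X, C, dt, A, eps=None, sample: bool = True,
                seed: int | None = None) -> dict:
        """Full pass; returns hidden states, posterior/prior/reconstruction
        parameters, the latent path z, propensities and outcome predictions."""
        h = self.embed_history(X, C, dt)
        h_prev = self._shift(h)
        if self.config.use_latent:
            post = self.posterior_params(h)
            prior = self.prior_params(h)
            if sample:
                z = sample_latent(post, seed=seed, eps=eps)
            else:
                z = post.mu
            recon = self.decode_proxies(z, h_prev)
        else:
            z = self.no_latent_proj(h).tanh()
            post = prior = recon = None
        a_prob = self.predict_propensity(z)
        y_pred = self.predict_outcome(z, A)
        return {"h": h, "post": post, "prior": prior, "z": z,
                "recon": recon, "a_prob": a_prob, "y_pred": y_pred}
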