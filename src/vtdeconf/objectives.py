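"""Training objectives: IPTW weights, weighted supervised loss, the
timestep-wise evidence lower bound, and the joint loss.

The joint loss is ``L = L_s - alpha * L_ELBO + w_a * L_propensity``: the
supervised (IPTW-weighted) outcome loss, minus the weighted ELBO of the
sequence VAE, plus a binary cross-entropy term that trains the propensity
head (weight 0 recovers the bare two-term objective).

Functions accept either numpy arrays or autodiff Tensors and return Tensors
so the same code path serves training and the closed-form unit tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, as_tensor
from .model import GaussianSeqParams

__all__ = [
    "LossReport",
    "iptw_weights",
    "supervised_loss",
    "propensity_cross_entropy",
    "gaussian_kl",
    "gaussian_log_likelihood",
    "elbo",
    "total_loss",
]

_EPS = 1e-7


@dataclass
class LossReport:
    supervised: float
    elbo: float
    kl_per_step: np.ndarray
    reconstruction_ll: float
    propensity_ce: float
    total: float


def iptw_weights(a_prob, p_treat: float, kind: str = "as_printed",
                 a_obs=None, clip_ceiling: float = 10.0) -> Tensor:
    """Inverse-probability-of-treatment weights from predicted propensities.

    `as_printed` evaluates w = Pr(A) * a' + (1 - Pr(A)) * (1 - a'), a convex
    combination bounded between Pr(A) and 1 - Pr(A).  `stabilized` is the
    conventional stabilized form Pr(A) * a / a' + (1 - Pr(A)) * (1 - a) /
    (1 - a') (requires the observed treatment), clipped at `clip_ceiling`.
    """
    a_prob = as_tensor(a_prob)
    if not 0.0 < p_treat < 1.0:
        raise ValueError("p_treat must lie strictly inside (0, 1)")
    if ((a_prob.data <= 0) | (a_prob.data >= 1)).any():
        raise ValueError("propensities must lie strictly inside (0, 1)")
    if kind == "as_printed":
        return a_prob * p_treat + (1.0 - a_prob) * (1.0 - p_treat)
    if kind == "stabilized":
        if a_obs is None:
            raise ValueError("stabilized weights need the observed treatment")
        a_obs = as_tensor(a_obs)
        w = a_obs * (p_treat / a_prob) + (1.0 - a_obs) * ((1.0 - p_treat) / (1.0 - a_prob))
        return -((-w).clip_min(-clip_ceiling))  # elementwise min(w, ceiling)
    raise ValueError(f"unknown IPTW kind {kind!r}")


def supervised_loss(w, y_pred, y_obs, mask=None, form: str = "squared") -> Tensor:
    """IPTW-weighted outcome loss over supervised positions.

    Default `squared` averages w * (y' - y)^2; `as_printed` averages the
    signed residual w * (y' - y) literally.
    """
    w = as_tensor(w)
    y_pred = as_tensor(y_pred)
    y_obs = as_tensor(y_obs)
    if mask is None:
        mask = np.ones(y_pred.shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("supervised loss needs at least one masked position")
    m = Tensor(mask.astype(np.float64))
    resid = y_pred - y_obs
    if form == "squared":
        per = w * resid * resid
    elif form == "as_printed":
        per = w * resid
    else:
        raise ValueError(f"unknown supervised loss form {form!r}")
    return (per * m).sum() * (1.0 / mask.sum())


def propensity_cross_entropy(a_prob, a_obs, mask=None) -> Tensor:
    """Binary cross-entropy between predicted propensities and treatments."""
    a_prob = as_tensor(a_prob)
    a_obs = as_tensor(np.asarray(a_obs, dtype=np.float64))
    if mask is None:
        mask = np.ones(a_prob.shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    p = a_prob.clip_min(_EPS)
    q = (1.0 - a_prob).clip_min(_EPS)
    per = -(a_obs * p.log() + (1.0 - a_obs) * q.log())
    m = Tensor(mask.astype(np.float64))
    return (per * m).sum() * (1.0 / mask.sum())


def gaussian_kl(post: GaussianSeqParams, prior: GaussianSeqParams) -> Tensor:
    """Closed-form KL(q || p) for diagonal Gaussians, summed over the latent
    dimension: result has shape (N, T)."""
    mu_q, lv_q = as_tensor(post.mu), as_tensor(post.log_var)
    mu_p, lv_p = as_tensor(prior.mu), as_tensor(prior.log_var)
    if np.isinf(lv_q.data).any() or np.isinf(lv_p.data).any():
        raise ValueError("variances must be strictly positive and finite")
    var_q = lv_q.exp()
    var_p = lv_p.exp()
    diff = mu_q - mu_p
    kl = 0.5 * (lv_p - lv_q + (var_q + diff * diff) / var_p - 1.0)
    return kl.sum(axis=-1)


def gaussian_log_likelihood(x, params: GaussianSeqParams) -> Tensor:
    """Diagonal-Gaussian log density of x, summed over the last axis."""
    x = as_tensor(x)
    mu, lv = as_tensor(params.mu), as_tensor(params.log_var)
    diff = x - mu
    per = -0.5 * (np.log(2.0 * np.pi) + lv + diff * diff * (-lv).exp())
    return per.sum(axis=-1)


def elbo(recon: GaussianSeqParams, x, post: GaussianSeqParams,
         prior: GaussianSeqParams, mask=None,
         return_parts: bool = False):
    """Single-sample ELBO: masked sum over timesteps of reconstruction
    log-likelihood minus per-step KL, averaged over units."""
    x = np.asarray(x, dtype=np.float64)
    n, t = x.shape[0], x.shape[1]
    if mask is None:
        mask = np.ones((n, t), dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    m = Tensor(mask.astype(np.float64))
    ll = gaussian_log_likelihood(x, recon)        # (N, T)
    kl = gaussian_kl(post, prior)                 # (N, T)
    if ll.shape != kl.shape:
        raise ValueError("reconstruction and KL shapes disagree")
    value = ((ll - kl) * m).sum() * (1.0 / n)
    if return_parts:
        recon_total = float((ll * m).sum().data) / n
        kl_steps = (kl.data * mask).sum(axis=0) / np.maximum(mask.sum(axis=0), 1)
        return value, recon_total, kl_steps
    return value


def total_loss(l_s, l_elbo, l_propensity=0.0, alpha: float = 1.0,
               propensity_loss_weight: float = 1.0) -> Tensor:
    """Joint objective L = L_s - alpha * L_ELBO + w_a * L_propensity."""
    return (as_tensor(l_s) - alpha * as_tensor(l_elbo)
            + propensity_loss_weight * as_tensor(l_propensity))
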