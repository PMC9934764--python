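"""Scikit-learn-style estimators.

:class:`VTDRegressor` trains the variational temporal deconfounder on a
:class:`~vtdeconf.datasets.LongitudinalDataset` and exposes factual outcome
prediction (`predict`) and individualized-treatment-effect estimation
(`predict_ite`).  :class:`GFormula` is the parametric
regression-plus-standardization baseline.  Both follow the sklearn estimator
contract (constructor stores hyperparameters unchanged, `fit` returns self,
fitted attributes end in an underscore, `get_params`/`set_params` work).
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.linear_model import Ridge

from . import objectives as obj
from .autodiff import Tensor
from .datasets import LongitudinalDataset
from .model import VTDConfig, VTDNetwork
from .nn import Adam

__all__ = ["ITEEstimates", "VTDRegressor", "GFormula"]


@dataclass
class ITEEstimates:
    y1_hat: np.ndarray      # predicted outcome under sustained treatment
    y0_hat: np.ndarray      # predicted outcome under no treatment
    ite_hat: np.ndarray     # y1_hat - y0_hat
    propensity: np.ndarray  # predicted treatment probability at the horizon
    weights: np.ndarray     # IPTW weights at the horizon


def _masked_stats(values: np.ndarray, mask: np.ndarray):
    """Mean/sd over masked positions, per trailing feature if 3-D."""
    if values.ndim == 3:
        sel = values[mask]
        mean = sel.mean(axis=0)
        sd = sel.std(axis=0)
    else:
        sel = values[mask & np.isfinite(values)]
        mean = sel.mean()
        sd = sel.std()
    return mean, np.where(sd < 1e-12, 1.0, sd)


class VTDRegressor(BaseEstimator):
    """Variational temporal deconfounder for longitudinal ITE estimation.

    Parameters mirror :class:`~vtdeconf.model.VTDConfig`; `use_latent=False`
    gives the no-latent ablation (outcome/propensity heads read a projection
    of the deterministic hidden state and the variational terms are dropped).
    Inputs and outcomes are standardized with training-split statistics and
    predictions are mapped back to the original scale.
    """

    def __init__(self, latent_dim=16, hidden_dim=64, n_heads=4, n_layers=2,
                 dt_embed_dim=8, decay_kind="reciprocal_log", decay_rate=1.0,
                 prior_inputs="both_states", alpha=1.0,
                 propensity_loss_weight=1.0, iptw_kind="as_printed",
                 supervised_form="squared", learning_rate=1e-3, epochs=200,
                 batch_size=64, patience=10, val_fraction=0.1,
                 use_latent=True, standardize=True, random_state=0, verbose=0):
        self.latent_dim = latent_dim
        self.hidden_dim = hidden_dim
        self.n_heads = n_heads
        self.n_layers = n_layers
        self.dt_embed_dim = dt_embed_dim
        self.decay_kind = decay_kind
        self.decay_rate = decay_rate
        self.prior_inputs = prior_inputs
        self.alpha = alpha
        self.propensity_loss_weight = propensity_loss_weight
        self.iptw_kind = iptw_kind
        self.supervised_form = supervised_form
        self.learning_rate = learning_rate
        self.epochs = epochs
        self.batch_size = batch_size
        self.patience = patience
        self.val_fraction = val_fraction
        self.use_latent = use_latent
        self.standardize = standardize
        self.random_state = random_state
        self.verbose = verbose

    # ------------------------------------------------------------------
    def _config(self) -> VTDConfig:
        return VTDConfig(
            latent_dim=self.latent_dim, hidden_dim=self.hidden_dim,
            n_heads=self.n_heads, n_layers=self.n_layers,
            dt_embed_dim=self.dt_embed_dim, decay_kind=self.decay_kind,
            decay_rate=self.decay_rate, prior_inputs=self.prior_inputs,
            alpha=self.alpha, propensity_loss_weight=self.propensity_loss_weight,
            iptw_kind=self.iptw_kind, supervised_form=self.supervised_form,
            learning_rate=self.learning_rate, epochs=self.epochs,
            batch_size=self.batch_size, patience=self.patience,
            val_fraction=self.val_fraction, use_latent=self.use_latent,
            seed=self.random_state)

    def _scale_inputs(self, ds: LongitudinalDataset):
        if self.standardize:
            X = (ds.X - self.x_mean_) / self.x_sd_
            C = (ds.C - self.c_mean_) / self.c_sd_
            y_seq = (ds.y_seq - self.y_mean_) / self.y_sd_
        else:
            X, C, y_seq = ds.X, ds.C, ds.y_seq
        return X, C, y_seq

    # ------------------------------------------------------------------
    def fit(self, dataset: LongitudinalDataset, val_dataset=None):
        cfg = self._config()
        rng = np.random.default_rng(cfg.seed)

        if val_dataset is None and cfg.val_fraction > 0:
            n = dataset.n_units
            n_val = max(1, int(round(cfg.val_fraction * n)))
            perm = rng.permutation(n)
            val_dataset = dataset.subset(perm[:n_val])
            train = dataset.subset(perm[n_val:])
        else:
            train = dataset
        self.split_manifest_ = {
            "train_units": np.sort(train.unit_ids).tolist(),
            "val_units": (np.sort(val_dataset.unit_ids).tolist()
                          if val_dataset is not None else []),
        }

        if self.standardize:
            self.x_mean_, self.x_sd_ = _masked_stats(train.X, train.mask)
            self.c_mean_ = train.C.mean(axis=0)
            c_sd = train.C.std(axis=0)
            self.c_sd_ = np.where(c_sd < 1e-12, 1.0, c_sd)
            self.y_mean_ = float(train.Y.mean())
            y_sd = float(train.Y.std())
            self.y_sd_ = y_sd if y_sd > 1e-12 else 1.0
        else:
            self.x_mean_ = np.zeros(train.n_covariates)
            self.x_sd_ = np.ones(train.n_covariates)
            self.c_mean_ = np.zeros(train.n_static)
            self.c_sd_ = np.ones(train.n_static)
            self.y_mean_, self.y_sd_ = 0.0, 1.0

        # empirical treated-unit fraction with Laplace smoothing keeps it in (0,1)
        k = int(train.treated_unit.sum())
        self.pr_treated_ = (k + 1) / (train.n_units + 2)

        self.network_ = VTDNetwork(train.n_covariates, train.n_static, cfg, rng)
        optimizer = Adam(self.network_.parameters(), lr=cfg.learning_rate)

        X, C, y_seq = self._scale_inputs(train)
        sup_mask = train.mask & np.isfinite(y_seq)
        y_seq = np.nan_to_num(y_seq)
        n_train = train.n_units

        self.history_ = []
        best = {"rmse": np.inf, "weights": None, "epoch": -1}
        bad_epochs = 0
        for epoch in range(cfg.epochs):
            order = rng.permutation(n_train)
            epoch_report = np.zeros(5)
            n_batches = 0
            for start in range(0, n_train, cfg.batch_size):
                idx = order[start:start + cfg.batch_size]
                eps = rng.standard_normal((len(idx), train.n_steps, cfg.latent_dim))
                out = self.network_.forward(X[idx], C[idx], train.dt[idx],
                                            train.A[idx], eps=eps)
                a_clip = np.clip(out["a_prob"].data, 1e-6, 1 - 1e-6)
                w = obj.iptw_weights(a_clip, self.pr_treated_, cfg.iptw_kind,
                                     a_obs=train.A[idx])
                l_sup = obj.supervised_loss(w, out["y_pred"], y_seq[idx],
                                            sup_mask[idx], cfg.supervised_form)
                l_ce = obj.propensity_cross_entropy(out["a_prob"], train.A[idx],
                                                    train.mask[idx])
                if cfg.use_latent:
                    l_elbo = obj.elbo(out["recon"], X[idx], out["post"],
                                      out["prior"], train.mask[idx])
                    # per-step, per-dimension normalization so alpha trades
                    # off quantities of comparable magnitude
                    steps = max(train.mask[idx].sum() / len(idx), 1.0)
                    l_elbo = l_elbo * (1.0 / (steps * train.n_covariates))
                else:
                    l_elbo = Tensor(0.0)
                loss = obj.total_loss(l_sup, l_elbo, l_ce, cfg.alpha,
                                      cfg.propensity_loss_weight)
                if not np.isfinite(loss.data):
                    raise RuntimeError(
                        f"training diverged (non-finite loss) at epoch {epoch}, "
                        f"batch {n_batches}")
                optimizer.zero_grad()
                loss.backward()
                optimizer.step()
                epoch_report += [float(l_sup.data), float(l_elbo.data),
                                 float(l_ce.data), float(loss.data), 1.0]
                n_batches += 1
            sup_m, elbo_m, ce_m, tot_m, _ = epoch_report / n_batches
            record = {"epoch": epoch, "supervised": sup_m, "elbo": elbo_m,
                      "propensity_ce": ce_m, "total": tot_m}
            if val_dataset is not None:
                val_pred = self._predict_factual(val_dataset)
                val_rmse = float(np.sqrt(np.mean((val_pred - val_dataset.Y) ** 2)))
                record["val_rmse"] = val_rmse
                if val_rmse < best["rmse"] - 1e-12:
                    best = {"rmse": val_rmse,
                            "weights": [a.copy() for a in self.network_.state_arrays()],
                            "epoch": epoch}
                    bad_epochs = 0
                else:
                    bad_epochs += 1
            self.history_.append(record)
            if self.verbose:
                print(f"epoch {epoch}: " + ", ".join(
                    f"{k}={v:.4g}" for k, v in record.items() if k != "epoch"))
            if val_dataset is not None and bad_epochs >= cfg.patience:
                break
        if best["weights"] is not None:
            self.network_.load_state_arrays(best["weights"])
            self.best_epoch_ = best["epoch"]
        else:
            self.best_epoch_ = len(self.history_) - 1
        self.n_epochs_ = len(self.history_)
        self.config_ = cfg
        return self

    # ------------------------------------------------------------------
    def _forward_inference(self, dataset: LongitudinalDataset, A=None,
                           chunk: int = 512):
        """Deterministic forward pass (posterior means), chunked over units."""
        X, C, _ = self._scale_inputs(dataset)
        A = dataset.A if A is None else A
        ys, ps = [], []
        for start in range(0, dataset.n_units, chunk):
            sl = slice(start, start + chunk)
            out = self.network_.forward(X[sl], C[sl], dataset.dt[sl], A[sl],
                                        sample=False)
            ys.append(out["y_pred"].data)
            ps.append(out["a_prob"].data)
        return np.concatenate(ys), np.concatenate(ps)

    def _predict_factual(self, dataset: LongitudinalDataset) -> np.ndarray:
        y_pred, _ = self._forward_inference(dataset)
        hz = dataset.horizon_index()
        return y_pred[np.arange(dataset.n_units), hz] * self.y_sd_ + self.y_mean_

    def predict(self, dataset: LongitudinalDataset) -> np.ndarray:
        """Factual horizon-outcome predictions on the original scale."""
        return self._predict_factual(dataset)

    def predict_ite(self, dataset: LongitudinalDataset) -> ITEEstimates:
        """Potential-outcome predictions at the horizon under the two arms."""
        ones = np.ones_like(dataset.A)
        zeros = np.zeros_like(dataset.A)
        y1, prop = self._forward_inference(dataset, A=ones)
        y0, _ = self._forward_inference(dataset, A=zeros)
        hz = dataset.horizon_index()
        rows = np.arange(dataset.n_units)
        y1_h = y1[rows, hz] * self.y_sd_ + self.y_mean_
        y0_h = y0[rows, hz] * self.y_sd_ + self.y_mean_
        p_h = np.clip(prop[rows, hz], 1e-6, 1 - 1e-6)
        w = obj.iptw_weights(p_h, self.pr_treated_, self.iptw_kind,
                             a_obs=dataset.A[rows, hz]).data
        return ITEEstimates(y1_hat=y1_h, y0_hat=y0_h, ite_hat=y1_h - y0_h,
                            propensity=p_h, weights=w)

    # ------------------------------------------------------------------
    def save(self, path) -> None:
        """Checkpoint the fitted model to a compressed npz container."""
        arrays = {f"param_{i}": a for i, a in enumerate(self.network_.state_arrays())}
        meta = {
            "config": self.config_.to_dict(),
            "p": self.network_.p, "d_static": self.network_.d_static,
            "pr_treated": self.pr_treated_,
            "y_mean": self.y_mean_, "y_sd": self.y_sd_,
            "split_manifest": self.split_manifest_,
            "best_epoch": self.best_epoch_,
        }
        np.savez_compressed(
            path, meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
            x_mean=self.x_mean_, x_sd=self.x_sd_,
            c_mean=self.c_mean_, c_sd=self.c_sd_, **arrays)

    @classmethod
    def load(cls, path) -> "VTDRegressor":
        with np.load(path) as f:
            meta = json.loads(bytes(f["meta"].tobytes()).decode())
            cfg = VTDConfig(**meta["config"])
            est = cls(**{k: v for k, v in cfg.to_dict().items() if k != "seed"},
                      random_state=cfg.seed)
            est.config_ = cfg
            est.network_ = VTDNetwork(meta["p"], meta["d_static"], cfg,
                                      np.random.default_rng(cfg.seed))
            n_params = len(est.network_.parameters())
            est.network_.load_state_arrays(
                [f[f"param_{i}"] for i in range(n_params)])
            est.pr_treated_ = meta["pr_treated"]
            est.y_mean_, est.y_sd_ = meta["y_mean"], meta["y_sd"]
            est.split_manifest_ = meta["split_manifest"]
            est.best_epoch_ = meta["best_epoch"]
            est.x_mean_, est.x_sd_ = f["x_mean"], f["x_sd"]
            est.c_mean_, est.c_sd_ = f["c_mean"], f["c_sd"]
        est.n_epochs_ = meta["best_epoch"] + 1
        est.history_ = []
        return est


class GFormula(BaseEstimator):
    """Parametric g-formula: linear outcome regression on flattened history
    plus standardization over treatment regimes.

    The horizon outcome is regressed on the covariate history, static
    covariates and treatment history (truncated to `history_window` steps);
    ITE is the predicted-outcome contrast between the all-ones and all-zeros
    treatment history.  With `interactions=True`, products of the horizon
    treatment with the horizon covariates and statics enter the design, which
    makes the implied effect unit-specific.
    """

    def __init__(self, history_window=None, ridge_alpha=1e-6,
                 interactions=False):
        self.history_window = history_window
        self.ridge_alpha = ridge_alpha
        self.interactions = interactions

    def _design(self, dataset: LongitudinalDataset, A=None):
        T = dataset.n_steps
        W = T if self.history_window is None else min(self.history_window, T)
        if W < 1:
            raise ValueError("history_window must be >= 1")
        A = dataset.A if A is None else np.asarray(A)
        n = dataset.n_units
        x_part = dataset.X[:, T - W:, :].reshape(n, -1)
        a_part = A[:, T - W:].astype(np.float64)
        blocks = [x_part, dataset.C, a_part]
        if self.interactions:
            hz = dataset.horizon_index()
            rows = np.arange(n)
            base = np.concatenate([dataset.X[rows, hz], dataset.C], axis=1)
            blocks.append(base * A[rows, hz][:, None])
        design = np.concatenate(blocks, axis=1)
        n_x, n_c = x_part.shape[1], dataset.C.shape[1]
        self.treatment_slice_ = slice(n_x + n_c, n_x + n_c + a_part.shape[1])
        return design

    def fit(self, dataset: LongitudinalDataset):
        design = self._design(dataset)
        self.model_ = Ridge(alpha=self.ridge_alpha)
        self.model_.fit(design, dataset.Y)
        self.coef_ = self.model_.coef_
        self.n_features_in_ = design.shape[1]
        return self

    def predict(self, dataset: LongitudinalDataset) -> np.ndarray:
        design = self._design(dataset)
        if design.shape[1] != self.n_features_in_:
            raise ValueError("feature count differs from the fitted window")
        return self.model_.predict(design)

    def predict_ite(self, dataset: LongitudinalDataset) -> ITEEstimates:
        ones = np.ones_like(dataset.A)
        zeros = np.zeros_like(dataset.A)
        y1 = self.model_.predict(self._design(dataset, A=ones))
        y0 = self.model_.predict(self._design(dataset, A=zeros))
        n = dataset.n_units
        p = np.full(n, 0.5)
        return ITEEstimates(y1_hat=y1, y0_hat=y0, ite_hat=y1 - y0,
                            propensity=p, weights=np.ones(n))
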