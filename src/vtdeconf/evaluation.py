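"""Evaluation metrics: factual RMSE, PEHE, and influence-function PEHE.

PEHE (precision in estimation of heterogeneous effects) is the mean squared
difference between true and predicted unit-level effects; it is reported
without a square root (the `root` option gives the rooted convention).  When
counterfactuals are unobserved, `if_pehe` estimates PEHE with a plug-in
effect from cross-fitted two-arm outcome regressions plus a first-order
influence-function correction driven by the estimated propensity.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import HistGradientBoostingRegressor
from sklearn.linear_model import LogisticRegression, Ridge

from .datasets import LongitudinalDataset

__all__ = ["MetricsReport", "rmse", "pehe", "if_pehe", "flatten_history",
           "evaluate_model"]


@dataclass
class MetricsReport:
    rmse: float
    pehe: float | None
    if_pehe: float | None
    n_units: int
    config: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {"rmse": self.rmse, "pehe": self.pehe, "if_pehe": self.if_pehe,
                "n_units": self.n_units, "config": self.config}


def rmse(y_pred, y_true) -> float:
    y_pred = np.asarray(y_pred, dtype=np.float64)
    y_true = np.asarray(y_true, dtype=np.float64)
    if y_pred.shape != y_true.shape:
        raise ValueError("length mismatch")
    if y_pred.size == 0:
        raise ValueError("empty input")
    return float(np.sqrt(np.mean((y_pred - y_true) ** 2)))


def pehe(ite_pred, ite_true, root: bool = False) -> float:
    """Mean squared difference between true and predicted effects."""
    ite_pred = np.asarray(ite_pred, dtype=np.float64)
    ite_true = np.asarray(ite_true, dtype=np.float64)
    if ite_pred.shape != ite_true.shape:
        raise ValueError("length mismatch")
    if ite_pred.size == 0:
        raise ValueError("empty input")
    value = float(np.mean((ite_true - ite_pred) ** 2))
    return float(np.sqrt(value)) if root else value


def _hash_folds(features: np.ndarray, y: np.ndarray, a: np.ndarray,
                n_folds: int) -> np.ndarray:
    """Fold labels from a content hash of each unit's row.

    Deterministic and invariant to the ordering of units (identical datasets
    in any permutation give every unit the same fold).
    """
    digests = []
    for i in range(features.shape[0]):
        h = hashlib.sha1()
        h.update(np.ascontiguousarray(features[i]).tobytes())
        h.update(np.float64(y[i]).tobytes())
        h.update(np.float64(a[i]).tobytes())
        digests.append(h.hexdigest())
    order = np.argsort(digests, kind="stable")
    folds = np.empty(len(digests), dtype=np.int64)
    folds[order] = np.arange(len(digests)) % n_folds
    return folds


def _make_regressor(kind: str, seed: int):
    if kind == "ridge":
        return Ridge(alpha=1e-3)
    if kind == "gbm":
        return HistGradientBoostingRegressor(random_state=seed, max_iter=100)
    raise ValueError(f"unknown nuisance kind {kind!r}")


def if_pehe(y_obs, a_obs, features, ite_pred, nuisance: str = "ridge",
            n_folds: int = 2, seed: int = 0, clip: float = 0.01,
            oracle_nuisances: dict | None = None) -> float:
    """Influence-function-corrected PEHE estimate without counterfactuals.

    A plug-in effect ``tau_plug = m1(x) - m0(x)`` comes from two-arm outcome
    regressions fitted on held-out folds (cross-fitting); the first-order
    correction re-weights the factual residual by ``(a - e(x)) / (e(x)(1 -
    e(x)))`` with propensities clipped to [clip, 1 - clip]:

        IF-PEHE = mean[ (tau_plug - tau_pred)^2
                        + 2 (tau_plug - tau_pred) * correction ]

    Pass `oracle_nuisances={"mu1": ..., "mu0": ..., "prop": ...}` (arrays) to
    bypass nuisance fitting, e.g. for validation against a synthetic oracle.
    """
    y = np.asarray(y_obs, dtype=np.float64)
    a = np.asarray(a_obs, dtype=np.float64)
    X = np.asarray(features, dtype=np.float64)
    tau_pred = np.asarray(ite_pred, dtype=np.float64)
    n = y.shape[0]
    if not (a.shape == (n,) and X.shape[0] == n and tau_pred.shape == (n,)):
        raise ValueError("inconsistent input shapes")
    if a.sum() == 0 or a.sum() == n:
        raise ValueError("need both treated and control units")

    if oracle_nuisances is not None:
        mu1 = np.asarray(oracle_nuisances["mu1"], dtype=np.float64)
        mu0 = np.asarray(oracle_nuisances["mu0"], dtype=np.float64)
        prop = np.asarray(oracle_nuisances["prop"], dtype=np.float64)
    else:
        mu1 = np.empty(n)
        mu0 = np.empty(n)
        prop = np.empty(n)
        folds = _hash_folds(X, y, a, n_folds)
        for fold in range(n_folds):
            test = folds == fold
            tr = ~test
            tr1 = tr & (a == 1)
            tr0 = tr & (a == 0)
            if tr1.sum() < 2 or tr0.sum() < 2:
                raise ValueError("a cross-fitting fold lacks one treatment arm")
            m1 = _make_regressor(nuisance, seed).fit(X[tr1], y[tr1])
            m0 = _make_regressor(nuisance, seed).fit(X[tr0], y[tr0])
            mu1[test] = m1.predict(X[test])
            mu0[test] = m0.predict(X[test])
            pm = LogisticRegression(max_iter=500, C=1.0)
            pm.fit(X[tr], a[tr])
            prop[test] = pm.predict_proba(X[test])[:, 1]
    prop = np.clip(prop, clip, 1.0 - clip)
    tau_plug = mu1 - mu0
    m_fact = np.where(a == 1, mu1, mu0)
    correction = (a - prop) / (prop * (1.0 - prop)) * (y - m_fact)
    diff = tau_plug - tau_pred
    return float(np.mean(diff ** 2 + 2.0 * diff * correction))


def flatten_history(dataset: LongitudinalDataset) -> np.ndarray:
    """Per-unit flattened (covariate history, statics, treatment history)."""
    n = dataset.n_units
    return np.concatenate(
        [dataset.X.reshape(n, -1), dataset.C,
         dataset.A.reshape(n, -1).astype(np.float64)], axis=1)


def evaluate_model(model, dataset: LongitudinalDataset,
                   nuisance: str = "ridge", seed: int = 0,
                   compute_if_pehe: bool = True) -> MetricsReport:
    """Factual RMSE, PEHE against the oracle when available, and IF-PEHE."""
    y_pred = model.predict(dataset)
    est = model.predict_ite(dataset)
    report_pehe = None
    ite_true = getattr(dataset, "ite_true", None)
    if ite_true is not None:
        report_pehe = pehe(est.ite_hat, ite_true)
    value_if = None
    if compute_if_pehe:
        feats = flatten_history(dataset)
        treated = dataset.treated_unit.astype(np.float64)
        value_if = if_pehe(dataset.Y, treated, feats, est.ite_hat,
                           nuisance=nuisance, seed=seed)
    cfg = getattr(model, "config_", None)
    return MetricsReport(
        rmse=rmse(y_pred, dataset.Y), pehe=report_pehe, if_pehe=value_if,
        n_units=dataset.n_units,
        config=cfg.to_dict() if cfg is not None else {})
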