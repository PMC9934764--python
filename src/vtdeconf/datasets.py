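"""In-memory containers for longitudinal treatment-outcome data.

A :class:`LongitudinalDataset` holds one unit (patient) per row: time-varying
covariates ``X``, a binary treatment process ``A``, per-step outcome targets
``y_seq`` (NaN where unsupervised), a horizon outcome ``Y``, static covariates
``C``, elapsed times ``dt`` between consecutive encounters, and a validity
mask for ragged/irregular sequences.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["LongitudinalDataset"]


@dataclass
class LongitudinalDataset:
    X: np.ndarray          # (N, T, p) time-varying covariates (proxies)
    A: np.ndarray          # (N, T) binary treatment indicators
    y_seq: np.ndarray      # (N, T) per-step outcome targets, NaN = unobserved
    Y: np.ndarray          # (N,) horizon outcome
    C: np.ndarray          # (N, d_static) static covariates
    dt: np.ndarray         # (N, T) elapsed time since previous encounter
    mask: np.ndarray       # (N, T) bool, True where the step is observed
    unit_ids: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=np.float64)
        self.A = np.asarray(self.A)
        self.y_seq = np.asarray(self.y_seq, dtype=np.float64)
        self.Y = np.asarray(self.Y, dtype=np.float64)
        self.C = np.asarray(self.C, dtype=np.float64)
        self.dt = np.asarray(self.dt, dtype=np.float64)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.unit_ids is None:
            self.unit_ids = np.arange(self.n_units)
        self.validate()

    # ------------------------------------------------------------------
    @property
    def n_units(self) -> int:
        return self.X.shape[0]

    @property
    def n_steps(self) -> int:
        return self.X.shape[1]

    @property
    def n_covariates(self) -> int:
        return self.X.shape[2]

    @property
    def n_static(self) -> int:
        return self.C.shape[1]

    def validate(self) -> None:
        n, t, _ = self.X.shape
        if self.A.shape != (n, t):
            raise ValueError(f"A has shape {self.A.shape}, expected {(n, t)}")
        if not np.isin(self.A[self.mask], (0, 1)).all():
            raise ValueError("treatment indicators must be binary")
        if self.Y.shape != (n,):
            raise ValueError(f"Y has shape {self.Y.shape}, expected {(n,)}")
        if self.C.shape[0] != n:
            raise ValueError("statics row count mismatch")
        if self.dt.shape != (n, t) or self.mask.shape != (n, t):
            raise ValueError("dt/mask shape mismatch")
        if not np.isfinite(self.Y).all():
            raise ValueError("horizon outcomes must be finite")
        if (self.dt[self.mask] < 0).any():
            raise ValueError("elapsed times must be nonnegative")

    # ------------------------------------------------------------------
    def subset(self, idx) -> "LongitudinalDataset":
        idx = np.asarray(idx)
        return LongitudinalDataset(
            X=self.X[idx], A=self.A[idx], y_seq=self.y_seq[idx], Y=self.Y[idx],
            C=self.C[idx], dt=self.dt[idx], mask=self.mask[idx],
            unit_ids=self.unit_ids[idx],
        )

    def horizon_index(self) -> np.ndarray:
        """Index of the last observed step per unit."""
        t = self.n_steps
        rev = self.mask[:, ::-1].argmax(axis=1)
        return t - 1 - rev

    @property
    def treated_unit(self) -> np.ndarray:
        """Boolean flag: the unit received treatment at some observed step."""
        return ((self.A == 1) & self.mask).any(axis=1)
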