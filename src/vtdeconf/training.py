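"""Dataset splitting and thin functional wrappers over the estimators."""

from __future__ import annotations

from typing import NamedTuple

import numpy as np

from .datasets import LongitudinalDataset
from .estimators import ITEEstimates, VTDRegressor
from .model import VTDConfig

__all__ = ["SplitResult", "split_dataset", "train", "estimate_ite"]


class SplitResult(NamedTuple):
    train: LongitudinalDataset
    val: LongitudinalDataset
    test: LongitudinalDataset
    manifest: dict


def split_dataset(dataset: LongitudinalDataset,
                  fractions=(0.8, 0.1, 0.1), seed: int = 0) -> SplitResult:
    """Unit-level disjoint train/val/test split with a recorded manifest."""
    fractions = tuple(float(f) for f in fractions)
    if len(fractions) != 3 or abs(sum(fractions) - 1.0) > 1e-8:
        raise ValueError("fractions must be three numbers summing to 1")
    n = dataset.n_units
    n_train = int(round(fractions[0] * n))
    n_val = int(round(fractions[1] * n))
    n_test = n - n_train - n_val
    if min(n_train, n_val, n_test) < 1:
        raise ValueError(f"too few units ({n}) for split fractions {fractions}")
    perm = np.random.default_rng(seed).permutation(n)
    idx_train = perm[:n_train]
    idx_val = perm[n_train:n_train + n_val]
    idx_test = perm[n_train + n_val:]
    manifest = {
        "seed": seed, "fractions": fractions,
        "train_units": np.sort(dataset.unit_ids[idx_train]).tolist(),
        "val_units": np.sort(dataset.unit_ids[idx_val]).tolist(),
        "test_units": np.sort(dataset.unit_ids[idx_test]).tolist(),
    }
    return SplitResult(dataset.subset(idx_train), dataset.subset(idx_val),
                       dataset.subset(idx_test), manifest)


def train(dataset: LongitudinalDataset, config: VTDConfig | None = None,
          val_dataset: LongitudinalDataset | None = None) -> VTDRegressor:
    """Fit a :class:`VTDRegressor` configured from a :class:`VTDConfig`."""
    config = config or VTDConfig()
    params = {k: v for k, v in config.to_dict().items() if k != "seed"}
    est = VTDRegressor(random_state=config.seed, **params)
    return est.fit(dataset, val_dataset=val_dataset)


def estimate_ite(model: VTDRegressor, dataset: LongitudinalDataset) -> ITEEstimates:
    """Deterministic two-arm potential-outcome contrast at the horizon."""
    return model.predict_ite(dataset)
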