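"""Delimited-text readers/writers and run manifests.

On disk a dataset is a directory of UTF-8 CSV files with header rows:

* ``longitudinal.csv`` — one row per (unit, step): ``unit_id, t, delta_t,
  x_1..x_p, a, y`` (``y`` may be empty at unsupervised steps);
* ``statics.csv`` — one row per unit: ``unit_id, c_1..c_d``;
* ``hidden.csv`` (synthetic only) — ``unit_id, t, z_1..z_r``;
* ``ite.csv`` (synthetic only) — ``unit_id, ite_true``;
* ``manifest.json`` — full generating/processing configuration, seeds,
  package version and file digests.

Rows may arrive in any order; the reader sorts by (unit_id, t), compacts
gaps in ``t`` into elapsed times and flags missing steps in the mask.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .datasets import LongitudinalDataset

__all__ = ["write_dataset", "read_dataset", "write_manifest", "file_digest"]


def file_digest(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_manifest(outdir, config: dict, seeds: dict, outputs: list[str]) -> Path:
    outdir = Path(outdir)
    manifest = {
        "package": "vtdeconf",
        "version": __version__,
        "config": config,
        "seeds": seeds,
        "outputs": sorted(outputs),
        "digests": {name: file_digest(outdir / name) for name in outputs
                    if (outdir / name).exists()},
        "wall_clock": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=str))
    return path


def write_dataset(dataset: LongitudinalDataset, outdir,
                  config: dict | None = None, seeds: dict | None = None) -> Path:
    """Write the dataset tables plus a manifest; returns the directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    n, t, p = dataset.X.shape
    rows = []
    # absolute time index reconstructed from elapsed times
    t_abs = np.cumsum(dataset.dt, axis=1) - dataset.dt[:, :1] + 1
    for i in range(n):
        for s in range(t):
            if not dataset.mask[i, s]:
                continue
            y_val = dataset.y_seq[i, s]
            rows.append([dataset.unit_ids[i], int(t_abs[i, s]),
                         dataset.dt[i, s], *dataset.X[i, s],
                         int(dataset.A[i, s]),
                         "" if not np.isfinite(y_val) else y_val])
    cols = ["unit_id", "t", "delta_t", *[f"x_{j+1}" for j in range(p)], "a", "y"]
    pd.DataFrame(rows, columns=cols).to_csv(outdir / "longitudinal.csv", index=False)

    stat = pd.DataFrame(dataset.C,
                        columns=[f"c_{j+1}" for j in range(dataset.C.shape[1])])
    stat.insert(0, "unit_id", dataset.unit_ids)
    stat.to_csv(outdir / "statics.csv", index=False)

    outputs = ["longitudinal.csv", "statics.csv"]
    Z = getattr(dataset, "Z", None)
    if Z is not None:
        zrows = []
        for i in range(n):
            for s in range(t):
                if dataset.mask[i, s]:
                    zrows.append([dataset.unit_ids[i], int(t_abs[i, s]), *Z[i, s]])
        zcols = ["unit_id", "t", *[f"z_{j+1}" for j in range(Z.shape[2])]]
        pd.DataFrame(zrows, columns=zcols).to_csv(outdir / "hidden.csv", index=False)
        ite = pd.DataFrame({"unit_id": dataset.unit_ids,
                            "ite_true": dataset.ite_true})
        ite.to_csv(outdir / "ite.csv", index=False)
        outputs += ["hidden.csv", "ite.csv"]
    write_manifest(outdir, config or {}, seeds or {}, outputs)
    return outdir


def _fail_rows(frame: pd.DataFrame, bad: np.ndarray, message: str):
    rows = (frame.index[bad] + 2).tolist()[:10]  # 1-based with header line
    raise ValueError(f"{message} (file rows {rows})")


def read_dataset(path) -> LongitudinalDataset:
    """Read a dataset directory written by :func:`write_dataset`.

    Rows are sorted by (unit_id, t); gaps in ``t`` become elapsed time and
    sequences shorter than the longest one are masked out at the tail.
    """
    path = Path(path)
    frame = pd.read_csv(path / "longitudinal.csv")
    required = {"unit_id", "t", "delta_t", "a"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"longitudinal table lacks columns {sorted(missing)}")
    x_cols = sorted([c for c in frame.columns if c.startswith("x_")],
                    key=lambda c: int(c.split("_")[1]))
    num_cols = ["t", "delta_t", "a", *x_cols] + (["y"] if "y" in frame else [])
    for col in num_cols:
        converted = pd.to_numeric(frame[col], errors="coerce")
        bad = converted.isna() & frame[col].notna()
        if bad.any():
            _fail_rows(frame, bad.to_numpy(), f"nonnumeric values in column {col!r}")
        frame[col] = converted
    bad_a = ~frame["a"].isin([0, 1])
    if bad_a.any():
        _fail_rows(frame, bad_a.to_numpy(), "treatment indicator a must be 0 or 1")
    dup = frame.duplicated(subset=["unit_id", "t"], keep=False)
    if dup.any():
        _fail_rows(frame, dup.to_numpy(), "duplicate (unit_id, t) pairs")
    frame = frame.sort_values(["unit_id", "t"], kind="stable")

    statics = pd.read_csv(path / "statics.csv")
    c_cols = sorted([c for c in statics.columns if c.startswith("c_")],
                    key=lambda c: int(c.split("_")[1]))
    statics = statics.set_index("unit_id")

    units = frame["unit_id"].unique()
    t_max = int(frame.groupby("unit_id").size().max())
    n, p = len(units), len(x_cols)
    X = np.zeros((n, t_max, p))
    A = np.zeros((n, t_max), dtype=np.int64)
    y_seq = np.full((n, t_max), np.nan)
    dt = np.ones((n, t_max))
    mask = np.zeros((n, t_max), dtype=bool)
    Y = np.zeros(n)
    C = np.zeros((n, len(c_cols)))
    for i, uid in enumerate(units):
        g = frame[frame["unit_id"] == uid]
        k = len(g)
        X[i, :k] = g[x_cols].to_numpy()
        A[i, :k] = g["a"].to_numpy()
        if "y" in g:
            y_seq[i, :k] = g["y"].to_numpy()
        t_vals = g["t"].to_numpy(dtype=np.float64)
        dt[i, :k] = np.diff(t_vals, prepend=t_vals[0] - 1.0)
        mask[i, :k] = True
        last_y = y_seq[i, :k][np.isfinite(y_seq[i, :k])]
        Y[i] = last_y[-1] if last_y.size else np.nan
        if uid in statics.index:
            C[i] = statics.loc[uid, c_cols].to_numpy()
    if not np.isfinite(Y).all():
        missing_units = units[~np.isfinite(Y)][:10].tolist()
        raise ValueError(f"no observed outcome for units {missing_units}")
    ds = LongitudinalDataset(X=X, A=A, y_seq=y_seq, Y=Y, C=C, dt=dt,
                             mask=mask, unit_ids=units)
    ite_path = path / "ite.csv"
    if ite_path.exists():
        ite = pd.read_csv(ite_path).set_index("unit_id")
        ds.ite_true = ite.loc[units, "ite_true"].to_numpy()
    return ds
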