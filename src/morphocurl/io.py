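"""Rollout trace persistence: HDF5 groups plus CSV summaries."""

from __future__ import annotations

from pathlib import Path
from typing import Dict, Optional

import h5py
import numpy as np
import pandas as pd


def write_rollout(path, arrays: Dict[str, np.ndarray], attrs: Optional[Dict] = None,
                  events: Optional[list] = None) -> None:
    """Write time-series arrays (states, observations, actions, rewards, ...)
    as HDF5 datasets, with scalar metadata as root attributes and events as
    a string dataset."""
    with h5py.File(path, "w") as f:
        for k, v in arrays.items():
            f.create_dataset(k, data=np.asarray(v))
        for k, v in (attrs or {}).items():
            f.attrs[k] = v
        if events:
            f.create_dataset("events", data=np.array(events, dtype="S64"))


def read_rollout(path) -> Dict[str, np.ndarray]:
    out: Dict[str, np.ndarray] = {}
    with h5py.File(path, "r") as f:
        for k in f.keys():
            out[k] = f[k][...]
        out["_attrs"] = dict(f.attrs)
    return out


def rollout_summary_csv(path, arrays: Dict[str, np.ndarray]) -> None:
    """One-row CSV of per-trace summary statistics (mean/min/max)."""
    row = {}
    for k, v in arrays.items():
        v = np.asarray(v, dtype=float).ravel()
        if v.size:
            row[f"{k}_mean"] = v.mean()
            row[f"{k}_min"] = v.min()
            row[f"{k}_max"] = v.max()
    pd.DataFrame([row]).to_csv(path, index=False)
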