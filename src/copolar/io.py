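"""Output serialization: trajectory tables, field snapshots, kymographs."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Sequence

import h5py
import numpy as np
import pandas as pd

from .model import Trajectory

__all__ = ["write_trajectory", "write_snapshots", "export_kymograph",
           "write_manifest"]


def write_trajectory(traj: Trajectory, path) -> None:
    """Tidy CSV of (time, cell, axis_angle_deg, polarized)."""
    traj.to_frame().to_csv(path, index=False)


def write_snapshots(traj: Trajectory, path) -> None:
    """Full field snapshots as an HDF5 container.

    Datasets: times, a, b (densities) and rac, rho (binned bound counts),
    each of shape (n_snapshots, n_cells, n_grid).
    """
    if traj.snapshots is None:
        raise ValueError("trajectory carries no snapshots "
                         "(pass snapshot_stride to simulate_group)")
    with h5py.File(path, "w") as f:
        for key, arr in traj.snapshots.items():
            f.create_dataset(key, data=np.asarray(arr))
        f.attrs["n_cells"] = traj.n_cells


def export_kymograph(trajectories: Sequence[Trajectory],
                     out_array: Optional[str] = None,
                     out_csv: Optional[str] = None) -> dict:
    """Space-time arrays of the fields and GTPase counts.

    Stacks the snapshot series of one or more realizations and averages
    over them (a single trajectory yields itself).  Returns a dict of
    arrays of shape (n_times, n_cells, n_grid): a, b, rac, rho, plus times.
    Optionally writes an ``.npz`` and/or a long-form CSV.
    """
    if not trajectories:
        raise ValueError("no trajectories given")
    for tr in trajectories:
        if tr.snapshots is None:
            raise ValueError("all trajectories must carry snapshots")
    t0 = trajectories[0].snapshots["times"]
    for tr in trajectories[1:]:
        if not np.array_equal(tr.snapshots["times"], t0):
            raise ValueError("trajectories must share snapshot times")
    out = {"times": np.asarray(t0)}
    for key in ("a", "b", "rac", "rho"):
        out[key] = np.mean([tr.snapshots[key] for tr in trajectories], axis=0)
    if out_array:
        np.savez_compressed(out_array, **out)
    if out_csv:
        n_t, n_cells, n_grid = out["a"].shape
        frames = []
        for key in ("a", "b", "rac", "rho"):
            arr = out[key]
            idx = np.indices((n_t, n_cells, n_grid))
            frames.append(pd.DataFrame({
                "time": out["times"][idx[0].ravel()],
                "cell": idx[1].ravel(), "site": idx[2].ravel(),
                "field": key, "value": arr.ravel()}))
        pd.concat(frames, ignore_index=True).to_csv(out_csv, index=False)
    return out


def write_manifest(path, config_dict: dict, seeds, version: str) -> None:
    """JSON manifest describing one run directory (config, seeds, version)."""
    Path(path).write_text(json.dumps(
        {"config": config_dict, "seeds": list(map(int, seeds)),
         "version": version}, indent=2, default=str))
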