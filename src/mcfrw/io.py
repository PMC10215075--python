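"""Trajectory and results persistence.

One compressed array container per trajectory (positions plus metadata),
a CSV exporter for spreadsheets and an XYZ exporter for molecular
viewers.  Geometry serialization lives in :mod:`mcfrw.geometry`.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .walker import Trajectory

__all__ = [
    "save_trajectory",
    "load_trajectory",
    "trajectory_path",
    "trajectory_to_csv",
    "trajectory_to_xyz",
    "save_quote_reports",
]


def trajectory_path(out_dir, index: int) -> Path:
    return Path(out_dir) / f"traj_{index:05d}.npz"


def save_trajectory(traj: Trajectory, path):
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    meta = {
        "delta_t": traj.delta_t,
        "seed": traj.seed,
        "n_steps": traj.n_steps,
        "n_rejections": traj.n_rejections,
        "status": traj.status,
        "record_stride": traj.record_stride,
        "base_delta_t": traj.base_delta_t,
        "stop_L": traj.stop_L,
    }
    np.savez_compressed(path, positions=traj.positions,
                        meta=np.bytes_(json.dumps(meta).encode()))


def load_trajectory(path) -> Trajectory:
    with np.load(path) as data:
        meta = json.loads(bytes(data["meta"]).decode())
        positions = data["positions"]
    return Trajectory(positions=positions, **meta)


def trajectory_to_csv(traj: Trajectory, path):
    """Columns: step, t_s, W_nm, T_nm, L_nm."""
    n = len(traj)
    df = pd.DataFrame({
        "step": np.arange(n) * traj.record_stride,
        "t_s": np.arange(n) * traj.delta_t,
        "W_nm": traj.positions[:, 0],
        "T_nm": traj.positions[:, 1],
        "L_nm": traj.positions[:, 2],
    })
    df.to_csv(path, index=False)


def trajectory_to_xyz(traj: Trajectory, path, element: str = "O"):
    with open(path, "w") as fh:
        fh.write(f"{len(traj)}\nwater random walk, positions in nm\n")
        for x, y, z in traj.positions:
            fh.write(f"{element} {x:.4f} {y:.4f} {z:.4f}\n")


def save_quote_reports(reports, summary_path, per_trajectory_path=None):
    """Write the per-quote summary CSV and optionally the full table."""
    from .analysis import quote_summary_table

    quote_summary_table(reports).to_csv(summary_path, index=False)
    if per_trajectory_path is not None:
        tables = [r.per_trajectory for r in reports if len(r.per_trajectory)]
        if tables:
            pd.concat(tables, ignore_index=True).to_csv(
                per_trajectory_path, index=False)
        else:
            pd.DataFrame(columns=["trajectory_id", "quote_L_nm", "tortuosity",
                                  "D_m2_per_s", "beta0", "beta1", "r2",
                                  "n_points"]).to_csv(
                per_trajectory_path, index=False)
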