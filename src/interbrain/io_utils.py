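"""CSV/JSON/NPZ serialization of trajectories, signals and sweep outputs."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .model_core import PhaseTrajectory
from .observables import TimeSeries

__all__ = [
    "write_timeseries_csv",
    "read_timeseries_csv",
    "write_trajectory_csv",
    "write_trajectory_npz",
    "read_trajectory_npz",
    "write_heatmap_csv",
    "read_heatmap_csv",
    "write_ztable",
]


def write_timeseries_csv(ts: TimeSeries, path: str | Path) -> None:
    """Wide layout: a time column plus one column per channel."""
    df = pd.DataFrame({"time_s": ts.times})
    for lab, row in zip(ts.labels, ts.values):
        df[lab] = row
    df.to_csv(path, index=False, float_format="%.12g")


def read_timeseries_csv(path: str | Path) -> TimeSeries:
    df = pd.read_csv(path)
    times = df.pop("time_s").to_numpy()
    if len(times) < 2:
        raise ValueError("time series must have at least two samples")
    fs = 1.0 / (times[1] - times[0])
    return TimeSeries(
        values=df.to_numpy().T, sampling_rate_hz=float(fs), labels=tuple(df.columns)
    )


def write_trajectory_csv(traj: PhaseTrajectory, path: str | Path) -> None:
    """Long layout: one (time, oscillator, phase) row per sample."""
    n, T = traj.phases.shape
    df = pd.DataFrame(
        {
            "time_s": np.repeat(traj.times, n),
            "oscillator": np.tile(np.asarray(traj.labels), T),
            "phase_rad": traj.phases.T.ravel(),
        }
    )
    df.to_csv(path, index=False, float_format="%.12g")


def write_trajectory_npz(traj: PhaseTrajectory, path: str | Path, metadata: dict | None = None) -> None:
    """Compressed array container with a JSON sidecar for the metadata."""
    path = Path(path)
    np.savez_compressed(
        path, phases=traj.phases, times=traj.times, omega=traj.omega,
        labels=np.asarray(traj.labels),
    )
    if metadata is not None:
        path.with_suffix(".json").write_text(json.dumps(metadata, indent=2, sort_keys=True) + "\n")


def read_trajectory_npz(path: str | Path) -> PhaseTrajectory:
    with np.load(path) as dat:
        return PhaseTrajectory(
            phases=dat["phases"], times=dat["times"], omega=dat["omega"],
            labels=tuple(str(x) for x in dat["labels"]),
        )


def write_heatmap_csv(heatmap: pd.DataFrame, path: str | Path) -> None:
    """Rows = CFC levels, columns = theta-IBC levels, both labeled."""
    heatmap.to_csv(path, float_format="%.12g")


def read_heatmap_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, index_col=0)
    df.columns = df.columns.astype(float)
    df.columns.name = "theta_ibc"
    df.index.name = "cfc"
    return df


def write_ztable(table: pd.DataFrame, csv_path: str | Path, json_path: str | Path | None = None) -> None:
    table.to_csv(csv_path, index=False, float_format="%.12g")
    if json_path is not None:
        Path(json_path).write_text(table.to_json(orient="records", indent=2) + "\n")
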