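"""On-disk formats: trajectory CSV files, the cohort table and the manifest.

A simulated (or recorded) data set is a directory::

    <data_dir>/
      manifest.yaml            # generator config, seed, config hash
      cohort.csv               # one row per patient
      trajectories/
        P001_A.csv             # columns t, x, y, vx, vy (SI units)
        P001_B.csv
        ...

All files are plain text; two runs with an identical config produce
byte-identical data files.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .kinematics import DIRECTIONS, Trajectory
from .synthetic import Cohort, GeneratorConfig

__all__ = [
    "config_hash",
    "write_trajectory",
    "read_trajectory",
    "write_cohort",
    "load_cohort",
]

_FLOAT_FORMAT = "%.9g"


def config_hash(config: GeneratorConfig) -> str:
    """Stable short hash of a generator configuration."""
    canonical = json.dumps(config.to_dict(), sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def write_trajectory(traj: Trajectory, path: Path | str) -> None:
    """Write one movement as a CSV with columns t, x, y, vx, vy."""
    tr = traj
    frame = pd.DataFrame({"t": tr.t, "x": tr.x, "y": tr.y})
    if tr.has_velocities:
        frame["vx"] = tr.vx
        frame["vy"] = tr.vy
    frame.to_csv(path, index=False, float_format=_FLOAT_FORMAT)


def read_trajectory(
    path: Path | str,
    direction: str,
    side: str,
    sample_rate: float | None = None,
) -> Trajectory:
    """Read a movement CSV; velocity columns are optional."""
    frame = pd.read_csv(path)
    for col in ("t", "x", "y"):
        if col not in frame.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    has_v = "vx" in frame.columns and "vy" in frame.columns
    return Trajectory(
        t=frame["t"].to_numpy(float),
        x=frame["x"].to_numpy(float),
        y=frame["y"].to_numpy(float),
        direction=direction,
        side=side,
        vx=frame["vx"].to_numpy(float) if has_v else None,
        vy=frame["vy"].to_numpy(float) if has_v else None,
        sample_rate=sample_rate,
    )


def write_cohort(cohort: Cohort, out_dir: Path | str) -> Path:
    """Write a cohort to a data directory; returns the directory path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort.table.to_csv(out / "cohort.csv", index=False, float_format=_FLOAT_FORMAT)

    manifest = {
        "config": cohort.config.to_dict(),
        "config_hash": config_hash(cohort.config),
        "seed": cohort.config.seed,
        "n_patients": cohort.n,
        "has_trajectories": bool(cohort.trajectories),
    }
    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)

    if cohort.trajectories:
        traj_dir = out / "trajectories"
        traj_dir.mkdir(exist_ok=True)
        for (pid, direction), traj in sorted(cohort.trajectories.items()):
            write_trajectory(traj, traj_dir / f"{pid}_{direction}.csv")
    return out


def load_cohort(data_dir: Path | str) -> Cohort:
    """Load a cohort directory written by :func:`write_cohort`."""
    data = Path(data_dir)
    manifest_path = data / "manifest.yaml"
    table_path = data / "cohort.csv"
    if not table_path.exists():
        raise FileNotFoundError(f"no cohort table at {table_path}")
    with open(manifest_path) as fh:
        manifest = yaml.safe_load(fh)
    config = GeneratorConfig.from_dict(manifest["config"])
    table = pd.read_csv(table_path)

    trajectories: dict[tuple[str, str], Trajectory] = {}
    traj_dir = data / "trajectories"
    if traj_dir.is_dir():
        sides = dict(zip(table["id"], table["side"]))
        for pid, side in sides.items():
            for direction in DIRECTIONS:
                path = traj_dir / f"{pid}_{direction}.csv"
                if path.exists():
                    trajectories[(pid, direction)] = read_trajectory(
                        path, direction, side, sample_rate=config.sample_rate
                    )
    return Cohort(table=table, trajectories=trajectories, config=config)
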