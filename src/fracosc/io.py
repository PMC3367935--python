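"""Serialization: trajectory CSV + JSON sidecars, scan tables, run configs."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Optional

import numpy as np
import pandas as pd
import yaml

from .grids import TimeGrid, Trajectory

__all__ = ["write_trajectory", "read_trajectory", "read_series",
           "RunConfig", "write_json"]


def write_trajectory(traj: Trajectory, path) -> Path:
    """Write a trajectory as CSV (`t,x[,y,z]`, full double precision) plus a
    JSON metadata sidecar (`<stem>.meta.json`) holding the solver echo."""
    path = Path(path)
    cols = {"t": traj.times}
    for i, lab in enumerate(traj.labels):
        cols[lab] = traj.states[:, i]
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.17g")
    meta = dict(traj.meta)
    meta["blown_up"] = traj.blown_up
    meta["labels"] = list(traj.labels)
    write_json(meta, path.with_suffix(".meta.json"))
    return path


def read_trajectory(path) -> Trajectory:
    """Read a trajectory CSV (and its sidecar, if present) back into memory."""
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    t = df["t"].to_numpy()
    if t.size < 2:
        raise ValueError("trajectory file must contain at least two samples")
    h = t[1] - t[0]
    if not np.allclose(np.diff(t), h, rtol=1e-9, atol=1e-12):
        raise ValueError("trajectory grid is not uniform")
    labels = [c for c in df.columns if c != "t"]
    meta: Mapping[str, Any] = {}
    blown = False
    sidecar = path.with_suffix(".meta.json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        blown = bool(meta.pop("blown_up", False))
        meta.pop("labels", None)
    grid = TimeGrid(h=float(h), n_steps=t.size - 1)
    return Trajectory(grid=grid, states=df[labels].to_numpy(), labels=tuple(labels),
                      meta=meta, blown_up=blown)


def read_series(path) -> tuple[np.ndarray, float]:
    """Read a scalar series from a single-column or `t,x` CSV.

    Returns ``(values, sample_period)``; the period is 1.0 when no time
    column is present.
    """
    df = pd.read_csv(Path(path), float_precision="round_trip")
    if df.shape[1] == 1:
        return df.iloc[:, 0].to_numpy(dtype=float), 1.0
    t = df.iloc[:, 0].to_numpy(dtype=float)
    x = df.iloc[:, 1].to_numpy(dtype=float)
    if t.size < 2:
        raise ValueError("series must contain at least two samples")
    return x, float(t[1] - t[0])


def write_json(obj, path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(obj, indent=2, default=_jsonify) + "\n")
    return path


def _jsonify(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


@dataclass
class RunConfig:
    """Reproducible description of one CLI run (echoed next to every output)."""

    model: str = "goodwin-frac-delay"
    params: dict = field(default_factory=dict)
    t_end: float = 500.0
    h: float = 0.01
    method: str = "abm"
    analyses: list = field(default_factory=lambda: ["classify"])
    outdir: str = "."
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.__dict__, sort_keys=False))
        return path
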