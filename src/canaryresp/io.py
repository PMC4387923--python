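"""Trajectory/trace file formats and run configuration.

Trajectories are written as plain CSV (column order
``t_ms,e_er,i_er,e_ra,i_ra,F,Fd,Fd2``) with a commented header block that
records the preset name, parameters and step, at full double precision so a
round trip is lossless.  Recorded air-sac pressure series (arbitrary units,
possibly non-uniformly sampled) are read with configurable column names,
resampled to a uniform grid and optionally min–max normalised to [0, 1] so
they can be fed to the feature operators.

Run configurations round-trip through YAML; unknown keys and out-of-range
values are rejected at parse time.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .model import ModelParams
from .simulate import Trajectory

__all__ = [
    "write_trajectory",
    "read_trajectory",
    "read_pressure_series",
    "SampledTrace",
    "RunConfig",
]

_COLUMNS = ["t_ms", "e_er", "i_er", "e_ra", "i_ra", "F", "Fd", "Fd2"]


def write_trajectory(trajectory: Trajectory, path) -> None:
    """Write a trajectory to ``path`` as commented-header CSV."""
    path = Path(path)
    meta = {k: v for k, v in trajectory.meta.items()}
    try:
        with path.open("w") as fh:
            fh.write(f"# canaryresp trajectory\n# meta: {json.dumps(meta)}\n")
            fh.write(",".join(_COLUMNS) + "\n")
            data = np.column_stack(
                [trajectory.times, trajectory.states, trajectory.drive_trace]
            )
            for row in data:
                fh.write(",".join(f"{v:.17g}" for v in row) + "\n")
    except OSError as exc:
        raise OSError(f"cannot write trajectory to {path}: {exc}") from exc


def read_trajectory(path) -> Trajectory:
    """Read a trajectory written by :func:`write_trajectory` (lossless)."""
    path = Path(path)
    meta: dict = {}
    with path.open() as fh:
        header_lines = []
        for line in fh:
            if line.startswith("#"):
                header_lines.append(line)
            else:
                break
    for line in header_lines:
        if line.startswith("# meta:"):
            meta = json.loads(line[len("# meta:"):])
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    if len(df) == 0:
        times = np.empty(0)
        return Trajectory(times, np.empty((0, 4)), np.empty((0, 3)), meta)
    return Trajectory(
        times=df["t_ms"].to_numpy(),
        states=df[["e_er", "i_er", "e_ra", "i_ra"]].to_numpy(),
        drive_trace=df[["F", "Fd", "Fd2"]].to_numpy(),
        meta=meta,
    )


@dataclass
class SampledTrace:
    """A uniformly sampled scalar trace (times in ms)."""

    times: np.ndarray
    values: np.ndarray

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])

    @property
    def t0(self) -> float:
        return float(self.times[0])


def read_pressure_series(
    path,
    time_column: str = "t_ms",
    value_column: str = "pressure",
    normalize: bool = False,
) -> SampledTrace:
    """Read a delimited pressure time series onto a uniform grid.

    Non-uniformly sampled input is linearly resampled to its median step.
    With ``normalize=True`` the amplitude is min–max scaled to [0, 1]
    (recorded pressure units are arbitrary).
    """
    path = Path(path)
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    for col in (time_column, value_column):
        if col not in df.columns:
            raise ValueError(f"{path}: column {col!r} not found (have {list(df.columns)})")
    t = pd.to_numeric(df[time_column], errors="coerce").to_numpy(float)
    y = pd.to_numeric(df[value_column], errors="coerce").to_numpy(float)
    if np.isnan(t).any() or np.isnan(y).any():
        raise ValueError(f"{path}: non-numeric cells in {time_column!r}/{value_column!r}")
    if len(t) < 3:
        raise ValueError(f"{path}: need at least 3 rows, got {len(t)}")
    order = np.argsort(t)
    t, y = t[order], y[order]
    steps = np.diff(t)
    if np.any(steps <= 0):
        raise ValueError(f"{path}: duplicate time points")
    dt = float(np.median(steps))
    if not np.allclose(steps, dt, rtol=1e-9, atol=1e-12):
        n = int(np.floor((t[-1] - t[0]) / dt)) + 1
        grid = t[0] + dt * np.arange(n)
        y = np.interp(grid, t, y)
        t = grid
    if normalize:
        lo, hi = float(y.min()), float(y.max())
        if hi > lo:
            y = (y - lo) / (hi - lo)
        else:
            y = np.zeros_like(y)
    return SampledTrace(times=t, values=y)


_VALID_PATTERNS = ("P0", "pulsatile", "P2", "P1")
_SCHEDULE_KEYS = {
    "f_onset", "d_total", "segment_duration", "fd_width", "fd2_width", "amplitude",
}
_SIM_KEYS = {"t0", "t_end", "dt", "initial"}


@dataclass
class RunConfig:
    """One simulation run: preset (or explicit parameters) + overrides."""

    preset: Optional[str] = None
    params: Optional[dict] = None
    schedule: dict = field(default_factory=dict)
    sim: dict = field(default_factory=dict)
    output: Optional[str] = None
    extract_features: bool = False

    def __post_init__(self) -> None:
        if self.preset is None and self.params is None:
            raise ValueError("RunConfig: either preset or params is required")
        if self.preset is not None and self.preset not in _VALID_PATTERNS:
            raise ValueError(f"RunConfig: unknown preset {self.preset!r}")
        if self.params is not None:
            ModelParams.from_dict(self.params)  # validates keys/values
        bad = set(self.schedule) - _SCHEDULE_KEYS
        if bad:
            raise ValueError(f"RunConfig.schedule: unknown keys {sorted(bad)}")
        bad = set(self.sim) - _SIM_KEYS
        if bad:
            raise ValueError(f"RunConfig.sim: unknown keys {sorted(bad)}")
        if "dt" in self.sim and not (0 < self.sim["dt"] <= 1.0):
            raise ValueError("RunConfig.sim: dt must lie in (0, 1]")
        for key in ("fd_width", "fd2_width"):
            if self.schedule.get(key) is not None and self.schedule[key] <= 0:
                raise ValueError(f"RunConfig.schedule: {key} must be > 0")
        if self.schedule.get("amplitude", 10.0) < 0:
            raise ValueError("RunConfig.schedule: amplitude must be >= 0")

    def to_dict(self) -> dict:
        return {
            "preset": self.preset,
            "params": self.params,
            "schedule": dict(self.schedule),
            "sim": dict(self.sim),
            "output": self.output,
            "extract_features": self.extract_features,
        }

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {"preset", "params", "schedule", "sim", "output", "extract_features"}
        bad = set(d) - known
        if bad:
            raise ValueError(f"RunConfig: unknown keys {sorted(bad)}")
        return cls(**{k: v for k, v in d.items() if v is not None or k in ("preset", "params", "output")})

    @classmethod
    def from_yaml(cls, source) -> "RunConfig":
        if isinstance(source, (str, Path)) and "\n" not in str(source):
            text = Path(source).read_text()
        else:
            text = str(source)
        data = yaml.safe_load(text)
        if not isinstance(data, dict):
            raise ValueError("RunConfig: YAML document must be a mapping")
        return cls.from_dict(data)
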