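"""Trajectory containers, CSV I/O, resampling, and grid quantization.

A trajectory is the time-stamped 2D path of one individual under one
tracking condition.  All downstream analyses (kinematics, diffusion,
survival, step-length fitting) consume :class:`Trajectory` objects.

Units are seconds and millimetres throughout; the CSV reader converts
from other units when a config declares them.
"""

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

#: conversion factors into the canonical units (s, mm)
_TIME_FACTORS = {"s": 1.0, "ms": 1e-3, "min": 60.0, "h": 3600.0}
_LENGTH_FACTORS = {"mm": 1.0, "cm": 10.0, "m": 1000.0, "um": 1e-3}

_CSV_COLUMNS = ("id", "condition", "t", "x", "y")


class TrajectoryFormatError(ValueError):
    """Raised when an input file does not match the trajectory CSV contract."""


@dataclass
class Trajectory:
    """Time-stamped 2D path of a single individual.

    Parameters
    ----------
    individual_id : str
        Opaque label for the animal (or simulated walker).
    condition : str
        Opaque tracking-condition label, e.g. ``servosphere``,
        ``small_arena``, ``large_arena`` or a walker kind.
    times : ndarray
        Sample times in seconds, strictly increasing.
    xs, ys : ndarray
        Positions in millimetres, same length as ``times``.
    fps_nominal : float or None
        Nominal sampling rate of the recording, frames per second.
    """

    individual_id: str
    condition: str
    times: np.ndarray
    xs: np.ndarray
    ys: np.ndarray
    fps_nominal: float | None = None

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.xs = np.asarray(self.xs, dtype=float)
        self.ys = np.asarray(self.ys, dtype=float)
        n = len(self.times)
        if n < 2:
            raise ValueError("a trajectory needs at least 2 samples")
        if len(self.xs) != n or len(self.ys) != n:
            raise ValueError("times, xs, ys must have equal length")
        if not (np.isfinite(self.times).all() and np.isfinite(self.xs).all()
                and np.isfinite(self.ys).all()):
            raise ValueError("trajectory contains non-finite values")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.times)

    @property
    def duration(self) -> float:
        """Elapsed time from first to last sample, seconds."""
        return float(self.times[-1] - self.times[0])

    @property
    def fps_estimated(self) -> float:
        """Mean sampling rate implied by the timestamps."""
        return (len(self.times) - 1) / self.duration


@dataclass(frozen=True)
class GridSpec:
    """Square lattice used to discretize hand-recorded arena positions.

    ``spacing`` is the cell side in mm (the field protocol used a printed
    20 mm grid); ``origin`` anchors the lower-left corner of cell (0, 0).
    Cells are half-open ``[k*s, (k+1)*s)`` so each point belongs to
    exactly one cell.
    """

    spacing: float = 20.0
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self):
        if self.spacing <= 0:
            raise ValueError("grid spacing must be positive")


def read_config(path) -> dict:
    """Read a flat key-value YAML config (units, grid spacing, FPS targets)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise TrajectoryFormatError("config must be a flat mapping")
    return cfg


def read_trajectories(path, column_map: dict | None = None,
                      time_unit: str = "s", length_unit: str = "mm",
                      fps_nominal: float | None = None) -> list[Trajectory]:
    """Read trajectories from CSV, one per distinct (individual, condition).

    The expected columns are ``id,condition,t,x,y`` (header required);
    ``column_map`` renames file columns onto these canonical names, e.g.
    ``{"track": "id"}``. Non-finite rows are dropped with a logged count;
    individuals with fewer than 2 usable rows are skipped with a warning.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    if column_map:
        df = df.rename(columns=column_map)
    missing = [c for c in _CSV_COLUMNS if c not in df.columns]
    if missing:
        raise TrajectoryFormatError(
            f"{path}: missing required column(s) {missing}; "
            f"expected {list(_CSV_COLUMNS)}")

    tf = _TIME_FACTORS[time_unit]
    lf = _LENGTH_FACTORS[length_unit]

    out: list[Trajectory] = []
    for (iid, cond), grp in df.groupby(["id", "condition"], sort=True):
        grp = grp.sort_values("t")
        vals = grp[["t", "x", "y"]].to_numpy(dtype=float)
        ok = np.isfinite(vals).all(axis=1)
        n_bad = int((~ok).sum())
        if n_bad:
            logger.warning("%s/%s: dropped %d non-finite row(s)", iid, cond, n_bad)
        vals = vals[ok]
        if len(vals) < 2:
            logger.warning("%s/%s: fewer than 2 usable rows, skipped", iid, cond)
            continue
        out.append(Trajectory(str(iid), str(cond),
                              vals[:, 0] * tf, vals[:, 1] * lf, vals[:, 2] * lf,
                              fps_nominal=fps_nominal))
    return out


def write_trajectories(trajectories, path) -> None:
    """Write trajectories to the canonical CSV (seconds, millimetres)."""
    frames = []
    for tr in trajectories:
        frames.append(pd.DataFrame({
            "id": tr.individual_id, "condition": tr.condition,
            "t": tr.times, "x": tr.xs, "y": tr.ys,
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def resample(traj: Trajectory, target_fps: float) -> Trajectory:
    """Reduce the frame rate by nearest-sample selection (no interpolation).

    The retained samples are the recorded frames nearest to the regular
    grid ``t0, t0 + 1/target_fps, ...``.  Dropping frames rather than
    interpolating mirrors how video-frame data are decimated and avoids
    smoothing turning angles.
    """
    if target_fps <= 0:
        raise ValueError("target_fps must be positive")
    nominal = traj.fps_nominal if traj.fps_nominal else traj.fps_estimated
    if target_fps > nominal * 1.05:
        raise ValueError(
            f"target_fps {target_fps} exceeds the trajectory rate ~{nominal:.3g}")

    t = traj.times
    step = 1.0 / target_fps
    n_out = int(math.floor((t[-1] - t[0]) / step)) + 1
    grid = t[0] + step * np.arange(n_out)
    right = np.searchsorted(t, grid)
    left = np.clip(right - 1, 0, len(t) - 1)
    right = np.clip(right, 0, len(t) - 1)
    idx = np.where(np.abs(t[right] - grid) < np.abs(grid - t[left]), right, left)
    idx = np.unique(idx)  # sorted, strictly monotone times preserved
    return replace(traj, times=t[idx], xs=traj.xs[idx], ys=traj.ys[idx],
                   fps_nominal=target_fps)


def quantize_to_grid(traj: Trajectory, grid: GridSpec) -> Trajectory:
    """Snap positions to the centers of their containing grid cells.

    Cell membership uses half-open intervals, so a point exactly on a
    grid line belongs to the upper cell.  Mapping to centers (rather
    than corners) keeps expected displacement magnitudes unbiased and
    makes the operation idempotent.
    """
    s = grid.spacing
    ox, oy = grid.origin
    qx = ox + (np.floor((traj.xs - ox) / s) + 0.5) * s
    qy = oy + (np.floor((traj.ys - oy) / s) + 0.5) * s
    return replace(traj, xs=qx, ys=qy)
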