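"""Per-frame movement characteristics and paired nonparametric comparison.

Instantaneous speed is the distance covered from one frame to the next
divided by the frame interval; the movement direction is the angle of
the displacement vector against the horizontal axis, and the turning
angle is the magnitude of its change between consecutive frames, in
[0, pi].  Frames with zero displacement have no defined heading and are
skipped, so turning angles are formed between the surrounding moving
segments.

The paired comparison across tracking conditions is the Wilcoxon
signed-rank test: exact null distribution for small untied samples,
tie-corrected normal approximation otherwise.
"""

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .io import Trajectory

logger = logging.getLogger(__name__)


@dataclass
class KinematicsSummary:
    individual_id: str
    condition: str
    fps_used: float
    mean_speed: float          # mm/s
    max_speed: float           # mm/s
    mean_turning_angle: float  # rad; NaN when undefined (<3 frames)
    n_frames: int


@dataclass
class WilcoxonResult:
    statistic: float   # V = sum of ranks of positive differences
    p_value: float
    n: int             # pairs after dropping zero differences
    method: str        # "exact" | "normal" | "degenerate"


def instantaneous_speed(traj: Trajectory) -> np.ndarray:
    """Frame-to-frame speed series, mm/s; length n_frames - 1."""
    dt = np.diff(traj.times)
    zero = np.nonzero(dt == 0)[0]
    if zero.size:
        raise ValueError(f"duplicate timestamp at index {zero[0]}")
    return np.hypot(np.diff(traj.xs), np.diff(traj.ys)) / dt


def _headings(traj: Trajectory) -> np.ndarray:
    """Displacement angles vs the horizontal axis, zero-displacement frames skipped."""
    dx = np.diff(traj.xs)
    dy = np.diff(traj.ys)
    moving = (dx != 0) | (dy != 0)
    return np.arctan2(dy[moving], dx[moving])


def turning_angles(traj: Trajectory) -> np.ndarray:
    """Magnitudes of direction change between consecutive moves, in [0, pi]."""
    if len(traj) < 3:
        raise ValueError("turning angles need at least 3 frames")
    h = _headings(traj)
    if len(h) < 2:
        logger.warning("%s: fewer than 2 nonzero displacements, no turning angles",
                       traj.individual_id)
        return np.empty(0)
    d = np.diff(h)
    return np.abs((d + np.pi) % (2 * np.pi) - np.pi)


def summarize(traj: Trajectory) -> KinematicsSummary:
    """Per-individual kinematics: mean/max speed and mean turning angle."""
    v = instantaneous_speed(traj)
    if len(traj) >= 3:
        ang = turning_angles(traj)
        mean_ang = float(np.mean(ang)) if len(ang) else math.nan
    else:
        mean_ang = math.nan
    return KinematicsSummary(
        individual_id=traj.individual_id, condition=traj.condition,
        fps_used=traj.fps_estimated, mean_speed=float(np.mean(v)),
        max_speed=float(np.max(v)), mean_turning_angle=mean_ang,
        n_frames=len(traj))


def _exact_signed_rank_p(v: float, n: int) -> float:
    """Two-sided exact p for the signed-rank statistic with integer ranks 1..n.

    Counts sign assignments by dynamic programming over the distribution
    of the positive-rank sum W+; p = min(1, 2*min(P(W+ <= v), P(W+ >= v))).
    """
    m = n * (n + 1) // 2
    counts = np.zeros(m + 1)
    counts[0] = 1.0
    for r in range(1, n + 1):
        counts[r:] += counts[:-r].copy()
    total = counts.sum()  # 2**n
    v = int(round(v))
    lo = counts[: v + 1].sum() / total
    hi = counts[v:].sum() / total
    return min(1.0, 2.0 * min(lo, hi))


def wilcoxon_signed_rank(a, b) -> WilcoxonResult:
    """Paired two-sided Wilcoxon signed-rank test.

    V is the sum of the ranks of positive differences (ranks of |a - b|
    with zero differences dropped and average ranks for ties).  The
    p-value uses the exact permutation null for n <= 25 without ties and
    the tie-corrected normal approximation otherwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    d = a - b
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return WilcoxonResult(0.0, 1.0, 0, "degenerate")
    ranks = stats.rankdata(np.abs(d))
    v = float(ranks[d > 0].sum())
    has_ties = len(np.unique(np.abs(d))) < n
    if n <= 25 and not has_ties:
        return WilcoxonResult(v, _exact_signed_rank_p(v, n), n, "exact")
    mean = n * (n + 1) / 4.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    var = n * (n + 1) * (2 * n + 1) / 24.0 - np.sum(tie_counts**3 - tie_counts) / 48.0
    if var == 0:
        return WilcoxonResult(v, 1.0, n, "degenerate")
    z = (v - mean) / math.sqrt(var)
    return WilcoxonResult(v, 2 * stats.norm.sf(abs(z)), n, "normal")
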