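"""Exit-time analysis of a square region with right censoring.

Each individual starts at the center of a square region (side 3600 mm
by default, matching a 3.6 m x 3.6 m effective arena) and is followed
until it leaves the square or the observation horizon (1800 s default)
is reached; an individual still inside at the horizon is right-censored.
Survival in the region is summarized by the Kaplan-Meier product-limit
estimator, and two tracking conditions are compared with the two-group
log-rank test (and its Gehan-Wilcoxon weighted variant).

Kaplan-Meier fitting and the log-rank statistics are delegated to
``lifelines``.
"""

from dataclasses import dataclass

import numpy as np
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test

from .io import Trajectory


@dataclass
class ExitRecord:
    individual_id: str
    condition: str
    exit_time: float            # s from trajectory start; horizon if censored
    censored: bool
    path_length_to_exit: float  # mm traveled up to exit or censoring


@dataclass
class SurvivalCurve:
    times: np.ndarray            # distinct event/censor times, increasing
    survival: np.ndarray         # S(t) at those times, non-increasing from <=1
    at_risk: np.ndarray          # n at risk just before each time
    events: np.ndarray           # events at each time


@dataclass
class LogRankResult:
    chi_squared: float
    p_value: float
    degenerate: bool = False    # no events in either group


def exit_record(traj: Trajectory, side: float = 3600.0,
                horizon: float = 1800.0) -> ExitRecord:
    """Time and path length until leaving the square centered on the start.

    Exit is detected at sample resolution: the exit time is the first
    sample at which |x - x0| or |y - y0| exceeds side/2.  If no sample
    within the horizon is outside, the record is censored at the horizon.
    """
    if side <= 0 or horizon <= 0:
        raise ValueError("side and horizon must be positive")
    t = traj.times - traj.times[0]
    dx = np.abs(traj.xs - traj.xs[0])
    dy = np.abs(traj.ys - traj.ys[0])
    seg = np.hypot(np.diff(traj.xs), np.diff(traj.ys))
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    outside = (dx > side / 2) | (dy > side / 2)
    if outside[0]:
        raise ValueError("trajectory does not start inside the square")
    hits = np.nonzero(outside & (t <= horizon))[0]
    if hits.size:
        i = hits[0]
        return ExitRecord(traj.individual_id, traj.condition,
                          float(t[i]), False, float(cum[i]))
    in_horizon = t <= horizon
    i = int(np.nonzero(in_horizon)[0][-1])
    return ExitRecord(traj.individual_id, traj.condition,
                      float(horizon), True, float(cum[i]))


def _durations_events(records):
    d = np.array([r.exit_time for r in records])
    e = np.array([not r.censored for r in records], dtype=bool)
    return d, e


def kaplan_meier(records: list[ExitRecord]) -> SurvivalCurve:
    """Product-limit estimate S(t) = prod_{t_i <= t} (1 - d_i / n_i)."""
    if not records:
        raise ValueError("need at least one record")
    d, e = _durations_events(records)
    kmf = KaplanMeierFitter().fit(d, event_observed=e)
    table = kmf.event_table.iloc[1:] if kmf.event_table.index[0] == 0 else kmf.event_table
    times = table.index.to_numpy(dtype=float)
    surv = kmf.survival_function_at_times(times).to_numpy()
    return SurvivalCurve(times=times, survival=surv,
                         at_risk=table["at_risk"].to_numpy(),
                         events=table["observed"].to_numpy())


def log_rank(group_a: list[ExitRecord], group_b: list[ExitRecord],
             wilcoxon: bool = False) -> LogRankResult:
    """Two-group log-rank test (chi-squared, 1 df).

    With ``wilcoxon=True`` the Gehan-Wilcoxon variant is computed
    instead, weighting each event time by the number at risk, which
    emphasizes early exits.
    """
    if not group_a or not group_b:
        raise ValueError("both groups must be nonempty")
    da, ea = _durations_events(group_a)
    db, eb = _durations_events(group_b)
    if not (ea.any() or eb.any()):
        return LogRankResult(0.0, 1.0, degenerate=True)
    kwargs = {"weightings": "wilcoxon"} if wilcoxon else {}
    res = logrank_test(da, db, event_observed_A=ea, event_observed_B=eb, **kwargs)
    return LogRankResult(float(res.test_statistic), float(res.p_value))
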