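"""Seeded synthetic 2D random walkers with known statistical structure.

Each walker kind is a standard null or alternative model for the
diffusion and step-length analyses:

- ``brownian``     i.i.d. Gaussian position increments (normal diffusion,
                   alpha = 1, thin-tailed move lengths);
- ``ballistic``    straight line at constant speed (alpha = 2);
- ``crw``          correlated random walk: constant speed, wrapped-normal
                   heading increments with concentration ``kappa``;
- ``truncated_levy`` constant-speed Levy walk whose move lengths follow a
                   truncated Pareto law P(x) ~ x^-mu on [a, b], uniform
                   random heading per move (superdiffusive for mu <= 3);
- ``bounded_arena`` a CRW confined to a circular arena with thigmotactic
                   wall-following, reproducing the MSD plateau seen in
                   small enclosed arenas.

Defaults emulate the study conditions: 30 frames per second for 1800 s
and walking speeds of order 10-16 mm/s.
"""

from dataclasses import dataclass

import numpy as np

from .io import Trajectory

_KINDS = ("brownian", "ballistic", "crw", "truncated_levy", "bounded_arena")


@dataclass
class WalkerConfig:
    """Parameters of one synthetic walker.

    Only the fields relevant to ``kind`` are used: ``sigma_step`` (mm per
    frame) for brownian; ``speed`` (mm/s) for the constant-speed kinds;
    ``kappa`` for crw and bounded_arena; ``mu``, ``a``, ``b`` for the
    truncated-Levy move-length law; ``arena_radius``, ``wall_follow_prob``
    and ``wall_dwell_mean`` for the bounded arena.
    """

    kind: str
    n_frames: int = 54000          # 1800 s at 30 FPS
    dt: float = 1.0 / 30.0         # s per frame
    speed: float = 13.0            # mm/s, mid-range of observed pillbug speeds
    sigma_step: float = 1.0        # mm per frame (brownian)
    kappa: float = 10.0            # heading concentration (crw)
    mu: float = 2.0                # Levy exponent, 1 < mu <= 3
    a: float = 10.0                # mm, lower truncation of move lengths
    b: float = 1000.0              # mm, upper truncation (2 orders of magnitude)
    arena_radius: float = 150.0    # mm, small-arena radius
    wall_follow_prob: float = 0.8  # probability of wall-following on contact
    wall_dwell_mean: float = 20.0  # mean wall-following duration, frames
    seed: int = 0

    def __post_init__(self):
        if self.kind not in _KINDS:
            raise ValueError(f"unknown walker kind {self.kind!r}; choose from {_KINDS}")
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.kind == "truncated_levy":
            if not (1.0 < self.mu <= 3.0):
                raise ValueError("Levy exponent must satisfy 1 < mu <= 3")
            if not (0 < self.a < self.b):
                raise ValueError("need 0 < a < b")


def sample_truncated_pareto(n: int, mu: float, a: float, b: float,
                            seed=None) -> np.ndarray:
    """Draw ``n`` i.i.d. move lengths from the truncated Pareto law.

    Density ``f(x) = (mu-1) x^-mu / (a^(1-mu) - b^(1-mu))`` on [a, b];
    at mu = 1 the log-uniform limit ``f(x) = 1/(x log(b/a))`` is used.
    Sampling is by inverse CDF, so draws are reproducible under ``seed``
    (an int or a ``numpy.random.Generator``).

    Raises ``ValueError`` for mu < 1 or a >= b.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not (0 < a < b):
        raise ValueError("need 0 < a < b")
    if mu < 1:
        raise ValueError("mu must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    u = rng.random(n)
    if abs(mu - 1.0) < 1e-9:
        return a * (b / a) ** u
    e = 1.0 - mu
    return (a**e - u * (a**e - b**e)) ** (1.0 / e)


def _brownian(cfg: WalkerConfig, rng) -> tuple[np.ndarray, np.ndarray]:
    steps = rng.normal(0.0, cfg.sigma_step, size=(cfg.n_frames - 1, 2))
    xy = np.vstack([[0.0, 0.0], np.cumsum(steps, axis=0)])
    return xy[:, 0], xy[:, 1]


def _ballistic(cfg: WalkerConfig, rng) -> tuple[np.ndarray, np.ndarray]:
    theta = rng.uniform(0, 2 * np.pi)
    d = cfg.speed * cfg.dt * np.arange(cfg.n_frames)
    return d * np.cos(theta), d * np.sin(theta)


def _crw(cfg: WalkerConfig, rng) -> tuple[np.ndarray, np.ndarray]:
    n = cfg.n_frames
    theta0 = rng.uniform(0, 2 * np.pi)
    if cfg.kappa > 0:
        dtheta = rng.normal(0.0, 1.0 / np.sqrt(cfg.kappa), size=n - 2)
    else:
        dtheta = rng.uniform(-np.pi, np.pi, size=n - 2)  # Pearson walk limit
    headings = theta0 + np.concatenate([[0.0], np.cumsum(dtheta)])
    step = cfg.speed * cfg.dt
    xs = np.concatenate([[0.0], np.cumsum(step * np.cos(headings))])
    ys = np.concatenate([[0.0], np.cumsum(step * np.sin(headings))])
    return xs, ys


def _truncated_levy(cfg: WalkerConfig, rng) -> tuple[np.ndarray, np.ndarray]:
    # Build the continuous constant-speed path as a piecewise-linear curve
    # over move boundaries, then sample it at the frame times.  The walker
    # therefore moves at exactly `speed` along the path; a move that ends
    # mid-frame hands the remaining frame time to the next move.
    total_t = (cfg.n_frames - 1) * cfg.dt
    mean_len = np.mean(sample_truncated_pareto(256, cfg.mu, cfg.a, cfg.b, rng))
    lengths = np.empty(0)
    while lengths.sum() < total_t * cfg.speed:
        n_more = max(16, int(1.5 * (total_t * cfg.speed - lengths.sum()) / mean_len))
        lengths = np.concatenate(
            [lengths, sample_truncated_pareto(n_more, cfg.mu, cfg.a, cfg.b, rng)])
    headings = rng.uniform(0, 2 * np.pi, size=len(lengths))
    bx = np.concatenate([[0.0], np.cumsum(lengths * np.cos(headings))])
    by = np.concatenate([[0.0], np.cumsum(lengths * np.sin(headings))])
    bt = np.concatenate([[0.0], np.cumsum(lengths / cfg.speed)])
    frame_t = cfg.dt * np.arange(cfg.n_frames)
    return np.interp(frame_t, bt, bx), np.interp(frame_t, bt, by)


def _bounded_arena(cfg: WalkerConfig, rng) -> tuple[np.ndarray, np.ndarray]:
    # CRW core; on hitting the circular wall the walker lands on the wall
    # and either follows it tangentially for a geometric number of frames
    # (thigmotaxis) or reflects inward.
    n, R = cfg.n_frames, cfg.arena_radius
    step = cfg.speed * cfg.dt
    sd = 1.0 / np.sqrt(cfg.kappa) if cfg.kappa > 0 else None
    xs = np.zeros(n)
    ys = np.zeros(n)
    heading = rng.uniform(0, 2 * np.pi)
    dwell = 0
    tang = 1.0
    for i in range(1, n):
        x, y = xs[i - 1], ys[i - 1]
        if dwell > 0:
            phi = np.arctan2(y, x) + tang * step / R
            xs[i], ys[i] = R * np.cos(phi), R * np.sin(phi)
            dwell -= 1
            if dwell == 0:
                heading = phi + tang * np.pi / 2  # leave along the tangent
            continue
        heading += rng.normal(0.0, sd) if sd is not None else rng.uniform(-np.pi, np.pi)
        px = x + step * np.cos(heading)
        py = y + step * np.sin(heading)
        r = np.hypot(px, py)
        if r <= R:
            xs[i], ys[i] = px, py
            continue
        # place on the wall at the contact direction
        xs[i], ys[i] = px * R / r, py * R / r
        if rng.random() < cfg.wall_follow_prob:
            dwell = rng.geometric(1.0 / cfg.wall_dwell_mean)
            tang = 1.0 if rng.random() < 0.5 else -1.0
        else:
            nx, ny = xs[i] / R, ys[i] / R  # reflect heading about the tangent
            vx, vy = np.cos(heading), np.sin(heading)
            dot = vx * nx + vy * ny
            heading = np.arctan2(vy - 2 * dot * ny, vx - 2 * dot * nx)
    return xs, ys


_GENERATORS = {
    "brownian": _brownian,
    "ballistic": _ballistic,
    "crw": _crw,
    "truncated_levy": _truncated_levy,
    "bounded_arena": _bounded_arena,
}


def generate(cfg: WalkerConfig) -> Trajectory:
    """Generate one seeded walker trajectory starting at the origin."""
    rng = np.random.default_rng(cfg.seed)
    xs, ys = _GENERATORS[cfg.kind](cfg, rng)
    times = cfg.dt * np.arange(cfg.n_frames)
    return Trajectory(individual_id=f"{cfg.kind}-{cfg.seed}", condition=cfg.kind,
                      times=times, xs=xs, ys=ys, fps_nominal=1.0 / cfg.dt)
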