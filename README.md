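# freewalk

Trajectory analysis for freely walking small animals — insects,
isopods, and other lab-scale walkers tracked as time-stamped 2D
positions. The package serves movement-ecology and behavior labs that
need to characterize *inherent* movement patterns from tracking data:
how fast and how straight an animal walks, whether its spreading is
normal or anomalous, how long it stays inside a region, and whether its
move lengths bear the signature of a Lévy walk.

## What it computes

- **Kinematics** — instantaneous speed, turning angles (the magnitude
  of heading change per frame, in [0, π]), per-individual summaries,
  and paired Wilcoxon signed-rank comparisons across tracking
  conditions (exact null for small untied samples).
- **Anomalous diffusion** — mean squared displacement curves, per
  individual or ensemble; the diffusion exponent α in MSD ~ t^α by OLS
  on the log–log curve (α = 1 normal diffusion, α > 1 superdiffusion,
  α < 1 subdiffusion); and α-versus-window profiles that reveal whether
  an arena wall, rather than the animal, set the exponent.
- **Exit-time survival** — time and path length until leaving a square
  region, with right censoring at the observation horizon;
  Kaplan–Meier curves and two-group log-rank (plus Gehan–Wilcoxon)
  tests via `lifelines`.
- **Lévy-walk detection** — per individual and per axis: segmentation
  into moves at direction reversals, maximum-likelihood fits of a
  truncated Pareto `f(x) ∝ x^−μ` on `[a, b]` versus a truncated
  exponential on the same support, model selection by Akaike weights
  (wAIC), and a Monte-Carlo Kolmogorov–Smirnov goodness-of-fit gate.
  A Lévy walk is supported when the truncated Pareto wins with
  1 < μ ≤ 3 over a meaningful range of scales.
- **Synthetic walkers** — seeded Brownian, ballistic, correlated,
  truncated-Lévy, and wall-bounded (thigmotactic) walkers, so every
  estimator can be validated against known ground truth.

## Worked example

```python
from freewalk import (WalkerConfig, generate, msd, ensemble_msd,
                      estimate_alpha, LevyConfig, classify_individual)

# Detect a Levy walk in a simulated walker with known exponent mu = 2
cfg = LevyConfig(fit_floor=50.0, gof_resamples=1000, seed=0)
walker = generate(WalkerConfig("truncated_levy", mu=2.0,
                               n_frames=6000, dt=1.0, seed=1))
cls = classify_individual(walker, cfg)
print(f"verdict: {cls.overall}  mu_x={cls.mu_x:.2f}  mu_y={cls.mu_y:.2f}")

# Diffusion exponent of a Brownian ensemble (expected alpha = 1)
curves = [msd(generate(WalkerConfig("brownian", n_frames=1800, dt=1.0,
                                    seed=s)), mode="from_start")
          for s in range(1, 101)]
est = estimate_alpha(ensemble_msd(curves), window=900.0)
print(f"ensemble alpha = {est.alpha:.3f}  (r^2 = {est.r_squared:.3f})")
```

Output:

```
verdict: TP_both  mu_x=1.82  mu_y=1.82
ensemble alpha = 1.022  (r^2 = 0.998)
```

The walker is classified as truncated-Pareto on both axes (`TP_both`)
with the Lévy exponent recovered near its true value of 2, and the
Brownian ensemble shows normal diffusion: the fitted slope of log MSD
against log lag over a 900 s window is 1 to within sampling noise.

A command-line interface mirrors the library —
`freewalk simulate | kinematics | msd | exit | levy` — reading and
writing a plain trajectory CSV (`id,condition,t,x,y`; seconds and
millimetres). See `freewalk --help`.

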