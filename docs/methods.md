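# Methods

`freewalk` analyzes 2D trajectories of freely walking small animals —
time-stamped positions of one individual per tracking condition — and
asks three questions: how the animal moves frame to frame (kinematics),
how it spreads through space (anomalous diffusion), and whether its
move-length distribution is consistent with a Lévy walk. A seeded
simulator of random walkers with known structure provides the ground
truth against which every stage is validated.

Units are seconds and millimetres throughout.

## Trajectory handling

Trajectories are read from a flat CSV (`id,condition,t,x,y`), grouped by
individual and condition, with non-finite rows dropped and logged.

**Resampling** reduces the frame rate by nearest-sample selection: the
retained samples are the recorded frames closest to the regular grid
`t0 + k/fps`. No interpolation is performed — recorded video frames are
dropped, not synthesized — because interpolation would smooth headings
and bias turning angles downward. Selection is idempotent at a fixed
rate, and on jittered input every retained sample lies within half a
native frame of its grid target (inter-sample *differences* can deviate
by up to a full native frame, since adjacent half-frame offsets add).

**Grid quantization** snaps positions to the centers of square lattice
cells (default spacing 20 mm, the resolution of hand-recorded arena
positions). Cells are half-open `[k·s, (k+1)·s)`, so boundary points
belong to the upper cell; center mapping keeps the operation idempotent
and displaces no point by more than `s·√2/2`. Downsampling and
quantization are independent composable steps; when both are needed we
downsample first, then quantize, so that the lattice is applied to the
frames actually analyzed.

## Synthetic walkers

Five walker kinds span the hypotheses the analyses discriminate, all
seeded and reproducible. Defaults emulate the experimental recording
conditions: 30 frames/s for 1800 s and walking speeds of order
10–16 mm/s (13 mm/s default).

- **brownian** — i.i.d. Gaussian position increments (sd `sigma_step`
  per frame). Normal diffusion, thin-tailed move lengths.
- **ballistic** — fixed random heading, constant speed. MSD = v²t².
- **crw** — correlated random walk: constant speed, heading increments
  from a wrapped normal with concentration `kappa` (sd `1/√kappa`);
  `kappa → ∞` recovers ballistic motion, `kappa = 0` a uniform-turning
  Pearson walk.
- **truncated_levy** — a constant-speed Lévy *walk*: move lengths drawn
  from the truncated Pareto law `P(x) ∝ x^−μ` on `[a, b]` (defaults
  μ = 2, a = 10 mm, b = 1000 mm — two orders of magnitude, admissible
  Lévy range 1 < μ ≤ 3), uniform random heading per move. The
  continuous constant-speed path is built as a piecewise-linear curve
  over move boundaries and sampled at the frame times, so a move ending
  mid-frame hands the remaining frame time to the next move and the
  along-path speed is exactly constant.
- **bounded_arena** — a CRW inside a circular wall (default radius
  150 mm). On contact the walker lands on the wall and, with
  probability `wall_follow_prob`, follows it tangentially for a
  geometric number of frames (mean `wall_dwell_mean`), else reflects
  inward. The wall-following mechanism is the simplest fixture that
  reproduces thigmotactic confinement and its MSD plateau; it is not a
  biological model.

Truncated-Pareto sampling uses the inverse CDF
`x = [a^(1−μ) − u·(a^(1−μ) − b^(1−μ))]^(1/(1−μ))`, with the log-uniform
limit form at μ = 1.

## Kinematics

Instantaneous speed is the frame-to-frame Euclidean displacement divided
by the frame interval. The movement direction is the angle of the
displacement vector against the horizontal axis; the turning angle is
the magnitude of its change between consecutive frames, wrapped to
[0, π]. Frames with zero displacement carry no heading and are skipped,
so turning angles are formed between the surrounding moving segments —
this avoids spurious 0 or π angles when the animal pauses. Summaries
(mean/max speed, mean turning angle) are unweighted arithmetic means,
appropriate for near-uniform frame intervals.

Paired comparisons across tracking conditions use the two-sided Wilcoxon
signed-rank test. The statistic V is the sum of the ranks of positive
differences (zero differences dropped, average ranks for ties). For
n ≤ 25 without ties the p-value comes from the exact permutation null,
computed by dynamic programming over the distribution of the
positive-rank sum; otherwise a tie-corrected normal approximation is
used (variance `n(n+1)(2n+1)/24 − Σ(t³−t)/48`).

## Mean squared displacement and α

MSD(τ) is computed at integer multiples of the frame interval in two
modes. `from_start` is the squared displacement from the first sample —
one noisy realization per individual, intended for ensemble averaging
across individuals. `time_averaged` averages over all origin pairs a lag
apart within one trajectory, giving per-individual curves stable enough
to report an exponent per animal. Time averaging assumes
increment stationarity; for confined walkers both modes show the same
plateau.

The diffusion exponent α in MSD ~ t^α is the slope of an unweighted OLS
fit of log MSD on log lag over lags in `(0, window]` (natural logs,
default window 900 s; zero-MSD points are excluded since their log is
undefined). `alpha_profile` re-estimates α across a list of windows:
for an unconfined walker α is window-stable, while confinement makes α
collapse toward 0 as the window grows past the plateau onset — this
contrast is the diagnostic for whether an arena wall, rather than the
animal, set the measured exponent.

## Exit-time survival analysis

Each individual is followed until it leaves a square region centered on
its starting position (default side 3600 mm, horizon 1800 s). Exit is
detected at sample resolution — the first recorded sample outside the
half-side in either coordinate — which matches data recorded on a 10 s
observation grid; no segment–boundary intersection is computed.
Individuals still inside at the horizon are right-censored. Exit times
are summarized with the Kaplan–Meier product-limit estimator and two
conditions are compared with the two-group log-rank test; a
Gehan–Wilcoxon variant (log-rank weighted by the number at risk, which
emphasizes early exits) is available alongside. Both are delegated to
`lifelines`. All times are reported in seconds.

## Lévy-walk detection

Per individual and per axis (x and y separately, to avoid pooling
artifacts and following the established 1D protocol): the trajectory is
resampled to 1 frame/s, the coordinate is segmented into moves at
direction reversals — a move is a maximal run of same-sign increments,
zero increments extend the run — and each move contributes its absolute
net displacement. Moves shorter than `min_step` (default 1 mm, the
sub-resolution jitter scale) are merged *into the following move*, so
signed moves always telescope to the net axis displacement.

Two single-parameter models are fit to the move lengths by maximum
likelihood on the observed support `[a, b] = [min, max]`:

- truncated Pareto: `f(x) = (μ−1) x^−μ / (a^(1−μ) − b^(1−μ))`, μ
  searched in (1, 10], continuous through the μ = 1 log-uniform limit;
- truncated exponential: `f(x) = λ e^(−λx) / (e^(−λa) − e^(−λb))`,
  matched to the same support so the likelihoods are comparable.

Both MLEs are bounded 1D optimizations (tolerance 1e−10); boundary
solutions are flagged. AIC uses k = 1 (a and b are fixed by the data,
not estimated), and models are compared by Akaike weights
`w_i = exp(−Δ_i/2)/Σ exp(−Δ_j/2)`.

**Fit floor.** Axis projection of a 2D walk and reversal-based
segmentation distort the small-step end of the move-length
distribution: a projected step is `L·|cos θ|`, which preserves a
power-law tail exactly but flattens the density below the smallest true
move, and consecutive moves with the same axis sign merge into sums
that inflate the bulk. Both artifacts bias the fitted exponent downward
if sub-resolution steps enter the likelihood. `LevyConfig.fit_floor`
therefore excludes moves below a declared spatial resolution from the
fit (an x_min bound in the usual power-law-fitting sense), with the
support reset to the retained min/max. For constant-speed data a floor
of roughly four frame-lengths (≈ 50 mm at 13 mm/s and 1 frame/s) is
recommended; with it, simulated Lévy walkers (μ = 2) are recovered with
mean μ̂ within ≈ 0.05 of truth and per-axis estimates within ≈ ±0.2.
Comparisons against a Brownian null are meaningful when the null's step
scale places its exponential body above the floor (σ of the order of
the floor); far below it only an extreme tail remains, over less than
half an order of magnitude, where no model is identifiable.

**Goodness of fit.** The wAIC winner must also pass an absolute
Monte-Carlo Kolmogorov–Smirnov check: B = 1000 samples of size n are
drawn from the fitted law and their KS distances to that law are
compared with the observed distance, `p = (1 + #{KS* ≥ KS})/(B + 1)`,
pass at p ≥ 0.05. The null distances use fixed (fitted) parameters
while the observed distance benefits from estimation, so the test is
deliberately conservative: segmentation and projection only approximate
the candidate families even when the underlying walk follows them, and
a sharper test (e.g. refitting each resample) rejects the correct
family on ground-truth Lévy walkers once n exceeds a few hundred.

A failed check leaves the axis *unclassified*; otherwise the verdict is
TP or Exp by the larger weight. The per-individual verdict is TP_both,
TP_one, or neither. Axes with fewer than `min_moves` (default 10) moves
are unclassified for insufficient data.

## Validation surface and its limits

The test suite validates every stage against independent oracles:
closed-form MSD curves, brute-force origin enumeration, hand
product-limit and hypergeometric computations, exhaustive sign
enumeration for the signed-rank test, analytic CDFs for the samplers,
and dense grid searches of every likelihood. End-to-end checks confirm
that Brownian ensembles yield α ≈ 1, ballistic walkers α = 2 to machine
precision, bounded-arena walkers the plateau/α-collapse signature,
Lévy walkers a TP verdict with μ̂ near truth, and Brownian walkers an
exponential verdict.

Problem sizes used in the checks are chosen to keep each property
measurable with margin: ensembles of 50–200 walkers of 1800–6000 frames
at 1 frame/s, 10⁴ i.i.d. draws for estimator recovery, 100 series per
model for selection accuracy, 200 replicate splits for the log-rank
type-I rate.

The synthetic walkers emulate sampling rate, duration, speed scale, and
the confinement geometry of real recordings, but not sensor noise,
speed variability within and between moves, pauses, or intermittent
behavioral switching. Passing tests therefore demonstrate that the
estimators recover the structure the walkers possess — not that real
animals possess that structure, nor that the segmentation's residual
exponent bias (downward, ≈ 0.05–0.1 after flooring) vanishes on real
data, where it should be assessed with matched simulations like these.

## Known limitations

- The reversal segmentation is 1D per axis; no 2D turning-angle
  segmentation is provided.
- Exit detection at sample resolution slightly overestimates exit times
  at low sampling rates (at most one frame interval).
- `from_start` MSD of a single individual is a single realization; only
  its ensemble mean is interpretable.
- The exponential/TP pair is the only model comparison implemented; no
  composite or bi-exponential competitors.
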