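# Methods

This note documents the models and procedures implemented in `placotax`, the
parameter choices that matter, and what the synthetic generator does and does
not emulate.

## Data model and conventions

A trial is a centroid time series sampled at 30 s/frame (stored as
`dt_min = 0.5`, configurable, never hard-coded), in millimetres, recentred so
the first valid sample is (0, 0).  The thermal gradient axis is a unit vector
at angle θ (radians from +x) pointing towards the warm side; the default
θ = π/2 puts heat at +y.  A displacement (dx, dy) decomposes into
`parallel = dx·cosθ + dy·sinθ` and `orthogonal = −dx·sinθ + dy·cosθ`
(left-of-warm positive).  The orthogonal sign only matters for plotting;
every statistic that uses the orthogonal component is sign-symmetric.

Frames where segmentation failed are carried as gaps (`valid = False`).
Window statistics skip any window touching a gap rather than interpolating:
interpolation would fabricate displacement, and fabricated displacement
contaminates every step-length and velocity statistic downstream.

## Momentary velocities and windrose

Momentary velocities are chord displacements over windows of *n* frames
divided by δt = n·0.5 min ("speed" is the chord length over δt, not the
within-window arc length — the chord is what the projection equations
measure).  Defaults: *n* = 2 (δt = 1 min), non-overlapping; overlapping
windows use stride 1 frame.  Windrose histograms use 10-min overlapping
windows, 16 direction sectors centred on the warm direction, speed bins in
mm min⁻¹, all bars normalised to unit total mass.  Before binning, windows
whose displacement is ≤ 0.0601 mm (the optical resolution limit) in *both*
x and y are discarded; these are centroid jitter from shape change, not
locomotion.  That filter is applied only to windrose summaries by default.

## MSD, α and the end window

The time-averaged MSD of one axis projection s(t) is
`MSD(τ) = ⟨(s(t+τ) − s(t))²⟩_t` at frame resolution.  To normalise trials of
very different durations, and to avoid the stagnant unfolding period at the
start and the wall approach at the end, the standard window is the 200
samples from `last−210` to `last−11` — a 100-min stretch ending 5 min before
the last frame (trajectories shorter than 211 frames fall back to the full
series, with a note in the results object).

α is the least-squares slope of log MSD vs log lag.  By default the fit uses
lags up to 20 frames (10 min).  Fitting *all* lags of a 200-point window is
statistically treacherous: at lags comparable to the window length the time
average rests on a handful of samples, and regressing the *logarithm* of
such noisy averages biases the slope low — on genuinely unbiased
exponential-step walks the all-lag estimate averages ≈ 0.77 instead of 1
(100 seeds), while the 20-lag default averages ≈ 0.96.  The lag range is a
parameter (`max_lag=None` fits everything) for users who want the raw
behaviour.

RMSD fits use the same end window.  Taylor's dispersal law
`RMSD(t) = [2v²τ(t − τ(1 − e^(−t/τ)))]^{1/2}` is fitted by bounded nonlinear
least squares (v, τ > 0; initial guesses from the curve's endpoints); the
ballistic alternative `RMSD = v·t` has the closed-form through-origin
solution.  Both report r² for model comparison.  Non-convergence is returned
as a flagged result, not an exception.

## Straightness, directionality, classification

`S = D/L` and `M = D·cosθₑ/L` with D the end-to-end displacement, L the total
path length (sum of chords between consecutive valid frames) and θₑ the
end-to-end angle to the warm axis.  M > 0 classifies a trial as positive
thermotaxis and M > 0.1 as effective thermotaxis; both inequalities are
strict.  "Fraction of time warmer" counts valid frames with strictly
positive warm-axis projection, so frames exactly on the starting isotherm
(including a fully stationary trajectory) count as not-warmer.  First
passage is the first time the radial distance from the start reaches 5 mm;
trials that never reach it are reported censored and excluded from means.

## Persistence length

For each contour window length L (default grid: 1 mm steps up to 20 mm) the
path is cut into maximal non-overlapping contours of arc length exactly L
(the cut point is linearly interpolated inside the crossing segment; the
trailing remainder is discarded).  The averaged squared end-to-end
displacement ⟨R²⟩ of those contours is matched to the worm-like-chain
relation `⟨R²⟩ = 2L_p²(L/L_p − 1 + e^(−L/L_p))`.  The left side is monotone
in L_p, so the single averaged point determines L_p by bounded root finding
(bracket [L_step, 10³ mm]); ⟨R²⟩ at or beyond the straight-path limit L²
makes the fit diverge, and the bound is returned with a flag.  The scan
reports L_p(L) and the window length maximising it.  Window lengths with
fewer than two contours are skipped.

## Step-length distributions

The step sample is the magnitude of the gradient-axis displacement over
2-min overlapping windows (the full chord is available via
`component="total"`).  The sample is binned into 40 equal-width density
bins, and three models are least-squares fitted to the *bin heights* —
fitting the histogram, not maximising likelihood, because the ranking
statistic is r² against those heights (a closed-form ML rate for the
exponential is available as an option):

- exponential `a·e^(−λx)`;
- one-sided Lévy `(c/2π)^{1/2} e^(−c/(2(x−μ)))/(x−μ)^{3/2}` with μ
  constrained below the sample minimum (the printed density has no free
  amplitude, so c and μ are the only parameters);
- power law `a·x^(−k)` on positive bins.

The best model is the r² argmax.  Calibration: on 10⁴ draws from an
exponential the rate is recovered within 5 % and the exponential wins the
ranking in ≥ 95 of 100 seeded runs.

## Complexity metrics

DFA: integrate the mean-subtracted series, cut into non-overlapping boxes,
detrend each box with an order-1 polynomial, take the RMS fluctuation F(s),
and regress log F on log s over 10 log-spaced scales from 4 to N/4.  These
are the standard textbook settings; they reproduce the theoretical
exponents (0.5 white noise, 1.5 integrated noise) within 0.05/0.1.
Fluctuations below numerical round-off are treated as zero, so inputs that
are deterministic at the detrend order raise rather than returning a
garbage slope.

Windowed entropy: smooth the series with a sliding mean at each window
size, discretise into 10 equal-width levels spanning the **raw** series'
range (fixed across window sizes), and report −Σp·log₂p.  Fixing the bin
edges is essential: re-binning each smoothed series over its own range
makes the value invariant to the concentration that smoothing produces
(a smoothed Gaussian is still a Gaussian), which would erase exactly the
window-size trend the metric exists to show.  Because the edges scale with
the series' own range, the value is still invariant to affine rescaling.
Absolute entropy values depend on the level count, which is recorded with
the output.  Both metrics default to running on the momentary v∥ series,
configurable.

Mann–Whitney U: U counts pairs (a, b) with a > b (ties ½).  For
min(n_a, n_b) ≤ 8 and no ties the two-sided p is exact, from full
enumeration of the C(n_a+n_b, n_a) rank assignments; otherwise a normal
approximation with tie and continuity corrections is used.  Tests verify
the exact mode against an independent brute-force permutation oracle and
the asymptotic mode against `scipy.stats.mannwhitneyu`.

Before/after comparison: directionality and mean momentary speed (30 s
non-overlapping sub-windows) in the 20-min windows on either side of the
perturbation time, requiring full coverage of both windows.

## Synthetic generator

The generator produces the study conditions the analysis assumes, not a
mechanistic organism model.  Per-frame step magnitudes are exponential with
rate λ (`step_rate`, default 10 mm⁻¹ → mean 0.1 mm per 30 s ≈ 0.2 mm min⁻¹,
a realistic gliding speed for an animal crossing a 52.5 mm arena over
hours).  The biased correlated walk draws each heading from a von Mises
distribution whose mean is the previous heading tilted towards the warm
axis with weight b — bias acts on *direction only*, never on step length,
so taxis raises v∥ without raising momentary speed, which is the signature
the before/after drug analysis relies on.  Pauses are geometric-duration
freezes (`pause_prob`, mean duration in minutes), emulating minutes-scale
freezing episodes; they are off by default and enabled explicitly where
wanted, since they deliberately break the exponential step distribution
with a point mass at zero.  Walks start at (0, 0) and terminate at the
first frame reaching the arena radius.  Dedicated modes provide exact
references: `ballistic` (straightness 1, α = 2), `diffusive` (α → 1),
`wlc` (fixed step, Gaussian heading increments with variance 2·step/L_p so
tangent correlation decays as e^(−s/L_p)), and `taylor_process` (2-D
Ornstein–Uhlenbeck velocity with RMS speed v and correlation time τ).
Cohort seeds are `base_seed + index`, so a cohort reproduces from one
integer.

What the generator does **not** emulate: organism shape change and the
centroid jitter it causes (beyond the optional image-stack wobble), wall
climbing and re-entry, the anecdotal response lag after a gradient flip,
spatial temperature nonuniformity, and any size dependence.  Passing tests
therefore demonstrate that the *estimators* are correct and well calibrated
on walks with known structure — not that real organisms follow these walks.

The image renderer draws one soft elliptical Gaussian blob per frame
(optional Gaussian pixel noise and shape wobble) and emits a ground-truth
centroid table; segmentation (per-frame Otsu or fixed threshold, size
filter, single-component rule, wall-radius truncation) recovers noiseless
centroids to < 0.5 px RMS.  Frames with zero or multiple surviving
components are marked invalid rather than guessed.

## Problem sizes and numerical choices

Test and calibration runs use deliberately modest sizes chosen to pin each
statistic down without waste: 211-frame walks (the minimum supporting the
standard end window) for α calibration, 100 seeds for stochastic means,
10⁴ samples for distribution fits, 10⁴-step chains for persistence
recovery, 2¹⁴-point series for DFA.  Fits use bounded scipy least squares
with data-driven initial guesses; degenerate inputs (constant series,
all-equal samples, zero-length paths, coincident beads) raise or flag
rather than returning silently wrong numbers.  Histogram and CSV float
formatting is fixed so that repeated runs are byte-identical under a fixed
seed.

## Known limitations

- The deposited experimental trajectories' column dialect is absorbed by a
  user-supplied mapping; no attempt is made to guess units.
- Persistence L_p comes from a single averaged ⟨R²⟩ point per window length,
  so no goodness-of-fit accompanies it (the scan shape itself is the
  diagnostic); straight segments push it to the divergence bound.
- Absolute entropy values depend on the discretisation; only trends across
  window sizes and comparisons at fixed settings are meaningful.
- No multiple-testing correction is applied to comparison tables, matching
  standard practice of reporting raw U and p per metric.
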