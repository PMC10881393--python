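# Methods

## Conventions

All azimuthal quantities are degrees, wrapped to `(-180, 180]`, positive
anticlockwise. In the closed-loop rig the bar position is the inverse of
the fly's heading; `circ.heading_from_bar` is the only place that sign flip
lives. Circular standard deviation is `sqrt(-2 ln R)` in degrees, where `R`
is the resultant length; at the dispersions reported here it is
indistinguishable from the linear standard deviation of the wrapped
residuals.

## The PFL3 population model

Each cell fires at `f(cos(H - H_pref) + d cos(G - G_pref))` with the
softplus `f(x) = a log(1 + exp(b(x + c)))` shared across cells
(`a = 29.23 Hz`, `b = 2.17`, `c = -0.7`, `d = 0.63`). Preferred angles come
from the printed connectome-derived lists: a common 12-entry goal-angle
list for both hemispheres and mirror-image heading-angle lists (left =
right negated and reversed). The default glomerular angle scheme follows
the Δ7 innervation of the bridge; cells innervating two glomeruli take the
innermost angle, which is already folded into the lists.

The turning signal is the right-minus-left sum of the 24 rates. It is
antisymmetric under joint reflection, `turn(-H, -G) = -turn(H, G)`, which
forces the zero heading to be exact at goals 0° and 180° and makes the
signed zero-heading error an odd function of the goal. Over a 0.5°-spaced
goal grid the error has mean zero and circular std 0.058°.

**Zero-crossing search.** `turn(H, G)` is evaluated on a 0.1° heading grid
(wrap-around included); a crossing is an interval where the signal passes
from positive to non-positive, refined by linear interpolation. Among
multiple negative-slope crossings the one nearest the goal is chosen. A
curve with no such crossing (possible under heavy silencing) yields an
undefined zero heading.

**9-column variant.** The alternative 9-column goal-angle assignment is
supported. The cell-to-column grouping is not printed anywhere we know of;
we infer it from the duplicated entries of the heading-preference lists
(cells 3–4, 6–7 and 9–10 of each hemisphere share a column), which yields
exactly nine groups of the twelve cells per side and preserves the mirror
symmetry. The variant produces a single negative-slope zero crossing per
goal, i.e. qualitatively the same steering behaviour.

**Silencing Monte-Carlo.** Per simulation a uniformly random subset of
cells (without replacement) is set to 0 Hz at all angles. Six evenly
spaced goal directions are each perturbed with wrapped-normal noise before
the zero heading is read off; the error is the absolute circular distance
to the unperturbed goal, and a direction counts as correct below 30° (the
behavioural criterion). An undefined zero crossing counts as maximally
wrong (180°, incorrect). The simulation grid is 0.5° for speed; the noise
amplitude is calibrated by bisection so the intact model matches a control
score. The published control flies' numeric score is not printed, so the
package default target is 5.0 of 6 directions; the direction of the
silencing effect is insensitive to this choice, and only the direction (not
the published 0.55–1.33 range, which depends on the unpublished control
value) is asserted.

**FC2-driven prediction.** Measured 16-column FC2 ΔF/F0 replaces the
cosine goal input: periodic linear interpolation to the 12 model columns,
then per-column min-max normalization to [-1, 1] over the whole recording.
Note this normalization only recovers the bump's spatial profile when the
bump visits all columns during the session; on a recording with a frozen
goal it degenerates to rescaled noise. The heading input is a bar-locked
synthetic compass signal: the bar plus a constant offset chosen so the mean
bar position matches the mean FC2 phase, then lagged 200 ms (nearest
frame) and sign-flipped. The alignment phase is decoded with anatomical
column angles (the negated preferred-goal angles), since the bump position
and the bar both live in brain coordinates. The lag is applied to the
offset bar series.

## Behavioural processing

Velocities are smoothed with a centred 500-ms boxcar; standstill is
filtered forward velocity ≤ 1 mm/s. Edge handling: the boxcar window
shrinks at the record edges; Gaussian filters use reflected padding (no
convention is canonical here, this one keeps DC gain exactly 1 in the
interior). The virtual trajectory integrates the forward/sideward velocity
vector rotated by the heading; heading 0 is +y by convention (arbitrary).
Bouts are the intervals between consecutive retained points of the
Ramer-Douglas-Peucker simplification (ε = 25 mm) whose endpoint-to-endpoint
displacement exceeds 200 mm; displacement, not path length, is used. Bout
goals are circular mean headings with standstill excluded; bar-jump
experiments instead use the pre-jump heading (a goal-assignment mode).
Bout boundaries do not clip standstill at their edges; standstill is
excluded only from the goal average. The 30-ms tracker latency correction
is an optional preprocessing shift (`behavior.shift_latency`); synthetic
data needs none.

The heading-stability series R removes standstill samples, concatenates
the record, and takes the resultant length of unit heading vectors in a
centred window (30/60/120 s) counted in retained samples.

## Imaging quantities

ΔF/F0 uses F0 = mean of the lowest 5% of each ROI's raw values over the
recording. Bump phase in the fan-shaped body is the population vector
average; the amplitude is normalized by the summed (rectified) activity so
it lies in [0, 1] and the thresholds 0.3 / 0.15 / 0.25 are scale-free (the
normalization is our choice; none is stated). Negative ΔF/F0 is clipped to
zero for phase decoding only and kept for bump metrics. The bridge phase
is a single-frequency Fourier projection at the anatomical period of 8.5
glomeruli over the 16-glomerulus vector — deliberately not an FFT bin, so
a uniform vector leaks a small amplitude; the decoded angle is the
transform's argument, whose sign convention is absorbed by the per-fly
phase-bar offset. Phase unwrapping uses shortest-arc differences.

Bar-jump trials zero the phase to its 1-s pre-jump circular mean and score
the final 1 s of the 2-s open-loop window, sign-flipping −90° trials.
Strict mode requires bout membership and return-to-heading (mean bar
5–10 s post within 30° of the 5-s pre-jump mean); both modes require a
visible post-jump bar and PVA > 0.3 throughout the scoring window. FC2
phase-jump detection finds peaks of the 500-ms-boxcar-filtered absolute
phase velocity (default floor 40°/s, a free parameter no source states)
with the PVA above 0.15 everywhere and 0.25 on average within ±1 s. LAL
transients require the 200-ms-Gaussian-smoothed right-minus-left signal to
exceed 0.1 for ≥ 1 s with prominence 1 and 3-s spacing; goal tuning
advances the LAL signal by 2 imaging volumes (~218 ms) and bins at 10°.

## Electrophysiology

Spikes are Butterworth-bandpassed peaks above a per-cell threshold spaced
by > 5 ms (corners and thresholds are configuration, as in the original
hand-tuned analysis); Vm within ±10 ms of a spike becomes NaN. Rates and
Vm are downsampled by interval averaging between camera triggers (counts
per interval divided by duration; no kernel smoothing). Heading tuning
uses 15° bins; the preferred heading is the phase of an exact linear
cosine fit to the spike-removed Vm curve. Goal-conditioned tuning uses 45°
bins of heading and goal relative to the preferred heading, with
right-side cells foldable into the left convention by negating both
relative angles. The five model parameters are fitted by bounded least
squares over populated bins with a multi-start over the preferred-angle
offset every 15° (initialization is not specified anywhere; the grid
avoids the circular parameter's local minima). Rate-versus-Vm alignment
bins Vm below −46 mV in 4 mV bins per goal bin and jointly fits per-bin
horizontal shifts and a common softplus; all shifts are free during the
fit and reported relative to the first populated bin. The 13 mV
junction-potential correction is an input convention, not applied here.

## Wind task

The allocentric wind direction is always the circular mean of bar minus
spigot over the wind-on window (the nominal set point can be off by up to
13°). Errors use the mean heading over the test windows of trials 2–3 per
block (standstill removed first); "correct" is error strictly below 30°.
The performance index is the hemifield time-fraction difference. A fly
with a fully-standstill block is excluded (raises), mirroring the study's
exclusion rule.

## Synthetic generators

The generators emulate the statistical structure each analysis assumes,
not the biophysics. Defaults, chosen once as field-typical values:

- **Agent**: 50 Hz; turning velocity = 1.0 (°/s)/Hz × the model's R−L
  signal; Brownian heading noise 30 °/√s (stationary heading scatter
  ~10–15°, matching stable menotaxis bouts); forward velocity
  2 + 8·max(0, cos(H−G)) mm/s, so walking slows when off-goal; ±90° bar
  jumps every 2 min with a 2-s open-loop hold during which the bar is
  frozen and closed loop resumes from the displaced position.
- **Bumps**: von-Mises profile (κ = 2.5), baseline 0.1, amplitude 1 ΔF/F0,
  Gaussian noise sd 0.05, first-order calcium kernel τ = 0.3 s (no
  indicator model is specified; first-order low-pass is the simplest
  consistent choice), 200-ms phase lag for heading-driven bumps, optional
  forward-velocity amplitude coupling. Bridge bumps are double
  (8.5 glomeruli apart). Ground-truth phase is the decoded phase of the
  noiseless filtered signal — the kernel's lag is not the decoder's to
  undo, so decode RMSE measures noise robustness only.
- **Spikes**: inhomogeneous Poisson at the single-cell model rate
  (matching the observed near-Poisson count variability); synthetic Vm
  traces inject stereotyped Gaussian waveforms for detector tests.
- **Wind cohorts**: 6 blocks × 3 trials, 30-s wind, test window 5 s after
  wind-off; control flies remember wind + N(0, 25°) per block and orient
  with 15° sample noise; compass-less flies hold a uniformly random
  heading in the test period; partially silenced flies steer via the
  lesioned model's zero heading with 30° goal noise. Cohort tables default
  to 10 Hz (the metrics are means; full 50 Hz adds nothing but rows).

Because the generators draw from the model itself, passing recovery tests
shows the *pipeline* is faithful — not that the model explains real flies.
Real recordings add motion artifacts, non-Poisson slow drift, phase
offsets between brain and arena, and behavioural idiosyncrasies that these
fixtures deliberately omit.

## Numerical notes and limitations

- Problem sizes in the examples, tests and acceptance script (0.5°
  simulation grids, 300–600 s sessions, 500-simulation Monte-Carlos,
  20-refit recovery experiments in the tests and 200 in the reproduction
  script) were chosen as the smallest sizes at which the quantities of
  interest are stable to well within their tolerances.
- Recovered parameters are aggregated across refits with the median: the
  softplus parameters trade off along a ridge, so the per-refit
  distribution of the output scale a is right-skewed and the mean
  overstates it; the median is centred on the generating value.
- Quantities that require the study's recordings (variance explained on
  real tuning data, phase-bar correlations, real silenced-fly counts) are
  out of scope; the recovery and symmetry analyses above are the testable
  surrogates.
- The softplus parameters a, b, c trade off along a ridge; under noise
  only their combination is well determined, so recovery is assessed on d,
  the angle offset, and a in the mean across refits.
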