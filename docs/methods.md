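# Methods

This note documents the models, conventions and numerical choices behind
`ambifocal`, in the spirit of a package methods appendix: what is computed,
under which assumptions, and what the synthetic benchmarks do and do not
demonstrate.

## Geometry and units

The display is described by its resolution (1024 × 768 px) and angular
radii (14.7° horizontal, 11.2° vertical at 71.5 cm). Pixel-to-degree
conversion is per-axis linear: `x_deg = (x_px − W/2) · half_width/ (W/2)`.
Exact tangent geometry would differ by < 2% at the screen edge; the linear
map is used because it is exactly invertible and the source display was
specified by its angular radii, not a projection model. Angular distances
are Euclidean in the flattened degree plane (small-angle convention).

All event intervals are half-open `[onset_ms, offset_ms)` in integer
milliseconds. This makes "fixations + saccades + blinks partition the
trial" an exact statement rather than an approximate one, and fixes every
boundary convention downstream (bin edges, interval slices, blink gaps).
Fractional input timestamps are rejected rather than rounded: silent
rounding would mask sample-rate errors.

## Event detection

Positions (in degrees) are boxcar-smoothed over `velocity_smooth_ms`
(default 3 ms) and differentiated with 2-point central differences
(endpoints replicated) to give 2-D speed and its time derivative. A saccade
candidate opens at the first sample where speed > 30 °/s OR |accel| >
8000 °/s²; the criteria are OR-combined at onset because that mirrors the
behaviour of the online parsers shipped with 1000 Hz video trackers, whose
published parameters these defaults are. The candidate must stay active for
≥ 4 ms and closes at the first sample where speed AND |accel| are both
below threshold. Completed candidates are kept when the start-to-end
deflection exceeds 0.1° — the deflection criterion is applied as a
post-hoc filter on completed candidates, not as an onset gate, and is
parameterisable. Amplitude is the angular distance from the onset sample to
the first post-saccade sample (not peak excursion).

Two boundary consequences of these definitions are deliberate and tested:

* at an instantaneous stop the |accel| criterion holds the candidate open
  one sample past the velocity run, so a planted linear ramp's offset is
  detected ~3 ms late while its onset is within 2 ms;
* each threshold criterion fails independently on NaN kinematics, so near
  blink edges a sample with valid speed but undefined acceleration can
  still open a candidate on the velocity criterion.

Blinks are maximal runs of missing pupil signal (NaN or 0 — the usual
video-tracker convention for lid closure). The default merge gap is 0 ms
(no merging), the literal reading of "periods in which pupil information
was missing". Samples inside blinks have their kinematics masked, so no
saccade candidate can span a blink; an explicit overlap check additionally
discards any candidate touching one. Fixations are the maximal uncovered
intervals; a fixation's `preceding_saccade_amplitude_deg` is set only when
a saccade's offset abuts its onset, so the first fixation of a trial and
any fixation following a blink remain unclassifiable.

## Cleaning cascade

Stages run in a fixed order — pre-onset → blink-adjacent → duration bounds
→ trial exclusion — because the tallies are order-dependent (an event that
is both blink-adjacent and too short is charged to the blink stage); a test
fixes the order by construction. Conventions:

* "within a 100 ms interval of a blink" = the gap between the half-open
  intervals is < 100 ms, symmetric before/after; overlap is a zero gap and
  always removed;
* duration bounds are strict ("shorter than 80 / longer than 1000"), so 80
  and 1000 ms fixations are kept;
* the trial-blink bound (4000 ms = 20% of a trial) is inclusive
  ("equal to or greater than");
* event-stage percentages are against the pre-cleaning fixation+saccade
  count, the trial stage against the trial count, and the total is the sum
  of stage percentages — the additive convention that reproduces the
  arithmetic of published exclusion tables.

Removed records are quarantined with their removal reason rather than
discarded, which makes the conservation property (kept + removed = input at
every stage) checkable and keeps the cascade auditable. Cleaning is
idempotent.

## Time-course model

Events are assigned to 500-ms bins by onset; participant means are computed
first and the grand mean and 95% CI are across participants (t
distribution, n−1 df). The aggregation unit is a parameter in principle
(participants vs trials vs events are all defensible), but participants are
the default because condition-level error bars in this literature are
across a fixed sample of observers. Bins are labelled by their END time
(bin 3 ↦ 1.5 s), matching how bins are named in the field; bins with fewer
than two participants are flagged and excluded from reach-time scans.

The model `y = b·e^(a/t)` is fit to the bin means by unweighted nonlinear
least squares (scipy `curve_fit`, tolerances 1e-10), initialised at b₀ =
mean of the last three bins and a₀ = slope of the OLS regression of log y
on 1/t. On noiseless data the log-linearised OLS solution is exact, which
provides the independent oracle used in the tests. The 95% CI for b is
t-based from the estimator covariance with (bins − 2) df. Fitting bin
means rather than raw events is intentional: the model describes the time
course of the *mean*, and unweighted means match the way such curves are
reported. For saccade amplitudes the first two bins are excluded
(`skip_bins=2`): amplitudes first rise to a peak at 1.5 s, which the
monotone model cannot express.

Time-to-asymptote is the t of the first (non-skipped) bin whose 95% CI
contains the fitted b, with no persistence requirement — only the first
such bin counts — and a "not found" result is a value, not an error. Note
that reach times shrink with sample size: wider CIs admit b earlier. They
are therefore comparable only within a fixed design.

## Classification and slicing

Ambient = preceding saccade amplitude > 5°, focal = ≤ 5° (the tie at
exactly 5°, a measure-zero event, goes to focal); no preceding saccade =
unclassified, and the three labels always partition the fixations. Early =
[0, 2) s and late = [6, 8) s, membership by event onset — an event
straddling a boundary counts where it began. The late window starts at 6 s
so that every condition has reached its fixation-duration asymptote by the
window's onset. Summary tables contain one row per participant × cell with
empty cells present (n = 0, missing mean); grand means are unweighted
means of participant means.

## Synthetic scanpath generator

Each trial alternates fixations and saccades from t = 0 until 20 s, with
the final event truncated at the trial boundary (and flagged by its
offset). Condition defaults take the published fitted asymptotes (fixation
durations 283.5 / 311.4 / 321.2 ms, saccade amplitudes 3.5 / 8.1 / 5.4°
for central / peripheral / control); acceleration-rate defaults (−0.15 /
−0.25 / −0.23 s and 0.3 / 0.4 / 0.4 s) were chosen once to land reach
times in the published 3.5–6 s range at the study's sample size.

* **Durations** are Gamma with shape κ = 6 and mean `b_fd·e^(a_fd/t)`;
  **amplitudes** are lognormal with log-sd 0.35. Only the means of these
  quantities are published; right-skewed families with these shapes are
  the standard empirical description, and both shapes are parameters. The
  generator's variances are conventions and must not be cited as
  reproducing any observed variance.
* **Curve clock.** The mean curves are evaluated at the end of the 500-ms
  bin containing the event onset — the same lattice the analysis bins on —
  rather than at the continuous onset time. With a continuous clock the
  realized mean inside a bin undershoots the curve at the bin's label
  (events early in the bin pull it down), biasing the fitted acceleration
  rate by 30–50% of |a|; the lattice clock makes the per-bin expected mean
  equal the curve at the label exactly, so parameter recovery is
  well-posed. The lattice also bounds the clock below by 0.5 s, which
  removes the t → 0 singularity of e^(a/t).
* **Mask-consistent targeting.** Under the central window, saccade
  endpoints must lie within 5° of gaze (amplitude ≤ 5°); under the
  scotoma, beyond 5°. Naive truncation of the amplitude distribution
  would shift realized means away from the condition curves — the curves
  describe *realized* (post-mask) means. The sampler therefore solves for
  the lognormal location whose conditional mean on the mask-feasible
  range equals the curve (Brent root-finding on the truncated-lognormal
  mean; solutions cached per bin). Where the target is infeasible (early
  central bins whose curve exceeds what a ≤ 5° distribution can average)
  the location is clamped to the achievable extreme; these are exactly the
  bins excluded from the amplitude fit. Directions are uniform, re-drawn
  up to 100 times to keep the endpoint on screen (amplitude capped at the
  farthest corner), with a clamp-and-recompute fallback.
* **Blinks** arrive at 0.12 /s and last Exp(150 ms); arrivals inside a
  fixation zero the pupil, mask gaze, and split the fixation (arrivals
  that would land inside a saccade are skipped), so the ground-truth
  events still partition the trial exactly. The cleaning cascade later
  removes the split fragments as blink-adjacent, which is why recovery
  runs are unbiased by blink splitting.
* **Rendering** to 1000 Hz samples uses a raised-cosine saccade velocity
  profile with duration ≈ 21 + 2.2·A ms, shortened for small amplitudes so
  the peak velocity (2A/D) clears the 30 °/s threshold whenever A ≳ 0.3°;
  Gaussian positional noise (sd 0.03°) is added during fixations.
  Event generation and rendering use separate child generators, so the
  event stream for a seed is identical with rendering on or off.

What the generator does *not* emulate: image-driven (saliency) targeting,
main-sequence variability beyond threshold-exceedance, pupil dynamics,
smooth pursuit or microsaccades, off-screen gaze and whole-scene occlusion,
or any scene-type effect (natural/urban labels are carried but do not
modulate the curves). Passing recovery tests therefore demonstrates that
the pipeline's estimators are consistent for data generated under its own
model assumptions — not that real recordings satisfy those assumptions.

## Problem sizes and known limitations

The multi-seed recovery and signature experiments in the test suite run the
design at 10 participants × 90 trials × 20 seeds at event level, a size
chosen to keep the experiments comfortably reproducible on one CPU while
leaving the per-condition Monte-Carlo error well below the tolerances
checked; the acceptance script runs the full 42-participant design once.
Sample-level detection accuracy is verified on individual rendered trials
and on 50 randomized ≤ 2-s streams against a brute-force oracle.

Known biases, all documented by tests: the 80-ms duration floor truncates
the left tail of early-bin durations, pulling the fitted acceleration rate
~10% toward zero (within the stated recovery tolerance, but systematic);
end-of-trial truncation drags the last bin's mean down slightly; and with
positional noise present the acceleration criterion can fire on noise,
producing occasional spurious micro-candidates that the deflection filter
mostly, but not entirely, removes — on real data such events are removed by
the cleaning cascade or by raising `min_deflection_deg`.
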