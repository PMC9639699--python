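# ambifocal

Eye-movement analysis for gaze-contingent scene viewing: event detection,
cleaning, and quantification of the ambient-to-focal transition.

## The scientific problem

When people freely view a scene, eye movements change systematically over
the first seconds: early *ambient* processing — large exploratory saccades
and short fixations that establish scene layout — gives way to *focal*
processing, with small saccades and long fixations on items of interest.
Gaze-contingent displays probe how central and peripheral vision contribute
to this transition: a *window* shows only the region within 5° of gaze
(central-vision condition), a *scotoma* occludes that region
(peripheral-vision condition), and a control condition leaves the scene
intact.

`ambifocal` is the analysis pipeline for such experiments. From raw 1000 Hz
gaze samples it:

1. **detects** blinks (missing pupil), saccades (speed > 30 °/s OR
   |acceleration| > 8000 °/s², sustained ≥ 4 ms, deflection > 0.1°), and
   fixations (the complement of the two);
2. **cleans** events with a four-stage cascade — pre-onset events,
   blink-adjacent events (< 100 ms gap), fixations outside 80–1000 ms, and
   trials with ≥ 4 s of blink — with full per-stage accounting;
3. **fits the time course**: measures are binned into 500-ms intervals by
   onset (participant means first, then across-participant mean with a
   t-based 95% CI) and the bin means are fit with the asymptote model

   &nbsp;&nbsp;&nbsp;&nbsp;*y(t) = b · e^(a/t)*

   where *b* is the asymptote and *a* the acceleration rate; the
   time-to-asymptote is the first bin whose 95% CI contains *b*. Saccade
   amplitudes skip the first two bins (they rise to a peak at 1.5 s before
   declining);
4. **classifies** each fixation as *ambient* (preceding saccade > 5°) or
   *focal* (≤ 5°), slices *early* (0–2 s) and *late* (6–8 s) windows, and
   exports tidy per-participant summary tables for any standard stats
   package (the rmANOVAs themselves are intentionally out of scope);
5. **simulates** the whole design — 42 participants × 90 trials (30 per
   condition, 15 natural + 15 urban scenes each) — as an alternating
   fixation–saccade process whose moments follow per-condition *b·e^(a/t)*
   curves, with mask-consistent saccade targeting, Poisson blinks and
   Gaussian gaze noise, returning ground-truth event tables so every stage
   is testable without recorded data.

The core operations are exposed as sklearn-style estimators
(`SaccadeDetector`, `EventCleaner`, `AsymptoteModel`,
`AmbientFocalClassifier`) with thin functional wrappers, plus an `af`
command line (`af simulate | convert | detect | clean | timecourse | run`).

## Worked example

```python
import ambifocal as af

cfg = af.SimulationConfig(seed=42, n_participants=6)
_, truth, manifest = af.simulate_dataset(cfg, render_samples=False)
result = af.run_pipeline(af.PipelineConfig(events=truth))

print(f"clean events: {len(result.events)}  "
      f"(removed {result.clean_result.report.total_pct:.1f}%)")
for cond in ("central", "peripheral", "control"):
    fit = result.fits[f"fixation_duration_ms/{cond}"]
    rt = result.reach_times[f"fixation_duration_ms/{cond}"]
    sa = result.fits[f"saccade_amplitude_deg/{cond}"]
    print(f"{cond:>10}: fd = {fit.b:6.1f} * exp({fit.a:+.3f}/t) ms, "
          f"asymptote reached at {rt} s;  sa asymptote {sa.b:.2f} deg")
```

prints

```
clean events: 64482  (removed 6.1%)
   central: fd =  283.0 * exp(-0.139/t) ms, asymptote reached at 2.0 s;  sa asymptote 3.50 deg
peripheral: fd =  307.6 * exp(-0.228/t) ms, asymptote reached at 2.5 s;  sa asymptote 8.10 deg
   control: fd =  314.5 * exp(-0.190/t) ms, asymptote reached at 2.5 s;  sa asymptote 5.41 deg
```

Reading this: each condition's fixation durations rise (*a* < 0) toward its
asymptote *b*; the central-vision condition plateaus lowest and earliest,
the control condition highest — and the fitted asymptotes recover the
generator's curve parameters (283.5 / 311.4 / 321.2 ms and 3.5 / 8.1 /
5.4°) to within about 1%. Reach times are earlier than in a full-size
sample because six participants give wide bin CIs. Note that under a 5°
window no saccade exceeds 5°, so the central condition has (correctly) no
ambient fixations.

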