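# chasescan

Tools for studying how eye movements support the detection of chasing
motion.  In the underlying task, an observer watches 14 white rings
moving at 14.5 deg/s inside an invisible 26 × 26 deg arena; one ring
(the chaser) relentlessly re-aims at another (the chasee) while the
rest move randomly, and the observer presses a button on spotting the
chasing pair.  `chasescan` re-implements that study as a fully
simulated, tested pipeline:

* **Stimulus simulation** — the chase display generator, including the
  heat-seeking chaser, wall bounces, and the rejection-sampled 3-deg
  minimum chaser–chasee distance of the distance-constrained (DC)
  trials.
* **Synthetic observers** — labeled 500 Hz binocular gaze emulating the
  two human tracking styles: group tracking of a close pair at gain
  0.75, or single-ring tracking at gain 0.97 with gaze alternating
  between the pair members.
* **Gaze preprocessing and event segmentation** — smoothing, gap
  interpolation, binocular fusion, resampling to the 85 Hz display
  rate, and extraction of fixations, saccades, slow/fast smooth
  movement (SSM/FSM), pursuit, exploration, and exploration vs.
  catch-up saccade labels (ES, CS1, CS2, …) from
  velocity/acceleration/duration thresholds plus gaze–agent proximity
  and direction criteria.
* **Template analyses** — rotationally aligned spatiotemporal samples
  around detections, saccades, smooth-movement episodes, or the
  ground-truth chase; PCA movies by Gram-matrix eigendecomposition;
  kernel-regression average templates; rail diagrams (time × on-axis
  position); ridge-line fits by simplex correlation maximization with
  the unimodal pattern max(0, 1 − |h/s|³), h(x,t) = (p + vt − x)/(1 + v²);
  linear-SVM classification movies; and the ideal-observer analysis on
  chase-centered samples.
* **Behavioral summaries** — log-normal detection-time fits, Bernoulli
  detection rates with bootstrap intervals, rolling ten-trial accuracy.

The interesting scientific output is the template structure: chase
appears in a rail diagram as two parallel ridges ~3.5–4 deg apart
moving at ~14 deg/s, and the first principal component of
chase-centered samples concentrates roughly 17% of the stimulus
variance — far more than gaze-locked detection samples achieve.

## Worked example

```python
from chasescan import (StimulusParams, generate_batch, io_samples,
                       io_analysis)

trials = generate_batch(StimulusParams(), 20, "mixed", seed=11)
samples = io_samples(trials, n=1500, seed=7)
res = io_analysis(samples)
print([round(v, 1) for v in res["var_percent"]])
print([round(v, 2) for v in res["ridge_speeds"]],
      round(res["line_offset_difference"], 2),
      round(res["inter_ridge_distance_at_lock"], 2))
```

prints (exact values vary slightly with the seed)

```
[17.9, 3.7, 3.2, 1.6, 1.4]
[14.2, 14.09] 4.28 3.75
```

Reading: the first principal component of 1,500 chase-centered samples
explains ~18% of the variance and its rail diagram shows two
near-parallel ridges travelling at ~14.1 deg/s — the chaser trailing
the chasee.  The two-line fit places the ridge offsets ~4.3 deg apart
while the empirical peak separation at the lock row is ~3.75 deg; the
fitted separation systematically exceeds the empirical one, so both
are always reported.

The `analysis/` directory holds numbered drivers that run the full
story on a simulated batch — stimulus geometry, synthetic observers,
event recovery, detection templates, the ES-vs-CS1 SVM contrast, the
ideal observer, and behavior summaries — writing tables under
`results/`.  The command-line entry point `chasescan`
(`simulate`, `synthgaze`, `events`, `io`, `behavior`, `run`) exposes
the same stages over plain-text trajectory and ASC-like gaze files.

## Documentation

`docs/methods.md` describes the stimulus model, the synthetic
observer, every event-segmentation rule, the template machinery and
its numerical safeguards, and the known limitations.
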