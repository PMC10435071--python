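# ofr — ocular following response analysis

Tools for analyzing **ocular following responses (OFR)**: short-latency
(~50–80 ms), reflexive slow eye movements that track the sudden motion of a
wide-field stimulus presented shortly after a centering saccade. OFR is a
workhorse behavior for studying sensory-motor transformation because it is
fast, stereotyped, and exquisitely stimulus-dependent: its onset latency and
eye speed vary with the postsaccadic delay, with the spatiotemporal
frequency of a grating stimulus, and with the congruence between saccade and
stimulus direction.

The package is aimed at oculomotor labs working with 500-Hz gaze recordings
(e.g. video eye trackers) and provides the full analysis chain plus a
ground-truth synthetic session generator, so every estimator can be
validated end to end without animal data.

## What it computes

* **Eye velocity** — Savitzky–Golay differentiation (order 3, 21 points /
  42 ms) of position traces, motion-onset alignment, projection onto the
  stimulus axis, trial averaging with pointwise SE. Signal loss and filter
  edges are masked, never extrapolated.
* **Onset latency** — global least-squares fit of the two-part piecewise
  linear model

      y(t) = a·c + b  (t < c),      y(t) = a·t + b  (t ≥ c)

  to the trial-averaged speed trace in a 30–150 ms window; `c` is the
  latency. Solved by an exhaustive changepoint scan with closed-form inner
  solves plus continuous refinement — deterministic, and verified against a
  dense brute-force oracle. Acceleration-threshold and baseline-deviation
  estimators are included for comparison.
* **Spatiotemporal tuning** — a 2-D Gaussian in log2 frequency fitted to
  eye-speed surfaces over spatial × temporal frequency, with the
  **speed-tuning index Q ∈ [0, 1]**: Q = 0 means separable tuning (preferred
  temporal frequency independent of spatial frequency), Q = 1 means pure
  speed tuning (preferred tf/sf constant). A nested F test assesses Q ≠ 0.
  Gain surfaces (eye speed / stimulus speed) are computed but never fitted.
* **Inference** — label-permutation tests for latency and speed slopes
  against condition values and for latency differences between groups,
  bootstrap SDs of means, pooled-variance two-sample t tests, and direction
  pooling (sign inversion of 180°/270° conditions) for congruence designs.
* **Synthetic sessions** — the three standard designs (postsaccadic delay
  6 × 2, frequency grid 7 × 6, direction congruence 4 × 2) with a generator
  whose noiseless response is exactly the flat-then-ramp form the latency
  model assumes, with planted latency-delay slope, gain decay, tuning
  surface, congruence factor, and per-sample position noise.

## Worked example

Simulate a postsaccadic-delay session (60 trials per delay × direction
condition), analyze it, and summarize:

```sh
ofr simulate --experiment delay --trials-per-condition 60 --seed 7 --out sess7
ofr analyze  --experiment delay --session sess7 --seed 7 --out rep7.json
ofr report   --in rep7.json
```

```
experiment: delay
median onset latency: 54.8 ms
  delay    10 ms: latency  50.00 ms, fixed-window speed 2.95 deg/s (n=120)
  delay    30 ms: latency  54.45 ms, fixed-window speed 2.53 deg/s (n=120)
  delay    50 ms: latency  54.88 ms, fixed-window speed 2.28 deg/s (n=120)
  delay   100 ms: latency  54.72 ms, fixed-window speed 1.63 deg/s (n=120)
  delay   200 ms: latency  61.17 ms, fixed-window speed 0.84 deg/s (n=120)
  delay   300 ms: latency  58.41 ms, fixed-window speed 0.45 deg/s (n=120)
latency_slope_vs_delay_ms: slope=0.02709, p=0.03297
window_speed_slope_vs_delay_ms: slope=-0.008449, p=0.000999
```

Reading this: latency rises and window speed falls with postsaccadic delay
(postsaccadic enhancement). "Fixed-window speed" is the mean speed in the
50-ms window starting 10 ms after the median latency (here 64.8–114.8 ms).
The slopes come from condition-mean regressions; their p values are
two-sided permutation probabilities from 1,000 label shuffles. The
generator's planted latency slope is 0.05 ms/ms — a single 720-trial session
estimates it with substantial sampling error (here 0.027), which is why
recovery checks in the test suite average over replicate sessions.

The same flow works with `--experiment tuning` (Q estimates, F tests, gain
surfaces per 60–110 / 80–130 / 100–150 ms window) and
`--experiment direction` (congruence t tests and latency-difference
permutation tests per axis). The library API (`ofr.run_experiment1/2/3`,
`ofr.fit_piecewise_latency`, `ofr.fit_tuning`, …) exposes everything the CLI
does; see `docs/methods.md` for the models, conventions, and limitations.

Recorded sessions enter through the two-CSV session format (samples +
trials tables with metadata headers) or `ofr.io.from_external`, which adapts
already-parsed dataframes via an explicit column mapping.

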