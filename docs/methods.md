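# Methods

This package analyzes ocular following responses (OFR): short-latency,
reflexive slow eye movements that track the sudden motion of a wide-field
stimulus after a centering saccade. It implements the full measurement
chain — velocity estimation, onset-latency fitting, spatiotemporal-frequency
tuning, and resampling inference — together with a synthetic session
generator that provides ground truth for every quantity the chain estimates.

## Velocity estimation

Gaze position is sampled at 500 Hz (2-ms step) in degrees of visual angle.
Velocity is the first-derivative output of a Savitzky–Golay filter of
polynomial order 3 and window length 21 samples (42 ms), scaled to deg/s.
This differentiator is exact for polynomial positions of degree ≤ 3, which
the test suite asserts to machine precision.

Edge samples (10 on either side) and any sample whose filter window overlaps
a NaN (signal loss) are masked invalid rather than padded or extrapolated;
padding would manufacture spurious acceleration at segment boundaries.
Trials are aligned to stimulus motion onset on a common −50 to +300 ms grid
and averaged pointwise (invalid samples excluded pointwise; a whole trial is
dropped if more than 25% of the grid is invalid — this threshold is
configuration, not a claim). The pointwise SE across trials accompanies each
mean profile. Analyses default to the signed velocity component along the
stimulus direction, `v_along = vx·cosθ + vy·sinθ`, so "negative = against
the stimulus" is unambiguous; horizontal/vertical components are selectable
for the direction-congruence analysis.

Averaging windows are half-open, `[start, start + 50) ms`, on the 2-ms grid.

## Onset latency

The primary estimator fits a two-part piecewise linear model to the
condition-mean speed trace in the 30–150 ms post-onset window:

    y(t) = a·c + b   (t < c)        y(t) = a·t + b   (t ≥ c)

with `c` the onset latency. Given `c`, the model is linear in `(a, b)`
through the regressor `u = max(t, c)`, so the fit scans every sample time in
the window as a candidate changepoint with a closed-form two-parameter
solve, then refines `c` continuously between the best grid candidate's
neighbours (bounded scalar minimization). The procedure is deterministic —
no random initialization — and ties in RSS are broken toward the smallest
`c` (earliest-onset convention). The grid-restricted changepoint is retained
in the diagnostics. A flat profile returns `a = 0` with `c` flagged
unidentifiable. Latency is only ever estimated on trial-averaged traces;
single-trial traces are too noisy for a stable changepoint.

Tests compare this optimizer against an independent dense brute-force scan
of `c` at 0.1-ms resolution (agreement ≤ 0.5 ms on noisy profiles) and check
Monte-Carlo accuracy (median |ĉ − c| ≤ 4 ms at mean-trace noise 0.3 deg/s).

Two alternative estimators are included for comparison: the first sustained
(≥ 3 samples) crossing of an acceleration threshold (default 40 deg/s²,
acceleration from the same SG differentiator applied to the mean speed), and
the first time mean speed exceeds the pre-response baseline mean + 1.5 SD.
The deviation estimator is markedly noise-sensitive (the tests demonstrate
its higher variance) and is not recommended.

## Spatiotemporal tuning and the speed-tuning index Q

Condition-mean eye speeds on the 7 × 6 spatial × temporal frequency grid
(0.04–2.48 cpd; 1.56–25 Hz) are fitted with a 2-D Gaussian in log2
frequency:

    y(sf, tf) = A·exp(−Δs²/σs²)·exp(−Δt²/σt²) + b
    Δs = log2(sf) − log2(sf0)
    Δt = log2(tf) − [Q·Δs + log2(tf0)]

`Q = 0` gives separable tuning (preferred TF independent of SF); `Q = 1`
puts the preferred-TF ridge on a constant speed `tf/sf = tf0/sf0`. Q is
bounded to [0, 1]. The temporal Gaussian is evaluated in log2(tf); an
alternative evaluation in linear tf is provided behind
`temporal_space="linear"` for sensitivity analysis, but only the log2
reading makes Q = 1 equal speed tuning, so it is the default. Note σt is in
log2 units under the default reading and in Hz under the linear one; the
reading is recorded with every fit.

Fitting is bounded nonlinear least squares (trust-region reflective) with a
deterministic multi-start over the observed argmax cell and its four grid
neighbours. Missing cells (e.g. conditions with too few trials) are dropped
from the fit with n adjusted; at least 10 cells are required. Significance
of Q uses a nested F test, `F = (RSS₀ − RSS₁) / (RSS₁/(n − 7))` on (1,
n − 7) df, where the reduced model is *re-optimized* over the remaining six
parameters with Q frozen at 0 — zeroing Q in the full fit would not give a
valid nested comparison.

**Boundary caveat.** When the true Q is exactly 0, the null hypothesis sits
on the boundary of the allowed parameter range, so about half of all noise
realizations leave the constrained estimate at Q̂ = 0 (F = 0) and the F test
rejects at roughly α/2 rather than α (measured ≈ 0.02–0.03 at α = 0.05 over
500 simulated null surfaces). The test is therefore conservative for
separable-tuned data; a significant result remains trustworthy.

Gain is eye speed divided by stimulus speed (`tf/sf` for a grating). Gain
surfaces are reported but never fitted with the Gaussian model: when the
optimum lies at the edge of the tested frequency range the fitted Q is
uninterpretable.

## Resampling inference

Randomization tests permute whole-trial condition labels. For the
latency-vs-delay slope, each permutation rebuilds the per-pseudocondition
mean traces, refits the piecewise model, and regresses latency on the
condition value (one point per level); the speed-vs-delay test uses mean
window speeds, where averaging commutes so permutations reduce to shuffling
per-trial scalars. Condition-mean regression (not trialwise) is used for
both responses — latency is only defined on condition means, and speed
follows for symmetry. p values are `(1 + b)/(1 + B)`, two-sided: strictly
positive and valid under exchangeability. Permutations that yield an
unfittable pseudocondition are recorded as failed and excluded, with the
count always reported. The latency-difference test for the congruence
experiment works the same way on two group-mean traces.

Bootstrap error bars are the SD of the bootstrap distribution of the mean
(default 1,000 resamples, seeded). The congruence comparison uses Student's
pooled-variance two-sample t test (df = n₁ + n₂ − 2); Welch's correction is
deliberately not the default so reported df match the pooled convention.

For the congruence experiment, trials with stimulus directions 180°/270°
have the relevant velocity component sign-inverted (an involution), then the
4 saccade × 2 relative-direction design collapses to identical-vs-opposite
groups per axis.

## Synthetic sessions

The generator emulates the trial sequence: eccentric fixation 5° from
center (200 ms), a raised-cosine centering saccade (30 ms, 5° — saccade
dynamics are unconstrained by the downstream analysis, which only uses the
post-saccadic epoch), a postsaccadic hold, then stimulus motion (300 ms)
plus a 70-ms recorded tail. The tracking response along the stimulus axis is
exactly the flat-then-ramp form the latency fit assumes: zero until

    c = base_latency + latency_delay_slope · delay,

then a linear ramp saturating at a plateau. A single multiplicative gain

    g = exp(−delay / gain_delay_decay) · congruence_factor^[identical]
        · (tuning surface term for gratings)

scales both the ramp slope and the plateau, so the entire noiseless
post-onset trace scales with condition gain and the rise time is
condition-invariant. This keeps the ramp fittable inside the 30–150 ms
window at every delay — scaling only the plateau would make long-delay
trials saturate within a few ms of onset and destroy the changepoint the
generator is supposed to plant. For gratings the gain term is the 2-D
Gaussian surface value normalized by its peak `A + b`, so measured window
speeds are proportional to the surface and the fit recovers the planted
(Q, sf0, tf0, σs, σt) exactly up to the A/b scale.

Default truth values are chosen to mimic a well-responding subject: base
latency 50 ms, latency-delay slope 0.05 ms/ms, base gain 0.2 at 30 deg/s
dot speed (peak speeds ≈ 6 deg/s), gain-decay time constant 200 ms
(exponential postsaccadic-enhancement decay), ramp slope 0.06 deg/s per ms
(≈ 100-ms rise), tuning peak at 0.16 cpd / 16 Hz with Q = 0.25, congruence
factor 1.3, and i.i.d. Gaussian position noise of SD 0.05° per sample.
White position noise through the SG differentiator yields single-trial
velocity noise of ≈ 2.3 deg/s per sample, which is what makes single-trial
latency estimation hopeless and trial averaging necessary, as in real data.

Reproducibility: one master seed; per-trial seeds derived by a stated
counter scheme (`(master · 1000003 + trial_id + 1) mod 2³¹`), so any trial
can be regenerated independently. Identical (spec, truth, seed) triples are
bit-identical.

What the generator does **not** emulate: blinks, microsaccades, glissades,
fixational drift structure, calibration error, or any correlated noise;
signal loss can be injected only as explicit NaN gaps. Passing recovery
tests therefore demonstrate correctness of the estimators under the stated
model, not robustness to every artifact of recorded eye data.

## Pipeline conventions

* Fixed speed windows start 10 ms after the median fitted latency across
  conditions (50-ms length); the offset-0 variant is always computed
  alongside, and delay-experiment speeds are additionally measured in 50-ms
  windows placed relative to each delay's own latency.
* Tuning analyses use three windows: 60–110, 80–130, 100–150 ms.
* Cells with fewer than 14 trials are flagged missing; an analysis aborts if
  more than half the cells are missing.
* Reports carry full provenance (config, seeds, trial counts) and are
  serialized as versioned JSON; sessions are two plain CSV files with
  metadata headers (format version, 500-Hz sample rate, deg/ms units).

## Problem sizes

The test suite and acceptance script size their simulations as follows:
recovery of the latency-delay slope uses 20 replicate sessions of 200
trials per delay × direction condition; congruence power uses 50 replicate
sessions of 16 trials per condition (64 trials per pooled axis, matching
the published scale); calibration rates use 400–500 null replicates with
199-permutation tests. These sizes give Monte-Carlo standard errors well
below the tolerances they are checked against.

## Known limitations

* The F test for Q is conservative at the Q = 0 boundary (see above).
* The changepoint scan guarantees the global grid optimum but refines only
  within the winning grid cell; a sub-grid global optimum two cells away
  would be missed (not observed against the brute-force oracle).
* The latency estimators assume the response keeps rising (or plateaus)
  through the fit window; oscillatory or transient responses violate the
  model.
* No binocular combination, calibration, or blink handling: upstream
  concerns.
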