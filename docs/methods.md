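# Methods

This note records the models and procedures the package implements, the
conventions that had to be fixed where the field's verbal descriptions
underdetermine them, and what the synthetic-data tests do and do not
establish about real recordings.

## Call acoustics

Each scored call contributes its duration and Wiener entropy, the log ratio
of the geometric to the arithmetic mean of its power spectrum. Conventions
(all recorded in `acoustics.SPECTRUM_META`): single-taper periodogram with a
Hann window over the whole call; DC bin excluded (offsets are acquisition
artifacts); natural logarithm (a base change only rescales values); bins
floored at machine-epsilon times the spectral maximum so pure synthetic
tones return a large negative value instead of −∞. Entropy is clamped at 0
from above; it is scale-invariant by construction. `segment_calls` (envelope
threshold, gap closing, minimum duration) is a convenience for unscored
audio — the canonical input is a verified call table.

## Locomotor activity

Raw motion is the mean absolute RGB difference per pixel between the first
and last frame of each second (channel differences summed, divided by the
pixel count — the "per pixel" reading; switchable). Because absolute pixel
differences scale with body size and camera geometry, the series is rescaled
within session: binarized at the session's 90th percentile (linear
interpolation between order statistics, strict `>` so a constant series is
all zeros) and smoothed with the p=0.10 spline, clamped to [0,1] (splines
through step data overshoot; the index is defined on [0,1]).

## ECG and the arousal index

Channel selection uses the ratio of the 95th-percentile to the median
absolute amplitude on the unmasked extent (spike-dominated channels score
high); ties go to the lower index. The chosen channel is resampled
40 kHz → 1500 Hz (polyphase, anti-aliased), high-pass filtered at 15 Hz
(4th-order Butterworth) and notch filtered at 60 Hz (Q=30), both zero-phase;
masked artifact regions propagate as NaN and each valid segment is filtered
independently.

Spike detection reports local maxima of the rectified signal above a
per-second adaptive threshold: the window's 95th amplitude percentile,
**floored at half the window's peak amplitude**. The floor matters at slow
rates: near 150 beats/min cardiac spikes occupy under 5% of a second's
samples, so a bare 95th percentile falls into the noise floor and admits
spurious spikes. A 50 ms refractory (half the minimum valid inter-beat
interval) keeps one maximum per spike, so the rectified pulse's second lobe
and notch-filter ringing are not counted twice.

Interval validation: ISI < 100 ms → the two spikes are replaced by their
midpoint, re-checked left-to-right until none remain (equivalent to
repeatedly fixing the first violation); ISI > 400 ms → the interval becomes
an invalid (NaN) region with both beats kept. Rates are obtained by binning
beats at 1500 Hz and convolving with a unit-area Gaussian kernel of σ=0.2 s
truncated at the 1 s window and renormalized — the `gausswin` convention for
a 1 s window (σ = L/(2·2.5)). A narrower σ=1/6 s (the ±3σ reading) ripples
by ~4% at 150–160 beats/min because it under-smooths the beat comb; σ=0.2 s
keeps end-to-end recovery error below 2% across 150–540 beats/min. Within
~10 ms of the 100 ms bound (above ~540 beats/min) detection jitter makes the
midpoint rule merge genuine beats — a property of the validation rule
itself, and a known limitation.

Sessions need rate coverage ≥ 50% (boundary inclusive). The arousal index is
the within-session mid-rank percentile of the 1 Hz rate scaled to [0,100]
(min → 0, max → 100, constant → 50), invariant under monotone transforms of
the rate. The first/last second are kernel-truncated; they are included.

## Smoothing splines

All curve fitting uses one engine: the natural cubic spline minimizing
`p Σ w_j (y_j − f(x_j))² + (1−p) ∫ f″²`, unit weights, solved via the
Reinsch/de Boor reduction to a pentadiagonal system in the interior second
derivatives (`scipy.linalg.solveh_banded`); the fit is the natural cubic
interpolant of its own knot values. Replicated abscissae (pooled traces,
pooled session curves) are collapsed to weighted means, which leaves the
objective unchanged; p=0 and fewer than four distinct sites fall back to the
weighted least-squares line. Tests verify agreement to 1e-8 with an
independent dense oracle that assembles the penalty quadratic form
numerically from curvature quadrature. The printed parameters — 0.10
(activity), 0.03/0.01 (individual/population trajectories), 0.1/0.3
(session/population peri-event), 1e-4 (developmental) — are meaningful only
under this convention.

## Maturity and transition days

Per session and domain, each behavior's share of scored domain time is
computed (overlaps summed, not de-overlapped; flagged). Sessions where the
domain was scored but a behavior never occurred contribute explicit zeros —
omitting them biases every trend. Classification fits
`proportion ~ day + (day|subject)` per behavior, Holm-corrects within
domain, and labels mature/immature by slope sign at adjusted p < 0.05; the
maturity index `m/(m+im)` is undefined (session skipped) when both times are
zero. Population trajectories (p=0.01) yield the transition day: the
earliest day where the spline reaches 0.5 and stays there for 3 days — the
persistence guard suppresses noise-driven first crossings. The 3-day window
and the 0.05-day search grid are fixed conventions.

## Peri-event dynamics and the scramble null

Windows (1 Hz samples, bin centers at t+0.5 s): locomotor activity −20…+5 s
around onsets and −5…+20 s around offsets; heart-rate percentile −10…+5 and
−5…+10. Windows clip at session edges with NaN padding. Session splines
(p=0.1) pool all of a session's trace samples; the population spline (p=0.3)
pools all session splines evaluated on the common grid. For display, a
±20 s axis stitches onset-anchored samples (rel < 0) to offset-anchored
samples (rel > 0), with the call interior excluded from band statistics.

Confidence bands resample 10 traces per session with replacement, refit both
spline levels, repeat 1000 times, and take pointwise 2.5th/97.5th
percentiles. The null band scrambles, per session and replicate, the
sequence of event durations and the sequence of inter-event gaps
independently (the leading silent stretch counts as a gap, so reassembly
starts at session start and preserves total occupied time), re-extracts
pseudo-event windows and refits. Developmental curves use each event's mean
signal during the event itself, averaged per session, splined over postnatal
day at p=1e-4; their CI resamples 10 per-event values per session and their
null recomputes event means after the scramble. All resampling is driven by
one seeded generator per band; identical seeds give identical bands.
Exceedance is pointwise (no cluster correction), reported as above / below /
inside plus contiguous runs.

## Mixed models

Gaussian models are REML fits with statsmodels `MixedLM`. The nested
structure `(x | day/subject)` is expressed as day-level random slopes plus
variance components for subject intercepts and slopes within day
(independent components — the exactly correlated nested structure is outside
`MixedLM`'s vocabulary); on singular or non-converged fits the ladder
descends to `(1|day/subject)` and then `(1|subject)`, recording the fallback.
Numeric covariates are standardized internally before optimization — with
day-scale slopes of order 1e-2 against unit responses the REML surface is
nearly flat in the slope variance, and optimizers stall at spurious optima —
and coefficients are reported back in per-original-unit terms. p-values use
a normal approximation to the t statistic; denominator-degrees-of-freedom
methods are software-specific, so the tested surface is sign and approximate
magnitude, not printed p-values. The logistic maturity model is fit as a
gaussian LMM on the empirical logit of the index (clipped at 0.025); the
day-coefficient sign and domain contrasts are the inferential targets.
Holm's step-down correction (via statsmodels, oracle-checked in tests) is
applied within the stated families: per behavior domain, the two acoustic
models, and the month-split reruns.

## Synthetic studies: what they emulate, and what they do not

The generator reproduces the emulated study's design: 7 subjects with
session counts (29, 29, 34, 34, 31, 31, 32) on distinct postnatal days in
1–61, 10-minute sessions, and the per-modality layout (audio 192, video 215,
ECG 149 sessions). Calls are a renewal process (exponential gaps at 5.7
calls/min) with truncated-normal durations (cry 1.2 ± 0.4 s, phee
3.0 ± 1.0 s). The logistic maturation schedule (midpoints 10/19/21 days,
slope 0.35/day) governs the expected mature *time share* within each domain,
so the maturity index crosses 0.5 at the configured midpoint even though
mature and immature bouts differ in duration; the implied per-bout count
probability is exposed separately. Behavior logs draw 70% of bouts from the
immature/mature pair (split by the schedule) and 30% from flat controls at
1.5 bouts/min. Motion is AR(1) positive noise (baseline 1.0, sd 0.25) plus
+1.5 during locomotor bouts, +0.8 during cries and −0.6 during phees.
Heart rate is an OU process (sd 20 bpm, τ=20 s) around 280 + 1·PND
beats/min, +30 during phees and +20 during locomotion, clipped to
[155, 590] so interval validation never deletes valid beats; beats come from
integrating the rate. ECG waveforms (biphasic ~20 ms pulses, peak 1.0,
configurable noise) are rendered on demand for short records; at full study
scale the 40 kHz corpus would be tens of gigabytes, so pipelines consume the
artifact-censored beat times directly and the waveform path is exercised on
short sessions.

Passing tests on these studies show the estimators recover *their own
generative structure* at study scale. They do not certify performance
against manual-scoring error, electrode motion artifacts beyond simple
masked dropouts, camera motion, overlapping callers, or real HRV structure.

## Problem sizes in tests and the acceptance script

Null calibration uses 200 uncoupled studies (2 subjects × 2 sessions,
240 s) with 1000 scramble replicates each; power uses 20 studies at the
default +30 bpm phee elevation (realized elevation ≥ 10 percentile points is
asserted, not assumed). Transition-day recovery uses 20 studies of
5 subjects × 25 sessions × 600 s (midpoints 10 and 20); sign recovery uses
100 simulations each of study-scale proportion-trend and call-type tables.
These sizes are the package's own choices for routine verification; all
scale knobs are plain function arguments.
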