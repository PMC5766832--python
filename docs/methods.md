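# Methods

`whisklearn` implements, as a tested pipeline, the analysis chain of
a head-fixed whisker-detection learning experiment: signal-detection
behavior, multi-area sensory-evoked potential (SEP) analysis,
time-resolved ROC decoding of single-trial LFP, spike-train modulation
testing, and the behavioral quantification of focal inactivation.
Because the pipeline is exercised against synthetic cohorts, this note
describes both the analysis conventions and the generative model, and
is explicit about what passing tests do and do not establish about
real recordings.

## Task and behavioral quantification

The detection task is go/no-go: stimulus trials (a brief single-whisker
deflection) and catch trials (no deflection) occur at random 6–12 s
inter-trial intervals, interleaved with 50% catch probability, without
predictive cues. A lick within the 1 s response window after a stimulus
is a hit (rewarded); within the window of a catch trial, a false alarm.
A lick during the 3–4 s no-lick window preceding a scheduled trial
aborts it; aborted trials never enter rate denominators. Licks within
100 ms of the stimulus are flagged premature: they still count toward
the hit rate (the animal was rewarded), but premature trials are
excluded from hit-conditioned evoked-response averages, since such
early licks are chance licks rather than stimulus responses. Whether premature
hits belong in the hit rate is a genuine convention choice; this
package counts them, and only the evoked-response averages are
sensitive to it.

Per-session sensitivity is

    d' = Z(hit rate) − Z(false-alarm rate),

with Z the standard-normal quantile function. The loglinear correction
— hit rate (n_hit + 0.5)/(n_stim + 1), FA rate (n_fa + 0.5)/(n_catch + 1)
— is applied to every session, not only to extremes, so d' is finite
at 0% and 100% rates and no session-dependent rule is needed. Z is
implemented by Acklam's rational approximation refined with one Halley
step; |CDF(Z(p)) − p| < 1e-9 over (0, 1), verified against an
independent high-precision quantile oracle in the tests.

Trained-condition sessions are the first three training days with day
index > 4 and d' > 1; neutral-exposure analyses use the last three
exposure days.

## Synthetic cohorts

The generator produces sessions with the statistical structure the
analyses assume; defaults are the study's conditions (14 mice, 8 days,
200 trials/session for detection; 12 mice for neutral exposure; 8 mice
for optogenetics).

**Behavior.** The hit probability follows a logistic curve in training
day (half-maximum at day 3.5, slope 1 day, asymptote 0.80) above a
constant false-alarm rate of 0.16, so trained mice reach the
typical performance scale of this task (hit rate ≈ 0.79, FA ≈ 0.16,
d' ≈ 2 after 5–12 days of training); the learning midpoint and slope
are free parameters of the scenario. Licks form a
short ~7 Hz bout; 5% of response licks are premature; 8% of trials are
aborted (the aborted-trial rate is a free scenario
parameter). In the neutral-exposure paradigm the lick train is a
session-long Poisson process (0.22 s⁻¹) statistically independent of
stimulus times, so stimulus-conditioned and unconditional lick
probabilities coincide by construction.

**LFP.** Each area's evoked kernel is a difference of exponentials with
configured onset latency, peak time, polarity and decay constant (the
rise constant is solved from the peak time); the functional form is a
modeling choice — real evoked waveforms have no canonical parametric
form.
Latencies run 8 ms (wS1) to 22 ms (mPFC), peaks 20–45 ms, all under
50 ms; polarity is negative (depolarizing-compatible) everywhere except
mPFC. Peak amplitude is `base + gain·d'` µV — gain 0 for wS1/wS2
(sensory responses present from day 1 and stable), 50–60 µV per d' unit
for mPFC/dCA1 (responses that develop with learning), intermediate for
wM1/PtA — multiplied by 1 + hit_gain on hit trials (0.3 in mPFC/dCA1,
0 in wS1, matching the absence of an early hit–miss difference there),
and by a lognormal per-session gain (sd 5%) emulating day-to-day
response variability in chronic recordings. In neutral-exposure
scenarios the d' coupling and hit gain are forced to zero and the
mPFC/dCA1 bases are near zero: stimuli evoke stable sensory responses
but nothing develops. Noise is AR(1) Gaussian (marginal SD 40 µV,
coefficient 0.98 at 2 kHz ≈ 25 ms correlation time, giving an LFP-like
low-frequency spectrum). A 1 ms, 4 mV artifact impulse is injected at
each stimulus onset so the artifact-removal stage is always exercised.

**Spikes.** Units are inhomogeneous Poisson: baseline 5 Hz, with a
rate increase (positive units) or decrease (negative units) during the
1 s post-onset window of stimulus trials, depth 50% of baseline on hits
and 40% of that on misses. One third of units are positive, one third
negative, in exact programmed proportions. Trough-to-peak durations are
a two-component Gaussian mixture (RSU 0.60 ms, FSU 0.25 ms, SD
0.05 ms, 20% FSU); the RSU/FSU boundary is 0.35 ms (≥ is RSU), a
field-standard default exposed as a parameter.

**Reproducibility.** All randomness derives from one master seed
through fixed per-stream/per-mouse/per-day substreams
(`default_rng([seed, stream, mouse, day])`), so cohorts are
reproducible and independent of generation order.

## SEP pipeline

Continuous LFP is cleaned by blanking [0, 2] ms after each stimulus
(linear interpolation) and band-passing 0.1–100 Hz with a 4th-order
Butterworth applied forward-backward (zero phase); the band is the
standard one for evoked-potential work, and the filter order and
artifact window are package conventions.
Epochs span −50 to +300 ms around onsets (catch trials use their
scheduled virtual onsets); each epoch subtracts its own 50 ms baseline
mean. Filtering runs in single precision when the input is single
precision; the ~µV error is negligible against the signals and the 10%
amplitude tolerances used throughout.

**First peak.** The first peak of an averaged SEP is the earliest
local extremum of the area's polarity within 3–100 ms whose magnitude
exceeds 2× the waveform's noise level. Two refinements matter in
practice. First, the noise level is the larger of the baseline SD and
the median per-sample SEM: per-epoch baseline correction whitens the
baseline of the average, so the baseline SD alone underestimates the
ripple in the rest of the waveform. Second, the search is anchored at
the response onset (first sustained supra-threshold crossing) when one
exists, so isolated pre-response ripples are not mistaken for the
peak. Even so, on strongly averaged data a slow-noise excursion
occasionally merges into the response onset and pulls the estimate off
by tens of ms; in cohort simulations this affects ≲5–10% of
mouse×area estimates, which is why cohort-level checks use robust
(fraction-within / median) aggregation.

**Condition contrasts.** Conditions (first-day vs trained/exposed, hit
vs miss) are measured at one fixed peak time per mouse and area, at the
nearest sample. The peak time is determined on the pooled average of
*all* analyzed sessions (D1 plus the reference days, one equal weight
per session) rather than on the reference condition alone: selecting
the time of the reference condition's own extremum measures that
condition at its own noise maximum and biases paired contrasts toward
spurious "growth" — a ~1 µV effect that null cohorts resolve easily.
With equal per-session weights, every session's noise has the same
covariance with the selection statistic, so the selected time point is
unbiased between conditions. Hit-conditioned averages
exclude premature trials. Day-by-day amplitudes for the amplitude-vs-d'
correlation are polarity-rectified (response magnitude), so learning-
driven growth is positive regardless of the area's polarity.

**Onset latency** is the first time after onset where |waveform| stays
above 2× the noise level for ≥5 ms. Onset-latency estimators have no
standard definition; this one is a documented convention.

**Statistics.** D1-vs-reference and hit-vs-miss waveform differences
are tested per 5 ms window with the paired Wilcoxon signed-rank test
across mice, reported uncorrected per window (mirroring a color-coded
significance display; noted prominently: ~5% of windows are expected
significant under the null). Amplitude-vs-d' association uses Pearson
r with the two-sided p from t = r√(n−2)/√(1−r²). Across-area
latency/peak-time orderings use the joint-ranking all-pairs procedure
below.

## ROC decoding (Stimulus Probability)

Single-trial mean LFP amplitude in 10 ms windows slid by 2.5 ms is
compared between stimulus and catch trials; the ROC area is the
Stimulus Probability (SP) for that window. SP equals the Mann-Whitney
U statistic over n_s·n_c with ties counted ½, the standard ROC tie
convention. Features are
polarity-aligned per area so that a detectable evoked response always
drives SP above 0.5; the sign flip leaves the shuffle null unchanged.
Chance bands are the per-window mean ± SD of SP over 100 within-session
label permutations, seeded and deterministic. Curves are computed per
session, averaged within mouse, then grand-averaged with SEM across
mice; computing per session before pooling keeps sessions
exchangeable.

## Spike pipeline

PSTHs use 10 ms bins (a package default, exposed as a parameter),
normalized to Hz by trials × bin width; z-scored PSTHs use
the −1–0 s baseline. Modulation is tested on hit trials: per-trial
(post − pre) rate differences over the 1 s windows around onset,
bootstrap-resampled 1000 times; p_pos is the fraction of bootstrap
means ≤ 0 and p_neg the fraction ≥ 0, with class positive/negative when
the corresponding fraction falls below α/2 = 0.025, so the overall
two-sided level is α = 0.05. Hit-vs-miss differences per unit use a
two-sided permutation test on the post-window rates, a package
convention.

## Inactivation

Optogenetic sessions flag 30% of trials (stimulus and catch alike) as
light-on; hit and FA rates are computed per mouse for each light state
and compared with the paired Wilcoxon signed-rank test. Muscimol
sessions are scored in the 5 min block starting 30 min after the
injection (half-open [1800, 2100) s on the injection-anchored clock)
and compared per area against a single pooled Ringer's control group
with the Mann-Whitney test, Holm-adjusted across tested areas. The
generator models inactivation purely as multiplicative effects on hit
probability (defaults 0.3–0.4 in wS1/wS2/dCA1/mPFC, 1.0 in wM1/PtA),
not as physics.

## Nonparametric statistics

The statistics used across the pipeline are implemented in-package
with exact small-sample behavior and are cross-checked against
independent oracles (full enumeration, permutation, and established
library implementations) in the test suite:

- Wilcoxon signed-rank: zero differences dropped (standard
  convention; all-zero input returns p = 1); exact null by dynamic
  programming for n ≤ 25 without ties, tie-corrected normal
  approximation with continuity correction otherwise.
- Mann-Whitney: exact null for min(n) ≤ 8 without ties; tie-corrected
  normal approximation otherwise.
- Holm: step-down, monotone, capped at 1.
- Dunn-Holland-Wolfe across-group comparison: realized as the
  joint-ranking all-pairs procedure — pool all observations, midrank, and declare pair (i, j)
  different when |R̄_i − R̄_j| exceeds
  z_{1−α/(k(k−1))} · √(S(1/n_i + 1/n_j)), with S the tie-corrected
  rank variance N(N+1)/12 − Σ(t³−t)/(12(N−1)). A permutation
  max-rank-difference oracle bounds disagreement on small samples.

## Problem sizes and what the tests show

Cohort-scale tests run at the study's sizes: 14 mice × 8 days ×
200 trials (detection), 12 mice (neutral exposure), 7 mice × 60 units
(spikes), 8 mice × 6 areas (optogenetics), 20 cohort seeds for the
inactivation significance pattern. To keep simulation affordable the
detection-cohort dissociation test analyzes the three-area panel
wS1/dCA1/mPFC (the uncoupled vs coupled contrast), and neutral-cohort
LFP is generated only for the days the analysis uses (day 1 plus the
last three); neither choice alters the analyzed conditions. The
neutral-exposure pattern (six uncorrected null tests per cohort, each
with a ~2.5% chance of a spurious one-directional "increase") is
evaluated over three independent cohorts requiring the pattern in at
least two, which is the test-level analog of the qualitative claim.

Passing these tests establishes that the pipeline is calibrated (null
tests reject at their nominal rates), recovers programmed effects at
realistic noise, and dissociates learning-coupled from stimulus-driven
signals under the generative model above. The generator does not
emulate inter-areal correlations, oscillatory structure, movement or
lick artifacts beyond the stimulus impulse, electrode drift, or
non-Poisson spiking; conclusions about real recordings inherit those
caveats. Quantities measured on real recordings (specific correlation
values, modulated-unit percentages) depend on the data; the synthetic
cohorts target the same qualitative structure and realistic
magnitudes, not any particular dataset's numbers.

## Degenerate inputs and tie-breaks

Validation errors name the offending field. A session with no catch
trials has no defined FA rate and is rejected. Flat waveforms yield an
explicit no-peak result, not an exception. An RSU/FSU duration exactly
at threshold is RSU. Muscimol block membership and all windows are
half-open [a, b). An empty spike train yields an all-zero PSTH. The
signed-rank test with fewer than 5 pairs cannot reach two-sided
p < 0.05 and warns accordingly.
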