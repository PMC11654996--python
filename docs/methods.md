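# Methods

## Scope and model of the experiment

The package reconstructs the computational chain of a mobile
heartbeat-synchronized visual stimulation setup: a wrist- or arm-worn PPG
sensor (134 Hz) detects pulse peaks live and triggers a flash of a virtual
body's silhouette; a clinical ECG (240 Hz) provides the reference beat
annotation for validating the detector; an asynchronous control condition
flashes at 80/90/110/120 % of the actual heart rate; and a within-subject
study protocol (2 synchronous + 2 asynchronous 5-minute blocks, randomized,
pain measured before and after each block) yields the outcome tables the
analysis module reduces and tests.

## Synthetic signal generator

**Beat times.** Inter-beat intervals are i.i.d. truncated normal with mean
`60/HR` and SD `hrv_sd_s`, truncated to [0.3, 2.0] s (30–200 bpm). A
truncated normal was chosen over autoregressive or respiratory-sinus
models as the simplest distribution with independently controllable mean
and variance; the first beat is at t = 0 and generation is fully
deterministic under a seed.

**PPG morphology.** Each beat contributes the sum of two Gaussians: a
systolic peak (σ = 70 ms, unit amplitude) delayed by the pulse-transit
time, and a dicrotic bump (amplitude 0.35, σ = 90 ms, +250 ms). This is
the minimal shape with a unique primary peak per beat, which is all the
peak-reporting detector contract needs. Pulse-transit defaults: 0.25 s
(wrist) and 0.20 s (upper arm), emulating the two sensor positions.

**ECG morphology.** A narrow dominant R spike (σ = 12 ms) with small Q/S
side dips; no P/T waves. The R spike is the unambiguous argmax near each
beat time, which is the property the reference annotator relies on.

**Noise.** Additive: sinusoidal baseline wander, white Gaussian sensor
noise, and motion artifacts modelled as Gaussian-windowed (σ = 150 ms)
damped 3 Hz oscillations — deliberately inside the pulse passband so they
genuinely challenge the detector. The "moderate" profile (wander amplitude
0.3 at 0.25 Hz, white SD 0.05, ~0.6 artifact bursts per minute with
amplitudes 0.5–1.2 relative to the unit pulse) is a plausible rendering of
the minor motion/breathing/sweating artifacts wearable recordings show; no
recorded data exist to calibrate it against, so these levels are free
parameters fixed once. What the generator does **not** emulate: pulse-wave
morphology changes with vascular tone, sensor saturation, respiratory
sinus arrhythmia, ectopic beats. Passing tests therefore demonstrate
correctness of the pipeline's logic and its noise robustness *within this
noise model*, not performance on real recordings.

## Causal PPG detector

Pipeline (single pass, no lookahead):

1. causal Butterworth band-pass, 0.5–8 Hz, order 2 (`lfilter`, forward
   only) — removes wander and high-frequency noise while keeping the
   systolic upstroke sharp;
2. slope-sum: running sum of the positive filtered derivative over a
   100 ms window — emphasises upstrokes over dicrotic bumps;
3. adaptive threshold: an exponentially decaying envelope of the slope-sum
   peaks (half-life 3 s) scaled by 0.4; the envelope tracks slow amplitude
   drift from sweating or contact changes. An absolute floor (1e-9) keeps
   flat-line input silent;
4. confirmation: after the threshold is crossed (armed state), the beat is
   emitted at the first downward zero-crossing of the filtered derivative,
   i.e. one sample after the filtered peak. A 0.3 s refractory period
   (200 bpm ceiling) and a 0.5 s startup blanking suppress double-fires
   and the filter transient. Plateau ties resolve to the earliest sample,
   minimising latency.

The causal filter delays the systolic peak by a constant ≈15 ms at 134 Hz
(measured on the synthetic pulse shape); emission adds one sample
(7.5 ms). Both are constant, so validation removes them as part of the
physiological pulse-transit offset; the end-to-end decision latency
(emission minus true peak) is ≈22 ms, inside the 50 ms budget, and is
asserted against ground truth in the tests. The detector standardises on
the systolic *peak* as its fiducial (not the foot or maximum slope); all
validation interprets beat times accordingly.

A vectorised driver runs the identical state machine with NumPy filtering
for speed; equivalence with the sample-by-sample streaming path is tested,
not assumed.

The ECG reference annotator is offline by design: zero-phase 5–40 Hz
band-pass (with 1 s internal zero-padding so edge beats survive the
filter), squared-energy smoothing over 80 ms, peak picking at 20 % of the
99.9th-percentile energy with a 0.25 s minimum distance, and R refinement
to the local band-passed argmax (±50 ms).

## Validation metrics

Matching first removes the median measured-minus-reference offset (the
constant pulse-transit plus processing lag is physiology, not error), then
pairs each reference beat with the nearest unclaimed measured beat within
a 0.4 s tolerance, greedily in time order. Greedy-nearest on sorted series
with a tolerance below half the minimum plausible interval is one-to-one
and order-preserving; tests cross-check it against an optimal assignment
oracle.

Interval RMSE is relative to each *reference* interval and reported in
percent — the only normalisation that makes an interval RMSE unit-free and
poolable across heart rates. Intervals are formed only between beats
matched at consecutive reference indices, so a missed beat breaks the
interval chain rather than producing one long spurious interval. Missed
beats are unmatched reference beats interior to the measured record;
reference beats before the first or after the last measured beat are
edge-excluded, and `matched + missed + edge-excluded = n_reference` is an
enforced invariant. Pooling reports the across-recording mean and sample
SD of RMSE and summed beat/miss totals; a single recording's SD is
undefined and flagged.

One reading of the source material conflates "RMSE of X %" with "wrong in
X % of cases"; this package implements the former (a relative
root-mean-square error), which is the only interpretation under which an
RMSE carries a percent sign.

## Stimulation engine

Synchronous schedules place one onset per beat at `beat + lag` with
`lag = 50 ms` by default (sensing + transport). Asynchronous schedules
integrate `interval = 60/(factor · HR(t))` forward from t = 0, re-drawing
the factor uniformly from {0.8, 0.9, 1.1, 1.2} at every 60 s boundary. How
often the original apparatus re-drew its factor is not documented;
per-minute re-draws keep the rate non-trackable while remaining testable,
and the epoch length is a parameter. A factor of 1.0 is rejected — it
would be synchronous stimulation. The flash envelope jumps to peak
brightness at onset and decays exponentially (τ = 0.4 s default; "slow
fade" is unquantified, so τ is exposed in configuration); overlapping
flashes take the maximum. Session plans draw a uniform permutation of
{sync, sync, async, async} (300 s blocks, 180 s rests).

## Study analysis

Questionnaire composites are unweighted item means: 3 usability items
(1–5), 7 sickness items (1–4), 7 ownership items (0–6; the published
analysis reports a single per-condition score without defining it, and the
item mean is this package's choice). Pain deltas: per block, the bilateral
(left/right) mean per phase; the signed difference is `post − pre` for the
fixed-pressure rating instrument (higher rating = more pain) and
`pre − post` for the pressure-threshold instrument (lower threshold = more
sensitive), so *positive always means increased pain sensitivity*; the
condition delta is the mean over the condition's two blocks. Missing
phases or sides raise an error naming every offending cell.

Paired contrasts are normality-gated. "Kolmogorov–Smirnov test of
normality" with estimated mean and SD is the Lilliefors variant, which is
what `statsmodels.stats.diagnostic.lilliefors` provides; a plain KS test
against a fixed normal would be anti-conservative here. If normal
(p > 0.05): one-sided paired *t* test, direction `sync < async` (the
analgesia hypothesis). Otherwise: Wilcoxon signed rank with Pratt handling
of zero differences, average ranks on ties, and the normal approximation
for p (reported with Z). The reported statistic is W⁺, the sum of
positive-difference ranks. All-zero differences yield a degenerate report,
not an exception.

## Synthetic study tables

The generator emulates a 20-participant cohort. Questionnaire items are
discretised clipped normals centred on the published item means/SDs;
ownership items are near-floor (geometric, clipped to 0–6); pain tables
contain a full randomized session per participant with baseline NRS ≈ 3
(SD 1.2) and thresholds ≈ 350 kPa (SD 80 across participants), per-reading
noise of 0.4 NRS points and 30 kPa (each stored threshold the mean of 3
repetitions), and **no true condition effect** — the study's null result
is the default condition, with `sync_effect_*` hooks to inject true
effects for power simulations. Group-level published outcomes (specific
delta means, the ownership Z) depend on the original per-participant data
and are not reproducible from summaries; tests therefore check the
machinery by oracle equivalence and simulation, with the usability
composite from the published item means (4.42) as the exact in-source
check. The sickness composite of the published item means is 1.116, which
differs from the published participant-level mean (1.175) because item
means rounded to two decimals do not commute with participant-level
averaging; it is reported as computed.

## Numerical choices and problem sizes

Seconds as floats, t0 = 0 at trace start; all beat times in trace time.
All randomness flows from explicit integer seeds via `numpy` Generators;
derived seeds stay below 2³¹. The acceptance script measures detector
quality on 20 five-minute recordings per noise condition (~7,000 reference
beats, comparable to the study's >6,500), heart-rate recovery on one
300 s recording, asynchronous rate accuracy over 600 s per factor, and
session-ordering uniformity over 60,000 seeds; these sizes keep the full
run under a minute while leaving Monte-Carlo error well below the margins
being checked.

## Known limitations

Real PPG failure modes (saturation, perfusion loss, arrhythmia) are out of
the noise model, so the detector's real-world missed-beat rate cannot be
inferred from these simulations. The matching tolerance (0.4 s) assumes
heart rates below ~150 bpm in the validation context. The Wilcoxon normal
approximation is coarse below n ≈ 10; exact enumeration is used only as a
test oracle. WFDB-style record/annotation I/O is not implemented; traces
and beat lists travel as the documented CSV formats.
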