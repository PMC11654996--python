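# cardiosync

Cardiac biosignal simulation, real-time PPG beat detection, ECG-referenced
validation and heartbeat-synchronized stimulus scheduling — the
computational chain of a mobile cardiovisual full-body-illusion setup, plus
the outcome analysis of the accompanying within-subject pain study.

## The problem

In cardiovisual stimulation experiments, a virtual body's silhouette
flashes in synchrony (or deliberate asynchrony) with the participant's
heartbeat to manipulate body ownership. A mobile setup senses the heartbeat
with a wrist/arm photoplethysmography (PPG) sensor sampling at 134 Hz, so
the beat must be detected *live*, within a ~50 ms budget of the systolic
peak, or the felt pulse and the shown flash fall out of synchrony. The
detector's output is judged against a clinical 240 Hz ECG reference with
two metrics:

* **relative interval RMSE** — for matched peak-to-peak intervals with
  reference value `r_i` and measured value `m_i`,

  `RMSE (%) = 100 · sqrt( mean( ((m_i − r_i)/r_i)² ) )`

* **missed beats** — reference beats with no detected partner, visible as
  gaps spanning more than one reference interval.

The asynchronous control ("shuffling mode") flashes at 80, 90, 110 or
120 % of the actual heart rate; sessions are 2 synchronous + 2
asynchronous 5-minute blocks in randomized order. Outcomes (usability and
sickness questionnaires, pressure-algometry pain deltas, body-ownership
scores) are reduced and tested with a normality-gated paired pipeline:
Lilliefors-corrected Kolmogorov–Smirnov on the paired differences, then a
one-sided paired *t* test if normal, otherwise the Wilcoxon signed-rank
test.

No recordings ship with the package: a synthetic generator produces
ground-truth beat times (truncated-normal inter-beat intervals) and renders
PPG (two-Gaussian pulse, configurable pulse-transit delay) and ECG (narrow
R spike) traces with controllable baseline wander, sensor noise and motion
artifacts, so every stage is testable end to end.

## The detector

Causal and single-pass, as a wearable requires: Butterworth band-pass
0.5–8 Hz (order 2, forward only) → slope-sum over a 100 ms window →
adaptive threshold (exponentially decaying peak envelope, half-life 3 s) →
beat confirmed at the first post-threshold downward zero-crossing of the
filtered derivative. Confirmation lands one sample after the filtered peak;
with the filter's constant ~15 ms peak lag the decision latency stays well
inside the 50 ms budget.

## Worked example

```
$ cardiosync demo --seed 42 --out-dir demo_out
demo report -> demo_out/report.json
```

runs the whole synthetic pipeline (simulate → detect → validate →
schedule → analyze). From `demo_out/report.json`:

```
"detection": {
  "n_true_beats": 141, "n_detected": 141, "n_reference": 141,
  "rmse_percent": 3.68, "n_missed": 0, "n_extra": 1,
  "max_decision_latency_s": 0.0075
}
```

On a 120-s moderately noisy recording the causal detector found all 141
beats the ECG reference annotated (one extra detection from a motion
artifact), with a 3.7 % relative interval RMSE and a 7.5 ms decision
latency. The report also carries the randomized session plan, the flash
schedules (141 synchronous onsets; 382 asynchronous onsets — the shuffled
factors average below 1 over this draw), questionnaire composites from a
simulated 20-participant cohort, and the paired condition tests on the
pain deltas, none of which reach significance because the generator
injects no true condition effect. Two runs with the same seed produce
byte-identical reports.

The same steps are available individually (`simulate`, `detect`,
`validate`, `schedule`, `analyze`) on CSV traces, beat lists and study
tables; see `cardiosync --help`.

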