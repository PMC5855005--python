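# gaitphase

Real-time gait phase detection from two-channel ground contact forces.

Wearable gait analysis commonly places two force sensitive resistors (FSRs)
under the ball and heel of a shoe and reduces each force trace to a binary
on/off-ground status by thresholding. A constant threshold either has to be
set per wearer (body-weight fractions) or needs the whole recording
(span-based methods), so it cannot track different people or walking
speeds online. `gaitphase` implements a **self-tuning triple-threshold
detector** that adapts per gait cycle, in real time, plus the standard
constant-threshold baselines, phase/event labelling, reliability scoring,
and a synthetic gait-force generator so the whole system can be exercised
without recorded data.

Each sensor channel keeps three ordered thresholds `t_l < t_m < t_h` and
retunes them once per cycle from the cycle's own extrema `T_max` (tracked
while `f ≥ t_h`) and `T_min` (tracked while `f ≤ t_l`):

    t_h ← β (T_max − t_l) + t_l        at the falling t_m crossing
    t_m ← γ (T_max − t_l) + t_l        at the falling t_l crossing
    t_l ← λ T_min + (1 − λ) t_m        at the next rising t_m crossing

with defaults β = 0.071, γ = 0.042, λ = 0.5 and initial thresholds
(15, 20, 25) N. `t_h` doubles as the contact threshold (`on iff f ≥ t_h`).
Because each retune fires at a *different* crossing point of the cycle,
every threshold updates exactly once per cycle and the triple provably
stays ordered. The (heel, ball) status pair then maps to per-sample gait
labels: stance (on, on), swing (off, off), heel-strike (heel only), and
heel-off (ball only).

## Worked example

Simulate a 10 s walk at 4 km/h (2000 Hz, two channels), detect phases with
the adaptive method, and score it against the post-hoc global-span
reference:

```sh
$ gaitphase simulate --speed 4 --duration 10 --seed 1 -o walk.csv
wrote 20000 samples per channel to walk.csv

$ gaitphase detect walk.csv --method sttta -o labels.csv --report report.json
wrote 20000 labels to labels.csv
wrote report to report.json
```

`report.json` contains the adapted thresholds and the event list
(excerpt):

```json
{
  "method": "sttta",
  "n_samples": 20000,
  "final_thresholds_N": {
    "ball": {"t_l": 19.59, "t_m": 40.43, "t_h": 54.82},
    "heel": {"t_l": 19.49, "t_m": 40.32, "t_h": 54.71}
  },
  "events": [
    {"label": "heel_strike", "time_s": 0.0525, "cycle_index": 1},
    {"label": "heel_off",    "time_s": 0.4420, "cycle_index": 1},
    {"label": "heel_strike", "time_s": 1.0680, "cycle_index": 2}
  ]
}
```

Starting from the fixed (15, 20, 25) N triple, both channels have settled
near the fixed point for this trial's ~517 N peaks — `t_h ≈ 54.8 N`, i.e.
about 10.6 % of the way from `t_l` to the peak — without being told the
wearer's weight or speed. The events alternate heel-strike/heel-off once
per 1 s cycle, as constructed.

```sh
$ gaitphase compare walk.csv --method-a sttta --method-b tam --burn-in-s 2
{
  "method_a": "sttta",
  "method_b": "tam",
  "percent_agreement": 99.25,
  "n_samples": 16000
}
```

After a 2 s burn-in (the cold-start cycles), the adaptive detector agrees
with the whole-recording reference on 99.25 % of samples while having seen
each sample only once, in order.

`gaitphase tune` grid-searches β and γ against a reference method over
training recordings, and the library API (`gaitphase.run_sttta`,
`gaitphase.step`, `gaitphase.detect_sequence`, …) exposes every stage,
including a pure streaming interface that is bit-identical to the batch
run.

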