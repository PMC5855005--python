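# Methods

## Problem and signal model

Two force sensitive resistors (FSRs) under the ball and heel of one foot
each produce a ground contact force (GCF) trace: during stance the loaded
sensor sees a force hump of hundreds of newtons, during swing it returns to
a near-zero baseline. Per-sample contact detection reduces each trace to a
binary on/off-ground status by thresholding, and the (heel, ball) status
pair maps to one of four gait labels — stance, swing, heel-strike,
heel-off — through a fixed rule table. The difficulty is the threshold:
per-cycle maxima vary roughly 300–1300 N across wearers and walking
speeds, while swing minima sit at 0–5 N, so any constant threshold is
either wearer-specific (body-weight fractions) or requires the whole
recording (span-based methods) and cannot run online.

The adaptive detector keeps three ordered thresholds per channel,
`t_l < t_m < t_h`, and retunes all three once per gait cycle from the
cycle's own force extrema:

- while `f >= t_h` the running per-cycle maximum `T_max` is tracked;
- at the falling crossing of `t_m`: `t_h <- beta * (T_max - t_l) + t_l`;
- at the falling crossing of `t_l`: `t_m <- gamma * (T_max - t_l) + t_l`,
  and the minimum region opens;
- while `f <= t_l` the running minimum `T_min` is tracked; the rising
  crossing of `t_l` closes the cycle;
- at the next rising crossing of `t_m`:
  `t_l <- lam * T_min + (1 - lam) * t_m`.

`t_h` doubles as the contact threshold (`on iff f >= t_h`, boundary
inclusive everywhere). Anchoring each retune to a *different* crossing
point is what guarantees a single retune per cycle: an adaptive threshold
that retunes at its own crossing can fire twice when the force re-crosses
the freshly lowered value within the same cycle.

## State machine and edge conventions

Crossings are detected between consecutive samples; the pre-stream sample
is treated as "below everything", so a trace that starts mid-stance syncs
immediately. A falling sample that crosses several thresholds at once
fires its points in cycle order within that one sample (maximum close,
`t_h` retune, `t_m` retune / minimum open), and symmetrically for rising
samples, so step inputs behave identically to steep ramps.

Choices where the procedure is genuinely open:

- **Retune activation.** Newly computed values take effect immediately at
  their computation points; since each point precedes the comparison
  region it serves in the next cycle, this is observationally equivalent
  to double-buffering the triple and simpler.
- **Cold start.** The machine is unsynchronized until the first rising
  `t_m` crossing. The `t_l` retune at that first crossing is skipped (no
  finalized minimum exists yet); the `t_m`/`t_h` retunes require a
  finalized maximum from the current cycle. Consequently the first cycle
  retunes `t_h` and `t_m` only.
- **Re-entry without reset.** The running maximum is initialized on first
  entry of the region above `t_h` and on re-entry within the same cycle is
  only ever raised, never re-initialized — a double-humped stance yields
  its true maximum. After the `t_h` retune has fired, further excursions
  above `t_h` in the same cycle are ignored outright.
- **Rejected retunes.** A computed value that would break
  `t_l < t_m < t_h` (e.g. the first cycle after a large amplitude *drop*,
  where the stale `t_m` exceeds the new `t_h` candidate) is discarded with
  a warning and the previous value retained; adaptation then completes on
  the following cycle. A real-time detector should degrade, not halt.
- **Counters.** `i` counts completed cycles (minimum region closed), `j`
  counts finalized maxima; incomplete boundary cycles make `i != j`
  legitimate.
- **Per-channel independence.** Ball and heel each run their own state;
  nothing couples the two before the rule table.

## Convergence and adaptation rates

For constant per-cycle extrema `M`, `m` the retunes form a linear map with
the unique fixed point

    t_l* = (lam*m + (1-lam)*gamma*M) / (lam + (1-lam)*gamma),
    t_m* = t_l* + gamma*(M - t_l*),
    t_h* = t_l* + beta*(M - t_l*),

and the `t_l` error contracts by `(1-lam)*(1-gamma)` per cycle — 0.479
per cycle at the defaults (`lam = 0.5`, `gamma = 0.042`). Two practical
consequences, both verified by the test suite and the acceptance script:

- from the default initial thresholds, reaching the `M = 1000 N, m = 0`
  fixed point (40.307, 80.614, 108.445) N to within 1e-6 N takes about 25
  cycles (each cycle removes just over half the remaining error; the
  thresholds are within ~2 % of `t_h*` after 5–6 cycles, which is what
  matters for classification);
- after an amplitude step (2 → 6 km/h doubles the peak), the thresholds
  re-converge at the same geometric rate: usable within one or two steps,
  within 1 % of the new `t_h*` after about 5 cycles.

These rates are properties of the update equations themselves, not of the
implementation.

## Parameters

| parameter | default | units | role |
|---|---|---|---|
| `beta`  | 0.071 | – | height of `t_h` above `t_l`, as a fraction of `T_max - t_l` |
| `gamma` | 0.042 | – | height of `t_m`, same scale; `0 < gamma < beta < 1` keeps ordering |
| `lam`   | 0.5   | – | weight of `T_min` vs `t_m` in the `t_l` retune |
| `t_l0, t_m0, t_h0` | 15, 20, 25 | N | initial triple; any ordered triple between typical swing minima and stance maxima works, the same one serves all wearers |
| filter cutoff | 10 | Hz | second-order Butterworth low-pass |

`beta` and `gamma` defaults are the output of the reliability grid search
(below); `lam = 0.5` is fixed first because `t_m` and `t_l` feed each
other.

## Reference methods and reliability

Three constant-threshold baselines share the classifier `on iff f >= T`:
body-weight (`T = 0.05*m*g`), global span (`T = min + 0.1*(max - min)`,
per channel per trial), and averaged per-cycle extrema
(`T = TMIN + alpha*(TMAX - TMIN)`, `alpha = 0.084`). For the last, the
per-cycle extrema are located by segmenting the trace into runs above and
below a split level (defaulting to the recording's own 10 %-of-span
threshold), one extremum per run — a self-contained stand-in for whatever
cycle segmentation a commercial package performs internally.

Reliability between two methods is the per-sample gait-label agreement
percentage (symmetric, bounded, 100 iff identical), with an optional
burn-in excluding the adaptive detector's cold-start cycles, since the
span-based references see the whole trace. `grid_search` sweeps
`(beta, gamma)` with `gamma < beta`, scores each pair against a reference
method averaged over training recordings, and breaks ties toward the
smaller pair. The CLI's default grid is coarse (0.01 steps over
[0.01, 0.30]); a 0.001-step sweep is ~42k cells and is left to explicit
flags.

## Synthetic gait generator

Each cycle (period `1/cadence_hz`, default 1 s; stance fraction 0.6)
contains a heel raised-cosine hump over the first 75 % of stance and a
ball hump over the last 75 %, overlapping at mid-stance, on a 1 N
baseline, with seeded Gaussian noise (default sd 2 N) and clamping at
zero. Peak amplitude follows
`mass*9.81*peak_scale*(0.4 + 0.1*(speed_kmh - 2))`, which with the
defaults (67.3 kg, scale 1.3) keeps per-cycle maxima within 300–1300 N
and minima within 0–5 N over 2–6 km/h. Only the monotone speed–amplitude
relationship is physiologically motivated; the slope, hump shape and
overlap timing are fixture choices. Speed changes switch amplitude at
cycle boundaries. Ground-truth labels are defined by thresholding each
channel's noise-free waveform at half its peak, so the truth is exactly
consistent with the rule table by construction.

What the generator does **not** emulate: double-peaked adult stance
profiles, step-to-step timing variability, sensor drift and hysteresis,
attachment artifacts, pathological gait, or uneven terrain. Tests passing
on this fixture therefore validate the algorithm's logic (ordering,
single-retune, convergence, concordance), not its clinical accuracy on
human recordings.

## Numerical and scale choices

- Boundary samples count as contact (`>=`) everywhere, and region
  membership uses the same convention.
- The detector expects low-pass-filtered input. The causal single-pass
  filter is the real-time default; zero-phase (forward–backward) filtering
  is available for offline parity but squares the magnitude response.
  On *unfiltered* wide-band noise comparable to the threshold gaps, bounce
  at a crossing can close a cycle early and pollute one retune; ordering
  is still enforced (bad retunes are rejected) and classification recovers
  within a cycle.
- CSV serialization: times at 6 decimals, forces at 3 (beyond the FSR's
  ±0.5 % full-scale accuracy); write/read/write round trips are
  byte-identical.
- Out-of-range calibration voltages clamp to [0, 5] V with a warning.
- Test and acceptance problem sizes: 30–100 s trials at 2000 Hz (100
  cycles for the retune-count check; 20 randomized 30 s trials, 1.2 M
  samples, for the ordering invariant), chosen to exercise full
  convergence while keeping the whole suite fast.

## Known limitations

- Swing sub-phases are out of scope (two FSRs cannot resolve them), as
  are abnormal-gait rule extensions, stairs and irregular terrain.
- A sharp amplitude *decrease* adapts one cycle slower than an increase
  because the first `t_h` candidate after the drop may be rejected to
  preserve ordering.
- The split-level cycle segmentation for the averaged-extrema reference
  assumes a single force hump per cycle per channel; strongly double-peaked
  stances would need a coarser split or explicit event segmentation.
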