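# Methods

## Event decoding

The decoder is a software port of the logger's acquisition logic. Each
channel is a reed switch; an OPEN→CLOSED transition is a candidate rotation.
Debouncing uses a **non-retriggerable lockout**: a candidate is accepted iff
it occurs at least `lockout_ms` (default 30 ms) after the previously
*accepted* rotation. Ignored (bouncing) edges do not restart the timer, so a
bounce burst shorter than the lockout can never mask the next true rotation.
The first CLOSED transition always detects. The 30 ms default was chosen as
roughly an order of magnitude longer than reed-switch bounce; on a 127 mm
wheel it caps recordable speed at `π·0.127 / 0.030 · 3.6 ≈ 47.9 km/h`, far
above what a mouse can sprint. Circumference is configuration, not a
constant, because practical builds differ in effective magnet radius.

Conventions that downstream code relies on:

- Minute bins are `[k·60000, (k+1)·60000)` ms, left-closed/right-open,
  anchored at the logger reset.
- Switch state before the first edge is the opposite of that edge (with no
  edges at all, OPEN — the rest state of a reed switch); its dwell accrues
  from t = 0, and state persists across bin boundaries and after the last
  edge, so every minute's open + closed dwell is exactly 60 000 ms.
- Duplicate same-state edges (glitches) are tolerated: they increment edge
  counts but only the first changes state. A field logger cannot afford to
  crash on a noisy input.
- Times are real-valued milliseconds internally; the CSV layer rounds the
  closed dwell to integer ms and assigns the complement to the open dwell,
  which keeps the 60 000 ms invariant exact after serialization.

## Synthetic behavior model

The simulator generates *dark-phase-dominant bouted running* under a 12:12
light/dark cycle; it exists to give every pipeline stage a known ground
truth, not to be a physiological model.

Per day (a 1440-min session starting at the daily reset, default at
lights-off, 10:20): the number of bout starts is Poisson with mean
`bout_rate_per_h × photoperiod_h`. Each bout is independently assigned to
the dark phase with probability `dark_activity_fraction`, starts uniformly
within its phase, and has an Exp(`bout_duration_min`) duration clipped at
the phase boundary. Bouts may overlap; their per-minute intensities
(`rot_per_min` × fractional coverage, × `ramp^day`) add, and each minute's
rotation count is Poisson with the summed intensity, capped at
`max_rot_per_min`.

Two properties of this construction carry the test suite:

1. **Exact expected dark share.** Bout durations and rates are identical in
   both phases and both phases span 12 h, so boundary-clipping losses are
   symmetric and the expected fraction of rotations in the dark equals
   `dark_activity_fraction` exactly — no spillover bias when estimating it
   back from decoded data.
2. **Exact round trip.** Within-minute rotation times are evenly spaced, so
   with the per-minute cap of 500 every inter-rotation gap is ≥ 120 ms —
   four lockouts — and the decoder recovers the simulated per-minute counts
   *exactly* when bounce and faults are off. Ground-truth distance therefore
   matches decoded distance to machine precision, and any discrepancy is a
   pipeline defect, not sampling noise.

Defaults (`BehaviorParams`): 2.5 bouts per dark hour, 10 min mean bout,
60 rotations/min, dark fraction 0.9, ramp 1.02/day. These are
order-of-magnitude choices tuned to the published range of murine wheel
running — ≈ 5–10 km/day, 200–300 active min/day, ≈ 1.5–2.5 km/h active
speed, and ~80% of minutes with zero rotations — not fits to any dataset.
What the model deliberately omits: ultradian structure beyond a single bout
scale, inter-day correlation other than the deterministic ramp, light-phase
"spillover" running around the transitions, and individual variability
beyond Poisson noise (all animals in a group share parameters). Passing
tests therefore demonstrate correctness of the *data path*, not realism of
mouse behavior.

Corruption models: contact bounce adds 1–3 spurious OPEN/CLOSED pairs within
`burst_window_ms` (default 3 ms) after a closure with probability
`p_bounce`; faults are offline windows (no edges emitted) and a drag factor
implemented as binomial thinning of emitted rotations (equivalent to scaling
the Poisson rate, but leaving ground truth pre-fault so the loss is
observable downstream).

## Time reconstruction

The reference loggers had no working real-time clock; absolute time comes
from a manually kept reset log (date → clock time). Missing entries are
imputed as the previous session's start plus the arithmetic mean, per day of
separation, of all consecutive recorded inter-reset intervals (or a supplied
constant), and flagged `IMPUTED`. The overall mean — rather than a running
mean — is used; the constant is exposed for users who prefer their own.
Sessions are never resampled onto a daily grid: a late reset shifts that
day's timestamps, and all downstream binning works from absolute timestamps.
Analysis "days" are sessions, not calendar midnights.

## Metrics

- **Active threshold**: fixed (acute protocol, 30) or derived as the lower
  quartile of *nonzero* per-minute counts pooled across the cohort (chronic
  protocol). Zeros are excluded because rest dominates (~80% of minutes); a
  zero-inclusive Q1 would collapse to 0. The quantile is nearest-rank by
  default (`linear` available); pooled-across-cohort was chosen over
  per-animal or per-day pooling to give one threshold per study. Strict `>`
  is used at the boundary, switchable to `≥`.
- **Active speed** is total active distance over total active time, not the
  mean of per-minute speeds — robust to how many minutes barely cleared the
  threshold.
- **Speed outliers**: absolute cap (default 20 km/h, ~40% of the debounce
  ceiling) OR the animal's other days' median + 5·MAD (leave-one-out,
  needing ≥ 3 other finite days). Both are annotations; the audit log lists
  every flagged animal-day.
- **Weeks** are consecutive 7-session blocks per animal; a short final week
  is kept (a 13-session study has a 6-session week 2). SEM is computed
  across animals (the experimental unit), never across days, and is NaN at
  n = 1.
- **Hourly profiles** bin by clock hour by default (so changing the nominal
  lights-off only relabels the zeitgeber axis); `anchor="zt"` bins from
  lights-on so that bins 12–23 are exactly the dark phase — that anchoring
  is what the dark-fraction estimator uses.
- **Quartile partition** of animals by total distance: top n//4 High, bottom
  n//4 Low, middle Average; ties broken by stable input order; fewer than 4
  animals degenerates to all-Average with a warning.

## Visualization

Actogram and heatmap correctness lives in their matrices: rotations per
10-min bin with a validity mask distinguishing "no data" from "zero
running". Actogram columns are anchored to clock midnight (the light mask
marks lights-on columns); double-plotting duplicates day d+1's first 24 h
into day d's right half, giving the identity
`values[d, 144:] == values[d+1, :144]` that the tests assert. Bars are
scaled per row maximum (classic actogram convention). Rendering is
matplotlib (Agg) and never mutates the matrices; matrices can be exported as
CSV sidecars. The heatmap's 10-min bins are counts per bin; a ×6 factor
converts to an hourly rate if preferred.

## Costing

Currency arithmetic is integer cents (parsed from strings, never through
binary floats) and print times integer minutes, so bill-of-materials and
print-plan totals are exact. A line item fails validation if its stated
total differs from unit × quantity by more than one cent (one cent absorbs
legitimate vendor rounding). The packaged reference BOM describes a
50-wheel, 3-logger build; the validator reports inventory inconsistencies
(e.g. filament spools short of the per-part masses × build size) rather than
reconciling them.

## Problem sizes and determinism

Simulation-backed tests use 2–3 day, 1–4 animal cohorts — large enough that
each day contains tens of bouts and ~15–20 k rotations, small enough to keep
the suite fast. The dark-fraction recovery check uses 20 independent seeds
and accepts the truth within 3 Monte-Carlo standard errors of the seed mean.
All randomness flows from explicit `numpy` Generators seeded at the call
site; property tests are derandomized. `scripts/acceptance.py` derives every
stochastic quantity from its `--seed` argument.

## Known limitations

- The simulator's phase-share exactness relies on equal-length phases;
  non-12:12 photoperiods introduce a small clipping asymmetry.
- With a session start offset from lights-off, phase windows wrap within the
  session rather than spilling into the next day's file.
- `stitch_sessions` assumes one shared reset log for all loggers (the
  reference protocol resets them together); a per-logger map can be supplied
  keyed by `(logger_id, date)`.
- The statistical modeling the summary tables feed (repeated-measures or
  mixed-effects ANOVA) is out of scope; use the per-animal weekly tables
  with your statistics package of choice.
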