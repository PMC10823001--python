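# wheelrun

Analytics for reed-switch rodent running wheels: decode raw switch-edge
streams into rotations, reconstruct absolute time from daily logger resets,
and compute the standard voluntary wheel-running measures — distance,
running duration, active-only speed, circadian actograms, and activity
distributions — together with a ground-truth simulator that makes the whole
pipeline testable without animal data.

The target hardware is the low-cost, open-source class of wheel loggers: a
magnet on the wheel closes a reed switch once per revolution, and a
microcontroller polls up to 13 wheels, logging per-minute summaries to CSV.
`wheelrun` is for labs running such wheels (exercise physiology, circadian
biology, addiction research) who want a tested, scriptable replacement for
ad-hoc spreadsheet analysis.

## The core quantities

- **Rotation detection.** An OPEN→CLOSED switch transition is one rotation,
  unless it falls within a lockout (debounce) window *L* after the previously
  detected rotation (default *L* = 30 ms, non-retriggerable). The fastest
  resolvable wheel speed is *v*<sub>max</sub> = *C*/*L* · 3.6 km/h for
  circumference *C* (m); for a 127 mm wheel, ≈ 47.9 km/h — far above murine
  sprinting speed.
- **Distance** (km/day): Σ rotations × *C* over all minutes.
- **Running duration** (active min/day): number of 1-min bins with rotation
  count strictly above a threshold — a fixed count (e.g. 30), or the lower
  quartile of nonzero per-minute counts pooled over the cohort.
- **Active speed** (km/h): distance accumulated in active minutes divided by
  active time.
- **Inclusion rules**: days with < 20 active minutes, zero-rotation (offline)
  days, and implausible speeds (absolute cap or per-animal median + 5·MAD)
  are flagged — never silently dropped — and skipped by group statistics
  (mean ± SEM across animals, in 7-session weeks).

## Worked example

Simulate a small cohort, stitch it into absolute-time series, and summarize:

```bash
wheelrun simulate --out demo/sim --seed 7 --days 13 --n-per-group 2
wheelrun stitch --logs demo/sim --reset-log demo/sim/reset_log.csv \
                --manifest demo/sim/manifest.csv --out demo/series
wheelrun summarize --series demo/series/series.csv \
                   --manifest demo/sim/manifest.csv --out demo/summary
wheelrun actogram --series demo/series/series.csv --mouse-id 1_0 --out demo/figs
wheelrun bom --wheels 50
```

The simulate/stitch/summarize steps print:

```
wrote 8 animals x 13 days to demo/sim
stitched 13 logger-days into demo/series/series.csv
104 animal-days summarized; 2 excluded
```

`demo/summary/daily_summary.csv` then holds one row per animal-day
(distance_km, active_min, active_speed_kmh, exclusion flags) and
`weekly_group_summary.csv` the group mean ± SEM per sex × genotype × week.
With the default behavior model an animal runs roughly 5–10 km/day in
200–300 active minutes at ≈ 1.4–2.6 km/h, ~90% of it in the dark phase —
typical figures for laboratory mice. The `bom` command validates the
packaged reference bill of materials and prints:

```
 MAJOR_EQUIPMENT: $806.13
      CONSUMABLE: $225.31
     grand total: $1,031.44
per wheel: 144 g PETG, 7 h 57 min
50 wheels: 7200 g, 397 h 30 min, 200 nuts
```

Everything the CLI does is a thin wrapper over the library
(`wheelrun.events`, `.simulate`, `.logio`, `.metrics`, `.viz`, `.bom`),
which is the recommended interface for anything beyond one-off runs.

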