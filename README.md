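# scn-coupling

Analysis of behavior-coupled modulation of suprachiasmatic nucleus (SCN)
multiunit electrical activity, with a calibrated synthetic-data generator
for end-to-end validation.

The SCN — the master circadian pacemaker — fires at high rates during a
nocturnal rodent's rest phase and at low rates during its active phase. In
vivo multiunit (MUA) recordings show that spontaneous behavioral activity
acutely *suppresses* SCN firing: the rate drops abruptly at behavior onset,
stays suppressed for the duration of the bout, and recovers exponentially
(over ~15 min) after the animal stops. The depth of the drop scales with
the intensity of the initiating behavior (grooming < moving < walking),
and because behavior is concentrated in the night, this coupling deepens
the trough of the rhythm — behavioral activity at the right phase *boosts*
circadian amplitude.

This package implements that analysis as a tested pipeline:

- **`synthetic_data`** — generator for recordings with the full statistical
  structure (plateau-shaped circadian rate, nocturnal behavior bouts,
  type-dependent suppression with exponential recovery, Poisson spike
  counts in 2-s bins, an imperfect PIR movement channel, per-spike
  amplitudes from two subpopulations, multi-animal cohorts), plus injected
  ground truth for parameter-recovery tests.
- **`io_formats`** — TSV/YAML formats for binned series, ethograms, event
  tables and configs; stream alignment and validation.
- **`rhythm`** — circadian smoothing by the lowest-bandwidth criterion
  (smallest moving-average bandwidth giving one peak and one trough per
  cycle), per-cycle amplitude `A = peak − trough`, ZT/CT phase mapping.
- **`events`** — ethogram-driven suppression detection, the magnitude
  statistic `M = 100·(B − S)/A` (baseline B = mean rate over the 2 min
  before the bout; S = mean rate during it), return-to-baseline time and
  exponential recovery fitting, duration classes, excitation transients
  after induced disturbances, per-animal responsiveness classification.
- **`subpopulations`** — equal-count spike-amplitude threshold windows from
  a 100-s baseline histogram and per-window suppression contrast.
- **`profiles_stats`** — PIR-conditioned circadian profiles (active vs
  inactive bins), night-active/day-active amplitude scenarios, one-way
  ANOVA with Bonferroni post-hoc tests across behavior types, day/night
  magnitude statistics, per-circadian-hour summaries.
- **`cli`** — the `scn-coupling` command (`simulate`, `analyze`, `subpop`,
  `report`) with reproducibility manifests.

## Worked example

Simulate a 4-day recording under the default (calibrated) conditions and
analyze it:

```sh
$ cat config.yaml
peak_rate: 120.0
trough_rate: 60.0
duration_h: 96.0
seed: 7

$ scn-coupling simulate --config config.yaml --out sim -v
[simulate] 0.3s bouts=61 bins=172800
$ scn-coupling analyze --in sim --out ana -v
[analyze] 0.7s bouts=61 detected=61
$ scn-coupling report --in ana
{
 "duration_class_fractions": {
  "1-25 min": 0.7049180327868853,
  "<1 min": 0.14754098360655737,
  ">25 min": 0.14754098360655737
 },
 "magnitude_by_type_pct": {
  "grooming": 32.38494065961737,
  "moving": 42.362454353991176,
  "walking": 59.006563171937536
 },
 "mean_recovery_min": 14.975730994152048,
 "n_candidate_bouts": 61,
 "n_detected": 61
}
```

All 61 behavior bouts were detected as suppression events. Their mean
magnitudes, grouped by the behavior that initiated each bout, recover the
injected coupling — grooming suppresses ~32% of the circadian amplitude,
moving ~42%, walking ~59% — and firing takes ~15 min to return to baseline
after a bout ends. Event-level detail (onset, baseline, magnitude, phase,
recovery time per event) is in `ana/events_suppression.tsv`; the rhythm
fit (chosen bandwidth, per-cycle peaks/troughs/amplitudes) is in
`ana/rhythm.json`; the PIR-conditioned circadian profile is in
`ana/profiles.tsv`.

The same machinery is available as a library:

```python
import scn_coupling as sc

cfg = sc.SimulationConfig(duration_h=96.0, seed=7)
rec = sc.simulate_recording(cfg)
res = sc.analyze_recording_obj(rec, compute_recovery=True)
print(res.fit.mean_amplitude_hz)        # ~60 Hz (peak 120 − trough 60)
print(res.events_df.head())
```

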