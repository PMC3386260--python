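# Methods

## The measurement model

A chronically implanted micro-electrode near the SCN yields pooled
multiunit spike counts in 2-s bins over days of recording. Alongside it run
two behavioral channels: a passive-infrared (PIR) detector giving a coarse
per-bin movement signal, and a video-scored ethogram assigning each second
one of nine behavior categories (digging, drinking, eating, grooming,
lying, moving, rearing, sitting, walking; lying and sitting count as rest).
All analyses live on a common clock in seconds from recording start; ZT/CT
phase is computed on demand from a light-schedule object (phase 0 =
lights-on/CT0, day = phase 0–12, night = 12–24) and never stored in files.

## Generative model (synthetic_data)

The generator produces recordings with the statistical structure the
analysis is designed for, plus the injected ground truth needed to test it
by parameter recovery.

**Circadian rate.** A smoothed trapezoid: day plateau `peak_rate`, night
plateau `trough_rate`, raised-cosine transitions of `transition_h` (2 h)
centered on phase 0 and 12. A trapezoid rather than a sinusoid makes the
peak and trough levels well defined, matching the plateau-like day levels
of in vivo recordings. Defaults are 120/60 Hz. These pooled-multiunit rates
are a design choice (single-unit SCN rates are ~1–10 Hz; a multiunit
electrode pools many): they leave headroom so that a night-time suppression
of up to ~70% of the amplitude can never clip the rate at zero, and they
set a signal-to-noise ratio at which the recovery kinetics are resolvable
in 10-s bins.

**Behavior schedule.** Bout onsets form a renewal process with gaps of at
least `min_gap_min` (40 min) plus an exponential excess (night mean 45
min); candidates falling in the subjective day are thinned so the expected
fraction of bout time at night equals `nocturnality` (0.85). The minimum
gap guarantees every bout a 2-min quiescent lead-in and keeps the previous
bout's recovery tail (≤1% residual after 40 min) out of the next baseline
window. Bout durations come from the three-class mixture 0.20/0.65/0.15:
uniform 10–60 s, log-uniform 1–25 min, uniform 25–45 min. Each bout starts
with an initiating behavior drawn uniformly from {grooming, moving,
walking}; longer bouts append sustaining segments (eating, rearing,
drinking) which hold — but never initiate — suppression. Re-draws of the
initiator inside a bout (escalation, deeper suppression) are supported by
the coupling operator but disabled by default so per-type magnitude means
stay interpretable against the depth table.

**Coupling.** At bout onset the rate steps down by `depth × A` within one
bin, where `A = peak_rate − trough_rate` and the depth is a Gaussian draw
(SD `depth_sd` = 0.03, truncated to [0, 1]) around the initiating
behavior's table value — grooming 0.32, moving 0.43, walking 0.59 — times
a day/night scale (below). Any bin overlapping the bout is fully
suppressed; after the last overlapped bin the deficit decays as
`exp(−t/τ_rec)`. Induced disturbances add a rectangular increment (40% of
A, 10–200 s, placed in the rest phase) with an optional post-excitation
undershoot.

**τ_rec = 8 min.** The package's return-to-baseline measurement (below)
declares recovery when the 10-s rate re-enters a ±2 SE Poisson band for a
sustained minute. For an exponential deficit D·exp(−t/τ) that happens
around `τ·ln(D/band) +` a run-length allowance; at the default rates the
band sits near a quarter of D, so τ = 8 min yields measured mean return
times of ~15 min (SD ~3.5) — the observed recovery scale. A smaller τ
would be reported as a proportionally faster return.

**Day/night depth scales (1.0599 / 0.9751).** The per-type depth table and
the day/night magnitude means (47% day, 43% night) cannot both be matched
exactly once 85% of bout time is nocturnal: a day/night-exact calibration
forces the pooled per-type means ~2% below the table (the two reference
datasets they encode were collected differently — the day/night means come
from a phase-uniform event sample). The default scales are therefore a
joint calibration, fitted on six 60-day design runs of the full pipeline
and then frozen: measured day/night means land at ~47.5/43.3% and pooled
per-type means within ~2–3% (≈1 percentage point) of the table.

**Observation channels.** Spike counts are Poisson with the modulated rate
(independent per bin). The PIR channel flags a 2-s bin with probability
0.7 when behavior covers ≥1 s of it, and never false-alarms. In waveform
mode the generator also emits a per-spike amplitude stream around each
bout (110-s baseline through the bout): two subpopulations with equal
18-Hz baseline rates but distinct amplitude distributions, of which only
the "responsive" (larger-amplitude) one is suppressed, plus a sub-threshold
noise-event stream.

**Cohort.** 14 animals, 9 with behavior coupling; 4 of the 5 uncoupled
animals carry a light-responsiveness flag (a label only — light responses
are not simulated).

**Determinism.** One master seed; per-component and per-animal child seeds
are spawned from `numpy.random.SeedSequence`, so identical config + seed
gives bit-identical outputs.

### What the generator does not emulate

Stationary Poisson counts (no bursting or slow electrode drift), a fixed
24-h period with no phase noise, hard-edged bouts with a single depth, no
PIR false positives, and no light-pulse responses. Passing the recovery
tests therefore shows the estimators are correct and well calibrated under
this model, not that real recordings meet its assumptions — in particular
real baselines drift, which is why the analysis carries an explicit
stationarity gate rather than assuming the problem away.

## Estimators

**Rhythm fit.** Counts are rebinned to 10 s and smoothed with a centered
moving average whose bandwidth is the smallest on the grid 0.5, 1, …, 6 h
for which every complete cycle (lights-off to lights-off) has exactly one
prominent local maximum and minimum (prominence ≥ 20% of the trace range,
which keeps micro-wiggles on flat plateaus from counting as extrema). On
simulations spanning hundreds of cycles a literal every-cycle requirement
is vetoed by a single stray cycle, so a bandwidth is accepted when ≥98% of
cycles conform (recordings up to 50 cycles still need all of them).
Behavior-bout windows plus a 35-min post-bout margin are excluded from the
fit — suppressions only lower the trace, so without the mask the trough,
and hence the amplitude denominator, would be biased; windows retaining
<25% of their bins are bridged by interpolation. Peak and trough levels
are the mean of the smoothed trace over the plateau band (within
max(4σ, 2.5% of range) of the extremum); a raw max/min over correlated
noise would be biased outward, and the plateau midpoint serves as the
extremum time on flat-topped cycles. Cycles whose extremum window holds
<10% unmasked data (e.g. a night spent entirely inside bout masks) are
dropped from amplitude statistics.

**Suppression events.** Detection is ethogram-driven: every maximal run of
active behavior (runs separated by <120 s merge) preceded by ≥2 min of
quiescence is a candidate. The baseline `B` is the mean rate over the
120 s ending at the last bin boundary before onset; `S` is the mean over
all bins overlapping the bout; the event is detected when the drop exceeds
`z·SE` under a Poisson null (`SE² = B(1/T_bout + 1/120)`, z = 3) *and*
`M = 100(B−S)/A ≥ 10%` of the cycle's amplitude. Both thresholds are
package decisions calibrated on zero-coupling simulations (false-positive
rate ≤0.5%) — the underlying experimental analyses selected clear
suppressions by inspection. A bout whose 2-min window falls inside the
previous event's 30-min recovery margin reuses the previous baseline.

**Stationarity gate.** `M` presumes the underlying rhythm is constant from
baseline through bout. Events whose fitted (unsuppressed) rhythm changes
by more than 5% of A across the measurement window — bouts straddling the
day/night transitions — violate that premise and carry magnitude biases of
several points, so they are flagged non-stationary. Magnitude and kinetics
statistics, the per-animal responsiveness test, and the null calibration
use stationary events; detection counts and duration classes use all
events.

**Recovery.** From bout offset, the 10-s rate is scanned for the first run
of six consecutive bins inside `B ± 2√(B/10)` Hz (the Poisson SD of a 10-s
rate); the run's start is the return time, capped at 30 min or the next
bout (right-censored otherwise). The deficit `B − rate(t)` is also fitted
with `D·exp(−t/τ)` by least squares, reporting τ̂.

**Excitations.** For each logged disturbance time (those inside a bout or
its recovery margin are excluded), an event is an excursion above
`B + 3.3√(B/10)` within 30 s; its duration is the time above the 2σ band,
and it is classed "undershoot" when two consecutive bins later fall below
the lower 3.3σ band within 5 min of its end.

**Responsiveness.** An animal with ≥20 stationary candidate bouts is
responsive when its detected fraction beats a binomial test (α = 0.01)
against the calibrated null false-positive rate (0.005).

**Subpopulations.** Window boundaries are midpoints between order
statistics at the i/k quantiles of above-noise baseline amplitudes (100-s
window), so per-window baseline counts differ by ≤1; boundary amplitudes
assign upward. Per-window magnitudes use the event formula; the response is
heterogeneous when the extreme windows differ by more than twice the
pooled Poisson SE.

**Profiles and statistics.** The phase-folded MUA profile (10-s bins,
0.1-h phase bins, circular moving-average smoothing) is split by PIR state;
the night-active amplitude is peak(inactive) − trough(active) and the
day-active amplitude peak(active) − trough(inactive). The across-type
comparison is a classical one-way ANOVA computed from sums of squares
(degenerate guards: zero within-variance with distinct means → F = ∞,
p = 0; identical means → F ≈ 0, p ≈ 1) with pooled-variance Bonferroni
pairwise tests; it is cross-checked in the tests against scipy and a
permutation null. The day/night comparison adds the animal as a blocking
factor (statsmodels OLS two-way ANOVA) when events from ≥2 animals are
present, α = 0.05.

## Problem sizes

The validation suite and `scripts/acceptance.py` choose simulation lengths
so every estimate rests on ample events while keeping runs to seconds on
one CPU: 32 days (≈130–160 events per initiating type) for per-type
magnitudes, 16 days (≈210 events) for recovery kinetics, 400 days (≈830
day-phase and ≈4800 night-phase events) for the day/night means, 72 h per
animal for the 14-animal cohort, and 660 days (≈10,000 bouts) for the
duration-class mixture.

## Known limitations

- Amplitude estimation needs enough unmasked night data; at activity
  levels far above the default nocturnality the trough becomes poorly
  constrained and more cycles are dropped.
- The return-to-baseline time depends on the signal-to-noise ratio through
  the band width: it measures "indistinguishable from baseline", not a
  fixed fraction of the deficit, and so would shift with firing rate.
- Magnitudes of 10-s bouts carry a Poisson noise floor of several
  percentage points per event (S is averaged over ≤5 bins); only their
  means are accurate.
- The per-event depth SD (0.03) mirrors the SEM scale of the reference
  group means, not measured per-event variability, which is unreported.
- Ties between the per-type depth table and the day/night means are
  resolved by the joint calibration described above; a generator targeting
  only one of the two reference datasets could match it more closely.
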