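"""Suppression/excitation event detection, magnitude and recovery kinetics.

The core statistic is the suppression magnitude

    M = 100 * (B - S) / A   [% of circadian amplitude]

where ``B`` is the baseline firing rate (mean over the last 2 min before the
bout), ``S`` the mean rate during the bout and ``A`` the circadian amplitude
(peak minus trough of the smoothed rhythm, by default of the cycle
containing the event). Detection is ethogram-driven: every behavior bout
preceded by enough quiescence is tested for a drop exceeding ``z`` Poisson
standard errors and a minimum magnitude.
"""
from __future__ import annotations

import dataclasses
import math

import numpy as np
from scipy import optimize, stats

from .io_formats import BinnedSeries, Ethogram, LightSchedule
from .rhythm import ArrhythmicError, RhythmFit

DURATION_SHORT = "<1 min"
DURATION_MID = "1-25 min"
DURATION_LONG = ">25 min"


@dataclasses.dataclass
class AnalysisParams:
    """Tunable detection/kinetics knobs (defaults calibrated on the null)."""

    z_threshold: float = 3.0        # Poisson z for the drop test
    m_min_pct: float = 10.0         # minimum magnitude, % of amplitude
    baseline_s: float = 120.0       # baseline window before onset
    quiescence_s: float = 120.0     # required quiet time before a bout
    merge_gap_s: float = 120.0      # bouts closer than this merge into one event
    recovery_margin_min: float = 30.0  # tail length treated as contaminated
    rhythm_mask_margin_min: float = 35.0  # post-bout margin excluded from the fit
    max_drift_frac: float = 0.05    # rhythm drift over the event window, as a
                                    # fraction of A, beyond which the constant-
                                    # baseline assumption is flagged as violated
    recovery_cap_min: float = 30.0  # max post-offset window for kinetics
    rebin_s: float = 10.0           # rebinning for recovery / excitation scans
    band_z: float = 2.0             # return-to-baseline noise band half-width
    band_run_bins: int = 6          # consecutive in-band bins required
    amplitude_mode: str = "cycle"   # "cycle" or "mean" amplitude denominator
    excite_z: float = 3.3           # onset threshold for excitation transients
    excite_scan_s: float = 30.0     # window after a disturbance to find onset
    undershoot_scan_min: float = 5.0  # post-excitation window for the undershoot test


@dataclasses.dataclass
class SuppressionEvent:
    onset_s: float
    offset_s: float
    initiating: str
    baseline_hz: float
    suppressed_hz: float
    amplitude_hz: float
    magnitude_pct: float
    z_score: float
    phase_h: float
    is_day: bool
    detected: bool
    stationary: bool = True
    baseline_reused: bool = False
    recovery_min: float = float("nan")
    tau_min: float = float("nan")
    recovery_censored: bool | None = None

    @property
    def duration_s(self) -> float:
        return self.offset_s - self.onset_s

    @property
    def duration_class(self) -> str:
        return classify_duration(self.duration_s)


@dataclasses.dataclass
class ExcitationEvent:
    disturbance_s: float
    onset_latency_s: float
    peak_increment_hz: float
    peak_increment_pct: float
    duration_s: float
    post_class: str  # "return" | "undershoot"
    detected: bool = True


@dataclasses.dataclass
class RecoveryResult:
    return_min: float
    tau_min: float
    deficit_hz: float
    censored: bool


def _window_rate(series: BinnedSeries, t_lo: float, t_hi: float) -> tuple[float, float]:
    """Mean rate (Hz) over bins overlapping [t_lo, t_hi) and the window length."""
    i0 = max(int(math.floor((t_lo - series.t0) / series.bin_s + 1e-9)), 0)
    i1 = min(int(math.ceil((t_hi - series.t0) / series.bin_s - 1e-9)), series.n)
    if i1 <= i0:
        return float("nan"), 0.0
    dur = (i1 - i0) * series.bin_s
    return float(series.values[i0:i1].sum() / dur), dur


def baseline_rate(series: BinnedSeries, t_event: float,
                  baseline_s: float = 120.0) -> float:
    """Mean discharge rate over the ``baseline_s`` preceding ``t_event``."""
    if t_event - baseline_s < series.t0 - 1e-9:
        raise ValueError("insufficient data before the event for a baseline")
    # end at the last bin boundary at/before the event so the window never
    # touches the (partially suppressed) bin containing the onset
    end = series.t0 + math.floor((t_event - series.t0) / series.bin_s
                                 + 1e-9) * series.bin_s
    b, _ = _window_rate(series, end - baseline_s, end)
    return b


def suppression_magnitude(baseline_hz: float, suppressed_hz: float,
                          amplitude_hz: float) -> float:
    """M = 100 * (B - S) / A, the suppression as % of circadian amplitude."""
    if not amplitude_hz > 0:
        raise ArrhythmicError("amplitude must be positive")
    return 100.0 * (baseline_hz - suppressed_hz) / amplitude_hz


def classify_duration(duration_s: float) -> str:
    """Duration class: [0, 60) s, [60 s, 25 min], (25 min, inf)."""
    if duration_s < 60.0:
        return DURATION_SHORT
    if duration_s <= 25.0 * 60.0:
        return DURATION_MID
    return DURATION_LONG


def detect_suppressions(series: BinnedSeries, ethogram: Ethogram,
                        fit: RhythmFit, schedule: LightSchedule,
                        params: AnalysisParams | None = None
                        ) -> list[SuppressionEvent]:
    """Test every quiescence-preceded behavior bout for a suppression.

    Returns one :class:`SuppressionEvent` per candidate bout with the
    ``detected`` flag set by the two-part criterion (Poisson z-test on the
    drop and a minimum magnitude). Bouts without a clean 2-min baseline
    reuse the previous event's baseline when the previous bout ended within
    the recovery margin; bouts without any usable baseline are skipped.
    """
    p = params or AnalysisParams()
    if not fit.rhythmic:
        raise ArrhythmicError("suppression magnitude needs a rhythmic fit")
    bouts = ethogram.active_bouts(merge_gap_s=p.merge_gap_s)
    events: list[SuppressionEvent] = []
    prev_offset = None
    prev_baseline = None
    for b in bouts:
        onset, offset = b.onset_s, min(b.offset_s, series.t_end)
        if offset - onset < series.bin_s:
            continue
        if prev_offset is not None and onset - prev_offset < p.quiescence_s:
            # no quiescent lead-in: cannot anchor a baseline; skip candidate
            prev_offset = b.offset_s
            continue
        reused = False
        if (prev_offset is not None
                and onset - prev_offset < p.recovery_margin_min * 60.0 + p.baseline_s):
            if prev_baseline is None:
                prev_offset = b.offset_s
                continue
            B = prev_baseline
            reused = True
        else:
            if onset - p.baseline_s < series.t0 - 1e-9:
                prev_offset = b.offset_s
                continue
            B = baseline_rate(series, onset, p.baseline_s)
        S, dur = _window_rate(series, onset, offset)
        A = fit.amplitude_at(onset, mode=p.amplitude_mode)
        M = suppression_magnitude(B, S, A)
        se = math.sqrt(max(B, 1e-12) * (1.0 / dur + 1.0 / p.baseline_s))
        z = (B - S) / se if se > 0 else math.inf
        detected = bool(B > S and z > p.z_threshold and M >= p.m_min_pct)
        drift = abs(fit.value_at(offset) - fit.value_at(onset - p.baseline_s))
        phase = float(schedule.phase_h(onset))
        events.append(SuppressionEvent(
            onset_s=onset, offset_s=offset, initiating=b.initiating,
            baseline_hz=B, suppressed_hz=S, amplitude_hz=A,
            magnitude_pct=M, z_score=z, phase_h=phase,
            is_day=bool(phase < 12.0), detected=detected,
            stationary=bool(drift <= p.max_drift_frac * A),
            baseline_reused=reused))
        prev_offset = b.offset_s
        prev_baseline = B
    return events


def recovery_time(series: BinnedSeries, event: SuppressionEvent,
                  baseline_hz: float | None = None,
                  params: AnalysisParams | None = None,
                  next_onset_s: float | None = None,
                  band_hz: float | None = None) -> RecoveryResult:
    """Return-to-baseline time and fitted exponential recovery constant.

    The post-offset trace is rebinned to ``rebin_s``; the return time is the
    start of the first run of ``band_run_bins`` consecutive bins inside the
    baseline noise band ``B +/- band_z * sqrt(B / rebin_s)`` (the Poisson SD
    of a rebinned rate). The deficit ``B - rate`` is also fitted with
    ``D * exp(-t / tau)`` by least squares over the same window.
    """
    p = params or AnalysisParams()
    B = baseline_hz if baseline_hz is not None else event.baseline_hz
    t_stop = series.t_end if next_onset_s is None else min(next_onset_s, series.t_end)
    t_stop = min(t_stop, event.offset_s + p.recovery_cap_min * 60.0)
    # 10-s bins anchored at the first series bin at/after the offset
    i0 = int(math.ceil((event.offset_s - series.t0) / series.bin_s - 1e-9))
    f = int(round(p.rebin_s / series.bin_s))
    i1 = int(math.floor((t_stop - series.t0) / series.bin_s + 1e-9))
    m = (i1 - i0) // f
    if m < 1:
        return RecoveryResult(float("nan"), float("nan"), float("nan"), True)
    counts = series.values[i0:i0 + m * f].reshape(m, f).sum(axis=1)
    rates = counts / p.rebin_s
    t_rel = series.t0 + i0 * series.bin_s - event.offset_s + np.arange(m) * p.rebin_s
    sigma = math.sqrt(max(B, 1e-12) / p.rebin_s)
    band = band_hz if band_hz is not None else p.band_z * sigma
    in_band = np.abs(rates - B) <= band
    run = min(p.band_run_bins, m)
    ret = float("nan")
    censored = True
    if m >= run:
        ok = np.convolve(in_band.astype(int), np.ones(run, dtype=int),
                         mode="valid") == run
        hits = np.nonzero(ok)[0]
        if hits.size:
            ret = float(t_rel[hits[0]]) / 60.0
            censored = False
    deficit = B - rates
    d0 = max(float(deficit[0]) if m else 0.0, 1e-6)
    tau = float("nan")
    d_fit = float("nan")
    try:
        popt, _ = optimize.curve_fit(
            lambda t, d, tau_s: d * np.exp(-t / tau_s),
            t_rel, deficit, p0=(d0, 60.0 * 5.0),
            bounds=((0.0, 1.0), (np.inf, 7200.0)), maxfev=2000)
        d_fit, tau = float(popt[0]), float(popt[1]) / 60.0
    except (RuntimeError, ValueError):
        pass
    return RecoveryResult(ret, tau, d_fit, censored)


def detect_excitations(series: BinnedSeries, disturbance_times,
                       fit: RhythmFit, schedule: LightSchedule,
                       params: AnalysisParams | None = None,
                       ethogram: Ethogram | None = None
                       ) -> tuple[list[ExcitationEvent], list[float]]:
    """Detect transient firing-rate increments after induced disturbances.

    A disturbance scores as an excitation if the 10-s rate exceeds
    ``B + z * sqrt(B / rebin_s)`` within ``excite_scan_s``; its duration is
    the time the rate stays above the (2-sigma) band, and the post class is
    ``"undershoot"`` when the rate subsequently falls below ``B - z*sigma``
    inside the recovery window. Disturbances falling inside an ongoing
    behavior bout are excluded and returned separately.
    """
    p = params or AnalysisParams()
    excluded: list[float] = []
    events: list[ExcitationEvent] = []
    bouts = ethogram.active_bouts(p.merge_gap_s) if ethogram is not None else []
    A = fit.mean_amplitude_hz if fit.rhythmic else float("nan")
    for td in disturbance_times:
        td = float(td)
        inside = any(b.onset_s - p.baseline_s < td <
                     b.offset_s + p.recovery_margin_min * 60.0 for b in bouts)
        if inside:
            excluded.append(td)
            continue
        B = baseline_rate(series, td, p.baseline_s)
        sigma = math.sqrt(max(B, 1e-12) / p.rebin_s)
        i0 = int(math.ceil((td - series.t0) / series.bin_s - 1e-9))
        f = int(round(p.rebin_s / series.bin_s))
        m = (series.n - i0) // f
        if m < 1:
            continue
        rates = series.values[i0:i0 + m * f].reshape(m, f).sum(axis=1) / p.rebin_s
        t_rel = series.t0 + i0 * series.bin_s - td + np.arange(m) * p.rebin_s
        scan = t_rel < p.excite_scan_s
        above_hi = rates > B + p.excite_z * sigma
        onset_idx = None
        for k in np.nonzero(scan)[0]:
            if above_hi[k]:
                onset_idx = int(k)
                break
        if onset_idx is None:
            events.append(ExcitationEvent(td, float("nan"), float("nan"),
                                          float("nan"), float("nan"),
                                          "none", detected=False))
            continue
        above_band = rates > B + p.band_z * sigma
        k_end = onset_idx
        while k_end < m and above_band[k_end]:
            k_end += 1
        duration = (k_end - onset_idx) * p.rebin_s
        peak = float(rates[onset_idx:k_end].max() - B) if k_end > onset_idx else 0.0
        post = "return"
        k_lim = min(m, k_end + int(p.undershoot_scan_min * 60.0 / p.rebin_s))
        below = rates[k_end:k_lim] < B - p.excite_z * sigma
        if np.any(below[:-1] & below[1:]):  # two consecutive sub-band bins
            post = "undershoot"
        events.append(ExcitationEvent(
            disturbance_s=td, onset_latency_s=float(t_rel[onset_idx]),
            peak_increment_hz=peak,
            peak_increment_pct=100.0 * peak / A if A and A > 0 else float("nan"),
            duration_s=duration, post_class=post, detected=True))
    return events, excluded


def classify_animal_responsiveness(n_detected: int, n_candidates: int,
                                   null_fpr: float = 0.005,
                                   alpha: float = 0.01,
                                   min_bouts: int = 20) -> str:
    """Per-animal verdict from the fraction of bouts yielding suppressions.

    A binomial test against the calibrated null false-positive rate: the
    animal is responsive when the detected fraction exceeds what chance
    detection would produce at the ``1 - alpha`` level.
    """
    if n_candidates < min_bouts:
        return "indeterminate"
    pval = float(stats.binom.sf(n_detected - 1, n_candidates, null_fpr))
    return "responsive" if pval < alpha else "non-responsive"
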