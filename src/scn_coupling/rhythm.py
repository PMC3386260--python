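"""Circadian rhythm fitting: smoothing criterion, per-cycle amplitude, phase.

The smoother is a centered moving average applied to 10-s rebinned firing
rates. Its bandwidth is not a free parameter: a grid of bandwidths
(0.5, 1, ..., 6 h) is scanned and the smallest one for which every complete
circadian cycle shows exactly one (prominent) local maximum and one local
minimum is used. If no bandwidth satisfies the criterion the input is
declared arrhythmic and the amplitude is undefined.

Event windows (behavior bouts and their recovery tails) can be excluded from
the fit so that behavioral suppression does not drag the trough estimate
down; excluded stretches are bridged by the surrounding data.
"""
from __future__ import annotations

import dataclasses
import math

import numpy as np
from scipy.signal import find_peaks

from .io_formats import BinnedSeries, LightSchedule

#: bandwidth grid (hours) scanned by the smoothing criterion
BANDWIDTH_GRID_H = tuple(0.5 * i for i in range(1, 13))


class ArrhythmicError(ValueError):
    """Raised when an operation requires a rhythmic fit and none exists."""


@dataclasses.dataclass
class CycleSummary:
    start_s: float
    end_s: float
    peak_time_s: float
    peak_hz: float
    trough_time_s: float
    trough_hz: float

    @property
    def amplitude_hz(self) -> float:
        return self.peak_hz - self.trough_hz


@dataclasses.dataclass
class RhythmFit:
    """Smoothed circadian trace with per-cycle peaks, troughs and amplitude."""

    t0: float
    bin_s: float
    smoothed_hz: np.ndarray
    bandwidth_h: float | None
    rhythmic: bool
    cycles: list
    noise_sd_hz: float = float("nan")

    @property
    def mean_amplitude_hz(self) -> float:
        if not self.rhythmic or not self.cycles:
            return float("nan")
        return float(np.mean([c.amplitude_hz for c in self.cycles]))

    def amplitude_at(self, t_s: float, mode: str = "cycle") -> float:
        """Amplitude of the cycle containing ``t_s`` (fallback: mean)."""
        if not self.rhythmic:
            raise ArrhythmicError("amplitude undefined for arrhythmic fit")
        if mode == "cycle":
            for c in self.cycles:
                if c.start_s <= t_s < c.end_s:
                    return float(c.amplitude_hz)
        return self.mean_amplitude_hz

    def value_at(self, t_s: float) -> float:
        i = int(round((t_s - self.t0) / self.bin_s - 0.5))
        i = min(max(i, 0), self.smoothed_hz.size - 1)
        return float(self.smoothed_hz[i])


def masked_moving_average(values: np.ndarray, valid: np.ndarray,
                          win_bins: int,
                          min_valid_frac: float = 0.25) -> np.ndarray:
    """Centered moving average ignoring invalid bins (O(n) via cumsums).

    Windows retaining fewer than ``min_valid_frac`` of their bins give an
    unreliable local mean; those positions (and fully invalid ones) are
    filled by linear interpolation from the nearest well-supported values.
    """
    n = values.size
    v = np.where(valid, values, 0.0)
    w = valid.astype(float)
    cv = np.concatenate([[0.0], np.cumsum(v)])
    cw = np.concatenate([[0.0], np.cumsum(w)])
    h = win_bins // 2
    i = np.arange(n)
    lo = np.maximum(i - h, 0)
    hi = np.minimum(i + h + 1, n)
    sw = cw[hi] - cw[lo]
    sv = cv[hi] - cv[lo]
    min_count = np.maximum(min_valid_frac * (hi - lo), 1.0)
    out = np.divide(sv, sw, out=np.full(n, np.nan), where=sw >= min_count)
    nan = np.isnan(out)
    if nan.any():
        if nan.all():
            raise ArrhythmicError("no valid data to smooth")
        out[nan] = np.interp(i[nan], i[~nan], out[~nan])
    return out


def _windows_to_mask(t0: float, bin_s: float, n: int, windows) -> np.ndarray:
    """Boolean exclusion mask from a list of (start_s, end_s) windows."""
    mask = np.zeros(n, dtype=bool)
    for s, e in windows:
        i0 = max(int(math.floor((s - t0) / bin_s)), 0)
        i1 = min(int(math.ceil((e - t0) / bin_s)), n)
        if i1 > i0:
            mask[i0:i1] = True
    return mask


def _extrema_per_cycle(sm: np.ndarray, prominence: float, t0: float,
                       bin_s: float, cycle_bounds) -> float:
    """Fraction of complete cycles with exactly one peak and one trough."""
    peaks, _ = find_peaks(sm, prominence=prominence)
    troughs, _ = find_peaks(-sm, prominence=prominence)
    pt = t0 + (peaks + 0.5) * bin_s
    tt = t0 + (troughs + 0.5) * bin_s
    ok = 0
    for c0, c1 in cycle_bounds:
        if (np.count_nonzero((pt >= c0) & (pt < c1)) == 1
                and np.count_nonzero((tt >= c0) & (tt < c1)) == 1):
            ok += 1
    return ok / len(cycle_bounds)


def _plateau_region(x: np.ndarray, idx: int, eps: float) -> tuple[int, int]:
    """Contiguous region around ``idx`` staying within ``eps`` of its value."""
    lo = idx
    while lo > 0 and x[lo - 1] >= x[idx] - eps:
        lo -= 1
    hi = idx
    while hi < x.size - 1 and x[hi + 1] >= x[idx] - eps:
        hi += 1
    return lo, hi


def _plateau_level(sm: np.ndarray, idx: int, eps: float, eps_level: float,
                   sign: float, halfwidth_bins: int) -> tuple[float, int]:
    """Level and midpoint index of the plateau around extremum ``idx``.

    The extremum *time* is the midpoint of the tight plateau (values within
    ``eps`` of the extremum — the flat-top tie-break). The *level* is the
    mean over the wider band within ``eps_level``, which on a flat-topped
    waveform spans essentially the whole plateau and so avoids the bias a
    raw max/min over correlated noise would carry.
    """
    x = sign * sm
    lo, hi = _plateau_region(x, idx, eps)
    mid = (lo + hi) // 2
    a, b = _plateau_region(x, idx, eps_level)
    a = min(a, max(mid - halfwidth_bins, 0))
    b = max(b, min(mid + halfwidth_bins, x.size - 1))
    level = float(np.mean(sm[a:b + 1]))
    return level, mid, (a, b + 1)


def smooth_mua(series: BinnedSeries, schedule: LightSchedule,
               exclude_windows=None, rebin_s: float = 10.0,
               grid_h=BANDWIDTH_GRID_H, prominence_frac: float = 0.2) -> RhythmFit:
    """Fit the circadian rhythm by the lowest-bandwidth smoothing criterion.

    Parameters
    ----------
    series : BinnedSeries
        MUA spike counts; must span at least one complete circadian cycle
        (lights-off to lights-off).
    exclude_windows : list of (start_s, end_s), optional
        Stretches (e.g. behavior bouts plus recovery tails) left out of the
        smoothing so suppressions do not bias peak/trough levels.
    prominence_frac : float
        An extremum only counts toward the one-peak/one-trough criterion if
        its prominence exceeds this fraction of the smoothed trace range.
    """
    rb = series.rebin(rebin_s)
    hz = rb.values / rebin_s
    n = hz.size
    valid = np.ones(n, dtype=bool)
    if exclude_windows:
        valid &= ~_windows_to_mask(rb.t0, rebin_s, n, exclude_windows)
    starts = schedule.cycle_starts(rb.t0, rb.t0 + n * rebin_s)
    cycle_bounds = [(s, s + schedule.period_s) for s in starts
                    if s + schedule.period_s <= rb.t0 + n * rebin_s + 1e-6]
    if not cycle_bounds:
        raise ArrhythmicError("series does not span one complete cycle")

    chosen = None
    sm = None
    for bw in grid_h:
        win = int(round(bw * 3600.0 / rebin_s))
        win += 1 - win % 2  # odd window
        cand = masked_moving_average(hz, valid, win)
        rng = float(np.max(cand) - np.min(cand))
        prom = prominence_frac * rng if rng > 0 else np.inf
        # require every cycle to conform; on very long recordings allow a
        # 2% fraction of stray cycles so one noisy cycle in hundreds cannot
        # veto every bandwidth
        if _extrema_per_cycle(cand, prom, rb.t0, rebin_s,
                              cycle_bounds) >= 0.98:
            chosen, sm = bw, cand
            break
    if chosen is None:
        # arrhythmic: keep the heaviest smoothing for inspection
        win = int(round(grid_h[-1] * 3600.0 / rebin_s)) | 1
        sm = masked_moving_average(hz, valid, win)
        return RhythmFit(rb.t0, rebin_s, sm, None, False, [])

    resid = hz[valid] - sm[valid]
    sigma_bin = 1.4826 * float(np.median(np.abs(resid - np.median(resid))))
    win = int(round(chosen * 3600.0 / rebin_s)) | 1
    sigma_sm = sigma_bin / math.sqrt(max(win, 1))
    rng = float(np.max(sm) - np.min(sm))
    eps = max(2.0 * sigma_sm, 0.01 * rng)
    eps_level = max(4.0 * sigma_sm, 0.025 * rng)

    halfwidth = max(int(round(0.5 * 3600.0 / rebin_s)), 1)  # +/- 0.5 h
    cycles = []
    skipped = []
    for c0, c1 in cycle_bounds:
        i0 = int(round((c0 - rb.t0) / rebin_s))
        i1 = int(round((c1 - rb.t0) / rebin_s))
        seg = sm[i0:i1]
        vseg = valid[i0:i1]
        pk = int(np.argmax(seg))
        tr = int(np.argmin(seg))
        pk_hz, pk_mid, pk_win = _plateau_level(seg, pk, eps, eps_level, +1.0,
                                               halfwidth)
        tr_hz, tr_mid, tr_win = _plateau_level(seg, tr, eps, eps_level, -1.0,
                                               halfwidth)
        summary = CycleSummary(
            start_s=c0, end_s=c1,
            peak_time_s=rb.t0 + (i0 + pk_mid + 0.5) * rebin_s, peak_hz=pk_hz,
            trough_time_s=rb.t0 + (i0 + tr_mid + 0.5) * rebin_s, trough_hz=tr_hz,
        )
        # a cycle whose extremum window holds (almost) no unmasked data has
        # an interpolated, unreliable level: keep it out of the amplitude
        support = min(float(np.mean(vseg[slice(*pk_win)])),
                      float(np.mean(vseg[slice(*tr_win)])))
        (cycles if support >= 0.1 else skipped).append(summary)
    if not cycles:
        cycles = skipped
    return RhythmFit(rb.t0, rebin_s, sm, chosen, True, cycles, sigma_bin)


def rhythm_amplitude(fit: RhythmFit) -> tuple[np.ndarray, float]:
    """Per-cycle peak-minus-trough amplitudes (Hz) and their mean."""
    if not fit.rhythmic:
        raise ArrhythmicError("amplitude undefined for arrhythmic fit")
    per_cycle = np.array([c.amplitude_hz for c in fit.cycles])
    return per_cycle, float(per_cycle.mean())


def to_circadian_time(t_s, schedule: LightSchedule):
    """Map recording time to ZT (LD) or CT (DD/LL) hours in [0, 24)."""
    t = np.asarray(t_s, dtype=float)
    if np.any(t < schedule.reference_s - 1e-9):
        raise ValueError("time precedes the schedule reference")
    phase = schedule.phase_h(t)
    return float(phase) if np.isscalar(t_s) else phase
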