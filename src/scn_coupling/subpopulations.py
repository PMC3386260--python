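"""Spike-amplitude threshold windows and subpopulation response contrast.

Multiunit activity pools spikes from many neurons; neurons near the
electrode produce larger action potentials. Splitting the spike-amplitude
range into non-overlapping windows with equal baseline counts (thresholds
from a 100-s pre-bout baseline histogram) yields approximately equal-sized
"subpopulations" whose responses during behavior can then be compared:
behavioral suppression may be present in one amplitude window and absent in
another.
"""
from __future__ import annotations

import dataclasses
import math

import numpy as np

from .io_formats import AmplitudeStream, BinnedSeries

BASELINE_WINDOW_S = 100.0


@dataclasses.dataclass
class AmplitudeWindows:
    """Contiguous half-open amplitude windows above the noise threshold."""

    noise_threshold: float
    edges: np.ndarray            # k+1 edges; edges[0] = threshold, edges[-1] = inf
    baseline_counts: np.ndarray  # spikes per window in the baseline
    baseline_duration_s: float

    @property
    def k(self) -> int:
        return int(self.baseline_counts.size)

    @property
    def baseline_rates_hz(self) -> np.ndarray:
        return self.baseline_counts / self.baseline_duration_s

    def assign(self, amplitudes: np.ndarray) -> np.ndarray:
        """Window index per spike; boundary values go to the upper window.

        Spikes at/below the noise threshold get index -1.
        """
        amps = np.asarray(amplitudes, dtype=float)
        idx = np.searchsorted(self.edges[1:-1], amps, side="right")
        idx[amps <= self.noise_threshold] = -1
        return idx


def amplitude_histogram(stream: AmplitudeStream, window: tuple[float, float],
                        bin_width: float = 0.02) -> tuple[np.ndarray, np.ndarray]:
    """Spike-amplitude histogram over a baseline window.

    ``window`` must be at least 100 s long (the pre-bout baseline length).
    Returns (counts, bin_edges); total counts equal the number of spikes in
    the window regardless of ``bin_width``.
    """
    t0, t1 = window
    if t1 - t0 < BASELINE_WINDOW_S - 1e-9:
        raise ValueError("baseline window must be at least 100 s")
    sel = (stream.times_s >= t0) & (stream.times_s < t1)
    amps = stream.amplitudes[sel]
    if amps.size == 0:
        raise ValueError("no spikes in the baseline window")
    lo, hi = float(amps.min()), float(amps.max())
    n_bins = max(int(math.ceil((hi - lo) / bin_width)), 1)
    return np.histogram(amps, bins=n_bins, range=(lo, lo + n_bins * bin_width))


def equal_count_windows(stream: AmplitudeStream, k: int, noise_threshold: float,
                        window: tuple[float, float]) -> AmplitudeWindows:
    """Equal-baseline-count amplitude windows above the noise threshold.

    Boundaries are the empirical i/k quantiles of the above-noise baseline
    amplitudes (taken as midpoints between neighboring order statistics), so
    per-window baseline counts differ by at most one spike.
    """
    t0, t1 = window
    if t1 - t0 < BASELINE_WINDOW_S - 1e-9:
        raise ValueError("baseline window must be at least 100 s")
    sel = (stream.times_s >= t0) & (stream.times_s < t1)
    amps = np.sort(stream.amplitudes[sel])
    amps = amps[amps > noise_threshold]
    n = amps.size
    if n < k:
        raise ValueError("fewer above-noise baseline spikes than windows")
    if np.unique(amps).size < k:
        raise ValueError("fewer distinct amplitude values than windows")
    cuts = [int(round(i * n / k)) for i in range(k + 1)]
    edges = np.empty(k + 1)
    edges[0] = noise_threshold
    edges[-1] = np.inf
    for j in range(1, k):
        c = cuts[j]
        edges[j] = 0.5 * (amps[c - 1] + amps[c])
    counts = np.array([cuts[j + 1] - cuts[j] for j in range(k)], dtype=float)
    return AmplitudeWindows(noise_threshold, edges, counts, t1 - t0)


def window_series(stream: AmplitudeStream, windows: AmplitudeWindows,
                  bin_s: float, t0: float, t_end: float) -> list[BinnedSeries]:
    """Per-window binned spike counts; summed over windows they reproduce
    the total above-noise counts in every bin exactly."""
    n = int(round((t_end - t0) / bin_s))
    idx = windows.assign(stream.amplitudes)
    out = []
    for w in range(windows.k):
        sel = idx == w
        times = stream.times_s[sel]
        keep = (times >= t0) & (times < t0 + n * bin_s)
        bins = np.floor((times[keep] - t0) / bin_s).astype(int)
        counts = np.bincount(bins, minlength=n).astype(float)
        out.append(BinnedSeries(t0, bin_s, counts, "mua"))
    return out


@dataclasses.dataclass
class WindowContrast:
    magnitudes_pct: np.ndarray
    baseline_hz: np.ndarray
    event_hz: np.ndarray
    se_pct: np.ndarray
    heterogeneous: bool
    suppressed_window: int  # index of the most-suppressed window


def window_contrast(series_by_window: list[BinnedSeries],
                    event_window: tuple[float, float],
                    baseline_window: tuple[float, float],
                    amplitude_hz: float) -> WindowContrast:
    """Per-window suppression magnitudes and a heterogeneity verdict.

    Each window's magnitude uses the event-module formula
    ``M_w = 100 (B_w - S_w) / A``. The response is heterogeneous when the
    largest minus the smallest window magnitude exceeds twice the pooled
    standard error of that difference.
    """
    if not amplitude_hz > 0:
        raise ValueError("amplitude must be positive")
    b0, b1 = baseline_window
    e0, e1 = event_window
    k = len(series_by_window)
    B = np.empty(k)
    S = np.empty(k)
    se = np.empty(k)
    for w, s in enumerate(series_by_window):
        i0, i1 = s.index_at(b0), s.index_at(b1 - 1e-9) + 1
        B[w] = s.values[i0:i1].sum() / ((i1 - i0) * s.bin_s)
        j0, j1 = s.index_at(e0), s.index_at(e1 - 1e-9) + 1
        S[w] = s.values[j0:j1].sum() / ((j1 - j0) * s.bin_s)
        var = max(B[w], 1e-12) * (1.0 / (b1 - b0) + 1.0 / (e1 - e0))
        se[w] = 100.0 * math.sqrt(var) / amplitude_hz
    M = 100.0 * (B - S) / amplitude_hz
    hi, lo = int(np.argmax(M)), int(np.argmin(M))
    pooled = math.sqrt(se[hi] ** 2 + se[lo] ** 2)
    return WindowContrast(M, B, S, se, bool(M[hi] - M[lo] > 2.0 * pooled), hi)
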