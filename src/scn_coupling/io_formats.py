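"""Delimited file formats and in-memory containers for the recording streams.

All streams live on a common clock: seconds from recording start. Multiunit
activity (MUA) arrives as spike counts in uniform bins (2 s by default), the
passive-infrared (PIR) channel as 0/1 (or graded, non-negative) values on the
same grid, and the ethogram as labeled behavior intervals at 1-s resolution.
Files are tab-separated UTF-8 with "." decimals and Unix newlines; comment
lines start with "#".
"""
from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

#: the nine scoreable behavior categories
BEHAVIOR_LABELS = (
    "digging", "drinking", "eating", "grooming", "lying",
    "moving", "rearing", "sitting", "walking",
)
#: behaviors counted as rest; everything else counts as behavioral activity
QUIESCENT_LABELS = frozenset({"lying", "sitting"})
ACTIVE_LABELS = frozenset(BEHAVIOR_LABELS) - QUIESCENT_LABELS


class FormatError(ValueError):
    """A file or stream violates the documented format contract."""


# ---------------------------------------------------------------------------
# containers


@dataclasses.dataclass
class BinnedSeries:
    """Uniformly binned values (spike counts or PIR) over recording time.

    Parameters
    ----------
    t0 : float
        Start time (s) of the first bin.
    bin_s : float
        Bin width in seconds (> 0).
    values : array-like
        One non-negative value per bin.
    channel : str
        ``"mua"`` for spike counts, ``"pir"`` for the movement channel.
    """

    t0: float
    bin_s: float
    values: np.ndarray
    channel: str = "mua"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size < 1:
            raise FormatError("values must be a non-empty 1-D array")
        if not self.bin_s > 0:
            raise FormatError("bin width must be positive")
        if np.any(self.values < 0):
            raise FormatError("negative values are not allowed")

    @property
    def n(self) -> int:
        return int(self.values.size)

    @property
    def t_end(self) -> float:
        return self.t0 + self.n * self.bin_s

    @property
    def bin_starts(self) -> np.ndarray:
        return self.t0 + np.arange(self.n) * self.bin_s

    @property
    def bin_centers(self) -> np.ndarray:
        return self.bin_starts + 0.5 * self.bin_s

    @property
    def rates_hz(self) -> np.ndarray:
        """Counts converted to Hz (count / bin_s)."""
        return self.values / self.bin_s

    def index_at(self, t_s: float) -> int:
        """Index of the bin containing time ``t_s`` (clipped to range)."""
        i = int(math.floor((t_s - self.t0) / self.bin_s + 1e-9))
        return min(max(i, 0), self.n - 1)

    def slice_time(self, t_lo: float, t_hi: float) -> "BinnedSeries":
        """Sub-series of whole bins fully inside ``[t_lo, t_hi)``."""
        i0 = int(math.ceil((t_lo - self.t0) / self.bin_s - 1e-9))
        i1 = int(math.floor((t_hi - self.t0) / self.bin_s + 1e-9))
        i0, i1 = max(i0, 0), min(i1, self.n)
        if i1 <= i0:
            raise FormatError("empty time slice")
        return BinnedSeries(self.t0 + i0 * self.bin_s, self.bin_s,
                            self.values[i0:i1], self.channel)

    def rebin(self, new_bin_s: float, agg: str = "sum") -> "BinnedSeries":
        """Aggregate into wider bins (integer multiple of ``bin_s``).

        ``agg="sum"`` for counts, ``agg="any"`` for 0/1 indicator channels.
        A trailing partial bin is dropped.
        """
        factor = new_bin_s / self.bin_s
        if abs(factor - round(factor)) > 1e-9 or round(factor) < 1:
            raise FormatError("new bin width must be an integer multiple")
        f = int(round(factor))
        m = self.n // f
        if m < 1:
            raise FormatError("series too short to rebin")
        block = self.values[: m * f].reshape(m, f)
        if agg == "sum":
            out = block.sum(axis=1)
        elif agg == "any":
            out = (block > 0).any(axis=1).astype(float)
        else:
            raise ValueError(f"unknown aggregation {agg!r}")
        return BinnedSeries(self.t0, new_bin_s, out, self.channel)


@dataclasses.dataclass
class Ethogram:
    """Sorted, non-overlapping labeled behavior intervals (1-s resolution)."""

    start_s: np.ndarray
    end_s: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.start_s = np.asarray(self.start_s, dtype=float)
        self.end_s = np.asarray(self.end_s, dtype=float)
        self.labels = np.asarray(self.labels, dtype=object)
        if not (self.start_s.size == self.end_s.size == self.labels.size):
            raise FormatError("ethogram columns have unequal lengths")
        order = np.argsort(self.start_s, kind="stable")
        self.start_s = self.start_s[order]
        self.end_s = self.end_s[order]
        self.labels = self.labels[order]
        bad = set(self.labels) - set(BEHAVIOR_LABELS)
        if bad:
            raise FormatError(
                f"unknown behavior label(s) {sorted(bad)}; "
                f"valid labels are: {', '.join(BEHAVIOR_LABELS)}")
        if np.any(self.end_s <= self.start_s):
            i = int(np.argmax(self.end_s <= self.start_s))
            raise FormatError(f"interval {i + 1} has end <= start")
        if self.start_s.size > 1:
            overlap = self.start_s[1:] < self.end_s[:-1] - 1e-9
            if np.any(overlap):
                i = int(np.argmax(overlap))
                raise FormatError(f"intervals {i + 1} and {i + 2} overlap")

    @property
    def n(self) -> int:
        return int(self.start_s.size)

    @property
    def span(self) -> tuple[float, float]:
        return float(self.start_s[0]), float(self.end_s[-1])

    def slice_time(self, t_lo: float, t_hi: float) -> "Ethogram":
        """Intervals clipped to ``[t_lo, t_hi]`` (empty result is an error)."""
        s = np.maximum(self.start_s, t_lo)
        e = np.minimum(self.end_s, t_hi)
        keep = e > s
        if not np.any(keep):
            raise FormatError("ethogram slice is empty")
        return Ethogram(s[keep], e[keep], self.labels[keep])

    def activity_coverage(self, t0: float, bin_s: float, n: int) -> np.ndarray:
        """Seconds of behavioral activity (non-quiescent labels) per bin."""
        cov = np.zeros(n)
        for s, e, lab in zip(self.start_s, self.end_s, self.labels):
            if lab in QUIESCENT_LABELS:
                continue
            i0 = max(int(math.floor((s - t0) / bin_s)), 0)
            i1 = min(int(math.ceil((e - t0) / bin_s)), n)
            if i1 <= i0:
                continue
            starts = t0 + np.arange(i0, i1) * bin_s
            overlap = np.minimum(starts + bin_s, e) - np.maximum(starts, s)
            cov[i0:i1] += np.clip(overlap, 0.0, None)
        return cov

    def activity_indicator(self, t0: float, bin_s: float, n: int,
                           min_cover_s: float = 1.0) -> np.ndarray:
        """Boolean per-bin activity: active if covered >= ``min_cover_s``."""
        return self.activity_coverage(t0, bin_s, n) >= min_cover_s - 1e-9

    def active_bouts(self, merge_gap_s: float = 0.0) -> list["Bout"]:
        """Maximal runs of active intervals, merged across short gaps."""
        bouts: list[Bout] = []
        cur: list[tuple[float, float, str]] = []
        for s, e, lab in zip(self.start_s, self.end_s, self.labels):
            if lab in QUIESCENT_LABELS:
                continue
            if cur and s - cur[-1][1] > merge_gap_s + 1e-9:
                bouts.append(Bout.from_segments(cur))
                cur = []
            cur.append((float(s), float(e), str(lab)))
        if cur:
            bouts.append(Bout.from_segments(cur))
        return bouts

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"start_s": self.start_s, "end_s": self.end_s,
                             "behavior": self.labels})


@dataclasses.dataclass
class Bout:
    """One episode of behavioral activity (contiguous active intervals)."""

    onset_s: float
    offset_s: float
    segments: list  # list of (start_s, end_s, label)

    @classmethod
    def from_segments(cls, segments: Sequence[tuple[float, float, str]]) -> "Bout":
        return cls(segments[0][0], segments[-1][1], list(segments))

    @property
    def initiating(self) -> str:
        return self.segments[0][2]

    @property
    def duration_s(self) -> float:
        return self.offset_s - self.onset_s


@dataclasses.dataclass
class LightSchedule:
    """Light regime and the circadian time reference.

    ``reference_s`` is the recording time that maps to phase 0 (ZT0 under LD,
    CT0 in constant conditions). Day is phase [0, 12), night [12, 24);
    ZT12/CT12 marks lights-off / activity onset.
    """

    regime: str = "LD"  # LD | DD | LL
    period_h: float = 24.0
    reference_s: float = 0.0
    lights_on_s: float | None = 0.0    # within-cycle time of lights on (LD)
    lights_off_s: float | None = None  # within-cycle time of lights off (LD)

    def __post_init__(self) -> None:
        if self.regime not in ("LD", "DD", "LL"):
            raise FormatError(f"unknown regime {self.regime!r}")
        if not self.period_h > 0:
            raise FormatError("period_h must be positive")
        if self.regime == "LD":
            if self.lights_off_s is None:
                self.lights_off_s = self.period_h * 1800.0  # half the cycle
            if self.lights_on_s is None:
                raise FormatError("LD schedule requires both light transitions")

    @property
    def period_s(self) -> float:
        return self.period_h * 3600.0

    def phase_h(self, t_s):
        """Circadian phase in hours [0, 24) (ZT under LD, CT otherwise)."""
        t = np.asarray(t_s, dtype=float)
        frac = np.mod((t - self.reference_s) / self.period_s, 1.0)
        return frac * 24.0

    def is_day(self, t_s):
        return self.phase_h(t_s) < 12.0

    def cycle_starts(self, t_lo: float, t_hi: float) -> np.ndarray:
        """Lights-off-anchored cycle starts (phase 12) within ``[t_lo, t_hi]``."""
        first = self.reference_s + 0.5 * self.period_s
        k0 = int(math.ceil((t_lo - first) / self.period_s - 1e-9))
        k1 = int(math.floor((t_hi - first) / self.period_s + 1e-9))
        if k1 < k0:
            return np.empty(0)
        return first + np.arange(k0, k1 + 1) * self.period_s


@dataclasses.dataclass
class AmplitudeStream:
    """Per-spike timestamps and amplitudes (waveform mode output)."""

    times_s: np.ndarray
    amplitudes: np.ndarray
    labels: np.ndarray | None = None  # subpopulation of origin, if known

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        order = np.argsort(self.times_s, kind="stable")
        self.times_s = self.times_s[order]
        self.amplitudes = self.amplitudes[order]
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=object)[order]


@dataclasses.dataclass
class AlignedStreams:
    """MUA, PIR and ethogram trimmed to their common time span."""

    mua: BinnedSeries
    pir: BinnedSeries | None
    ethogram: Ethogram | None
    indicator: np.ndarray | None  # per-MUA-bin behavioral-activity flag


# ---------------------------------------------------------------------------
# readers / writers


def _data_rows(path) -> list[tuple[int, list[str]]]:
    rows = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            rows.append((lineno, line.split("\t") if "\t" in line else line.split()))
    return rows


def _is_number(tok: str) -> bool:
    try:
        float(tok)
        return True
    except ValueError:
        return False


def read_binned_series(path, channel: str = "mua") -> BinnedSeries:
    """Read a two-column (t_start_s, value) series; bin width is inferred.

    Non-uniform bins and negative values raise :class:`FormatError` naming
    the offending data row (1-based, counting data rows only).
    """
    rows = _data_rows(path)
    if rows and not all(_is_number(tok) for tok in rows[0][1][:2]):
        rows = rows[1:]  # header
    if len(rows) < 2:
        raise FormatError(f"{path}: need at least 2 data rows to infer bin width")
    t = np.array([float(r[1][0]) for r in rows])
    v = np.array([float(r[1][1]) for r in rows])
    d = t[1] - t[0]
    if not d > 0:
        raise FormatError(f"{path}: non-increasing times at row 2")
    diffs = np.diff(t)
    bad = np.abs(diffs - d) > 1e-6 * max(d, 1.0)
    if np.any(bad):
        row = int(np.argmax(bad)) + 2  # first row breaking uniformity
        raise FormatError(f"{path}: non-uniform bin width at row {row}")
    neg = v < 0
    if np.any(neg):
        row = int(np.argmax(neg)) + 1
        raise FormatError(f"{path}: negative value at row {row}")
    return BinnedSeries(float(t[0]), float(d), v, channel)


def write_binned_series(series: BinnedSeries, path) -> None:
    name = "count" if series.channel == "mua" else series.channel
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(f"t_start_s\t{name}\n")
        for t, v in zip(series.bin_starts, series.values):
            fh.write(f"{t:.10g}\t{v:.10g}\n")


def read_ethogram(path) -> Ethogram:
    """Read a (start_s, end_s, behavior) table; validates labels and overlap."""
    rows = _data_rows(path)
    if rows and not _is_number(rows[0][1][0]):
        rows = rows[1:]
    if not rows:
        raise FormatError(f"{path}: empty ethogram")
    for lineno, toks in rows:
        if len(toks) < 3:
            raise FormatError(f"{path}: line {lineno}: expected 3 columns")
    return Ethogram(
        np.array([float(r[1][0]) for r in rows]),
        np.array([float(r[1][1]) for r in rows]),
        np.array([r[1][2] for r in rows], dtype=object),
    )


def write_ethogram(eth: Ethogram, path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("start_s\tend_s\tbehavior\n")
        for s, e, lab in zip(eth.start_s, eth.end_s, eth.labels):
            fh.write(f"{s:.10g}\t{e:.10g}\t{lab}\n")


def read_amplitudes(path) -> AmplitudeStream:
    rows = _data_rows(path)
    if rows and not _is_number(rows[0][1][0]):
        rows = rows[1:]
    times = np.array([float(r[1][0]) for r in rows])
    amps = np.array([float(r[1][1]) for r in rows])
    labels = None
    if rows and len(rows[0][1]) > 2:
        labels = np.array([r[1][2] for r in rows], dtype=object)
    return AmplitudeStream(times, amps, labels)


def write_amplitudes(stream: AmplitudeStream, path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("spike_time_s\tamplitude\tsubpop\n")
        labels = stream.labels
        if labels is None:
            labels = np.array(["?"] * stream.times_s.size, dtype=object)
        for t, a, lab in zip(stream.times_s, stream.amplitudes, labels):
            fh.write(f"{t:.10g}\t{a:.10g}\t{lab}\n")


def align_streams(mua: BinnedSeries, pir: BinnedSeries | None = None,
                  ethogram: Ethogram | None = None,
                  min_cover_s: float = 1.0) -> AlignedStreams:
    """Trim all streams to their common span and derive the activity flag.

    A MUA bin counts as behaviorally active when non-quiescent behavior covers
    at least ``min_cover_s`` of it (default 1 s of a 2-s bin).
    """
    t_lo, t_hi = mua.t0, mua.t_end
    if pir is not None:
        if abs(pir.bin_s - mua.bin_s) > 1e-9:
            raise FormatError("PIR and MUA bin widths differ")
        t_lo, t_hi = max(t_lo, pir.t0), min(t_hi, pir.t_end)
    if ethogram is not None:
        s, e = ethogram.span
        t_lo, t_hi = max(t_lo, s), min(t_hi, e)
    if t_hi - t_lo < mua.bin_s:
        raise FormatError("streams have empty time intersection")
    mua_t = mua.slice_time(t_lo, t_hi)
    pir_t = pir.slice_time(mua_t.t0, mua_t.t_end) if pir is not None else None
    eth_t = ethogram.slice_time(mua_t.t0, mua_t.t_end) if ethogram is not None else None
    indicator = None
    if eth_t is not None:
        indicator = eth_t.activity_indicator(mua_t.t0, mua_t.bin_s, mua_t.n,
                                             min_cover_s)
    return AlignedStreams(mua_t, pir_t, eth_t, indicator)


def write_event_table(events_df: pd.DataFrame, path, meta: dict | None = None) -> None:
    """Write an event table as TSV (6 significant digits) plus a JSON sidecar."""
    path = Path(path)
    df = events_df.copy()
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        df.to_csv(fh, sep="\t", index=False, float_format="%.6g", lineterminator="\n")
    if meta is not None:
        sidecar = path.with_suffix(path.suffix + ".meta.json")
        with open(sidecar, "w", encoding="utf-8") as fh:
            json.dump(meta, fh, indent=1, sort_keys=True, default=str)


def read_event_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
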