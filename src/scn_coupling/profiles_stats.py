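"""Behavior-conditioned circadian profiles and group statistics.

Conditioning the circadian MUA profile on the PIR channel (active vs
inactive 10-s bins) separates the rhythm in the presence of behavior from
the rhythm in its absence; the two curves define the amplitude the clock
would attain if activity were concentrated in the night (maximal) or in the
day (reduced). Group statistics reproduce the classical analyses: one-way
ANOVA across initiating-behavior types with Bonferroni post-hoc tests, and
day/night magnitude comparison (two-way with animal as a blocking factor
when cohort data are present).
"""
from __future__ import annotations

import dataclasses
import itertools
import math
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import BinnedSeries, LightSchedule


@dataclasses.dataclass
class ConditionedProfile:
    """Phase-folded MUA levels split by behavioral state."""

    phase_h: np.ndarray          # phase-bin centers (h)
    active_mean_hz: np.ndarray   # NaN where a phase bin holds no active bins
    inactive_mean_hz: np.ndarray
    active_smooth_hz: np.ndarray
    inactive_smooth_hz: np.ndarray
    n_active: np.ndarray
    n_inactive: np.ndarray
    partial: bool                # True if one subset is empty over >50% of phases

    @property
    def active_coverage(self) -> float:
        return float(np.mean(self.n_active > 0))

    @property
    def inactive_coverage(self) -> float:
        return float(np.mean(self.n_inactive > 0))


def _circular_smooth(values: np.ndarray, counts: np.ndarray, win: int) -> np.ndarray:
    """Count-weighted circular moving average; empty stretches interpolated."""
    n = values.size
    v = np.where(counts > 0, values * counts, 0.0)
    w = counts.astype(float)
    h = win // 2
    idx = (np.arange(-h, h + 1)[None, :] + np.arange(n)[:, None]) % n
    sv = v[idx].sum(axis=1)
    sw = w[idx].sum(axis=1)
    out = np.divide(sv, sw, out=np.full(n, np.nan), where=sw > 0)
    nan = np.isnan(out)
    if nan.any() and not nan.all():
        i = np.arange(n)
        out[nan] = np.interp(i[nan], i[~nan], out[~nan], period=n)
    return out


def conditioned_profiles(mua: BinnedSeries, pir: BinnedSeries,
                         schedule: LightSchedule, rebin_s: float = 10.0,
                         phase_bin_h: float = 0.1,
                         smooth_bandwidth_h: float = 1.0) -> ConditionedProfile:
    """Split the phase-folded MUA profile by PIR-detected activity.

    A 10-s bin is "active" if any PIR signal fell within it. Each subset is
    averaged per phase bin and smoothed with a circular moving average (the
    rhythm smoother applied on the folded axis).
    """
    m = mua.rebin(rebin_s)
    p = pir.rebin(rebin_s, agg="any")
    n = min(m.n, p.n)
    hz = m.values[:n] / rebin_s
    active = p.values[:n] > 0
    phase = schedule.phase_h(m.bin_starts[:n] + 0.5 * rebin_s)
    n_bins = int(round(24.0 / phase_bin_h))
    bin_idx = np.minimum((phase / phase_bin_h).astype(int), n_bins - 1)

    def _fold(mask):
        cnt = np.bincount(bin_idx[mask], minlength=n_bins)
        tot = np.bincount(bin_idx[mask], weights=hz[mask], minlength=n_bins)
        mean = np.divide(tot, cnt, out=np.full(n_bins, np.nan), where=cnt > 0)
        return mean, cnt

    act_mean, act_n = _fold(active)
    inact_mean, inact_n = _fold(~active)
    win = max(int(round(smooth_bandwidth_h / phase_bin_h)) | 1, 1)
    act_sm = (_circular_smooth(np.nan_to_num(act_mean), act_n, win)
              if act_n.sum() else np.full(n_bins, np.nan))
    inact_sm = (_circular_smooth(np.nan_to_num(inact_mean), inact_n, win)
                if inact_n.sum() else np.full(n_bins, np.nan))
    partial = (np.mean(act_n == 0) > 0.5) or (np.mean(inact_n == 0) > 0.5)
    centers = (np.arange(n_bins) + 0.5) * phase_bin_h
    return ConditionedProfile(centers, act_mean, inact_mean, act_sm, inact_sm,
                              act_n, inact_n, partial)


def amplitude_scenarios(profile: ConditionedProfile) -> dict:
    """Amplitude of the rhythm under night-active vs day-active behavior.

    night_active: behavior confined to the night -> peak of the inactive
    curve minus trough of the active curve (amplitude is maximal).
    day_active: behavior confined to the day -> peak of the active curve
    minus trough of the inactive curve (amplitude is reduced).
    Values in Hz and as % of the inactive-curve (undisturbed) amplitude.
    """
    for name, curve in (("active", profile.active_smooth_hz),
                        ("inactive", profile.inactive_smooth_hz)):
        if np.all(np.isnan(curve)):
            raise ValueError(f"{name} curve undefined; cannot form scenarios")
    pk_in = float(np.nanmax(profile.inactive_smooth_hz))
    tr_in = float(np.nanmin(profile.inactive_smooth_hz))
    pk_ac = float(np.nanmax(profile.active_smooth_hz))
    tr_ac = float(np.nanmin(profile.active_smooth_hz))
    a0 = pk_in - tr_in
    night_active = pk_in - tr_ac
    day_active = pk_ac - tr_in
    return {
        "baseline_amplitude_hz": a0,
        "night_active_amplitude_hz": night_active,
        "day_active_amplitude_hz": day_active,
        "night_active_pct": 100.0 * night_active / a0 if a0 > 0 else float("nan"),
        "day_active_pct": 100.0 * day_active / a0 if a0 > 0 else float("nan"),
    }


def one_way_anova(groups: list[np.ndarray]) -> tuple[float, float]:
    """Classical one-way ANOVA from sums of squares; returns (F, p).

    Degenerate inputs: zero within-group variance with distinct means gives
    (inf, 0.0); identical group means give F ~ 0, p ~ 1.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    k = len(groups)
    if k < 2 or any(g.size < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 observations each")
    n_tot = sum(g.size for g in groups)
    grand = sum(g.sum() for g in groups) / n_tot
    ss_between = sum(g.size * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_b, df_w = k - 1, n_tot - k
    ms_b = ss_between / df_b
    ms_w = ss_within / df_w
    if ms_w == 0.0:
        return (0.0, 1.0) if ms_b == 0.0 else (math.inf, 0.0)
    f = ms_b / ms_w
    return float(f), float(stats.f.sf(f, df_b, df_w))


def _bonferroni_pairwise(groups: dict[str, np.ndarray], ms_w: float,
                         df_w: int) -> dict[tuple[str, str], float]:
    """Pooled-variance pairwise t-tests with Bonferroni correction."""
    names = sorted(groups)
    pairs = list(itertools.combinations(names, 2))
    out = {}
    for a, b in pairs:
        ga, gb = groups[a], groups[b]
        se = math.sqrt(ms_w * (1.0 / ga.size + 1.0 / gb.size))
        if se == 0:
            p = 0.0 if ga.mean() != gb.mean() else 1.0
        else:
            t = (ga.mean() - gb.mean()) / se
            p = 2.0 * float(stats.t.sf(abs(t), df_w))
        out[(a, b)] = min(p * len(pairs), 1.0)
    return out


@dataclasses.dataclass
class TypeStats:
    table: pd.DataFrame                       # mean, sem, n per behavior type
    f_stat: float
    p_value: float
    pairwise_p: dict                          # Bonferroni-adjusted p per pair
    significant: bool


def _magnitude_events(events_df: pd.DataFrame) -> pd.DataFrame:
    """Events entering magnitude statistics: detected, and with a baseline
    stationary enough for the constant-B definition of M to hold."""
    df = events_df
    if "detected" in df:
        df = df[df["detected"]]
    if "stationary" in df:
        df = df[df["stationary"]]
    return df


def magnitude_by_type(events_df: pd.DataFrame, alpha: float = 0.01) -> TypeStats:
    """Suppression magnitude by initiating behavior: mean +/- SEM and ANOVA."""
    df = _magnitude_events(events_df)
    groups = {}
    for name, sub in df.groupby("initiating"):
        vals = sub["magnitude_pct"].to_numpy(dtype=float)
        if vals.size < 2:
            warnings.warn(f"behavior type {name!r} has n < 2; excluded")
            continue
        groups[name] = vals
    if len(groups) < 2:
        raise ValueError("need at least 2 behavior types with >= 2 events")
    rows = [{"initiating": k, "mean_pct": v.mean(),
             "sem_pct": v.std(ddof=1) / math.sqrt(v.size), "n": v.size}
            for k, v in sorted(groups.items())]
    f, p = one_way_anova(list(groups.values()))
    n_tot = sum(v.size for v in groups.values())
    df_w = n_tot - len(groups)
    ms_w = (sum(((v - v.mean()) ** 2).sum() for v in groups.values()) / df_w
            if df_w > 0 else 0.0)
    pairwise = _bonferroni_pairwise(groups, ms_w, df_w)
    return TypeStats(pd.DataFrame(rows), f, p, pairwise, bool(p < alpha))


@dataclasses.dataclass
class DayNightStats:
    day_mean: float
    day_sem: float
    day_n: int
    night_mean: float
    night_sem: float
    night_n: int
    p_value: float
    significant: bool
    method: str


def day_night_stats(events_df: pd.DataFrame, alpha: float = 0.05) -> DayNightStats:
    """Day (phase 0-12) vs night (12-24) suppression magnitudes.

    With events from >= 2 animals the comparison is a two-way ANOVA with the
    animal as a blocking factor (statsmodels OLS); otherwise a one-way ANOVA
    across the two phase classes.
    """
    df = _magnitude_events(events_df)
    day = df[df["is_day"]]["magnitude_pct"].to_numpy(dtype=float)
    night = df[~df["is_day"]]["magnitude_pct"].to_numpy(dtype=float)
    if day.size == 0 or night.size == 0:
        raise ValueError("events fall into only one phase class")

    def _sem(v):
        return float(v.std(ddof=1) / math.sqrt(v.size)) if v.size > 1 else float("nan")

    n_animals = df["animal"].nunique() if "animal" in df else 1
    if n_animals >= 2 and day.size > 1 and night.size > 1:
        import statsmodels.formula.api as smf
        from statsmodels.stats.anova import anova_lm
        work = df[["magnitude_pct", "is_day", "animal"]].copy()
        model = smf.ols("magnitude_pct ~ C(is_day) + C(animal)", data=work).fit()
        tab = anova_lm(model, typ=2)
        p = float(tab.loc["C(is_day)", "PR(>F)"])
        method = "two-way ANOVA (animal block)"
    else:
        _, p = one_way_anova([day, night])
        method = "one-way ANOVA"
    return DayNightStats(float(day.mean()), _sem(day), int(day.size),
                         float(night.mean()), _sem(night), int(night.size),
                         p, bool(p < alpha), method)


def per_hour_profile(events_df: pd.DataFrame) -> pd.DataFrame:
    """Mean magnitude and event count per circadian hour (24 bins, [h, h+1))."""
    df = events_df[events_df["detected"]] if "detected" in events_df else events_df
    if len(df) < 1:
        raise ValueError("need at least one event")
    hours = np.minimum(np.floor(df["phase_h"].to_numpy(dtype=float)), 23).astype(int)
    mags = df["magnitude_pct"].to_numpy(dtype=float)
    rows = []
    for h in range(24):
        sel = hours == h
        rows.append({"hour": h, "n": int(sel.sum()),
                     "mean_magnitude_pct": float(mags[sel].mean()) if sel.any()
                     else float("nan")})
    return pd.DataFrame(rows)
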