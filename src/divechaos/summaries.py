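"""Diurnal statistics, time budgets and episode comparisons.

All summaries are pure functions of (timestamps, values/labels, options):
rerunning them on persisted tables reproduces the outputs exactly.  Hour of
day is read on a configurable local clock (``utc_offset_h``); "day" defaults
to 06:00-18:00.  No hypothesis tests are attached — the day/night eCDF gap
is a descriptive statistic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import ks_2samp

from .errors import ConfigError, DataError


def _hours(times, utc_offset_h: float) -> np.ndarray:
    t = pd.DatetimeIndex(times)
    h = t.hour + t.minute / 60.0 + t.second / 3600.0
    return (np.asarray(h, dtype=float) + utc_offset_h) % 24.0


def diurnal_percentiles(times, values, bin_h: int = 3,
                        percentiles=(5, 50, 75),
                        utc_offset_h: float = 0.0) -> pd.DataFrame:
    """Per-hour-of-day-bin percentiles of a feature.

    Bins tile 24 h exactly; empty bins yield NaN rows.  Window membership
    is decided by the timestamp passed in (use window midpoints).
    """
    if 24 % bin_h != 0:
        raise ConfigError("bin_h must divide 24")
    h = _hours(times, utc_offset_h)
    v = np.asarray(values, dtype=float)
    edges = np.arange(0, 25, bin_h)
    rows = []
    for a, b in zip(edges[:-1], edges[1:]):
        sel = (h >= a) & (h < b) & np.isfinite(v)
        row = {"bin_start_h": a, "bin_h": bin_h, "n": int(sel.sum())}
        for p in percentiles:
            row[f"p{p}"] = float(np.percentile(v[sel], p)) if sel.any() else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class DayNightECDF:
    day_x: np.ndarray
    day_f: np.ndarray
    night_x: np.ndarray
    night_f: np.ndarray
    max_gap: float
    n_day: int
    n_night: int


def day_night_ecdf(times, values, day_window=(6.0, 18.0),
                   utc_offset_h: float = 0.0) -> DayNightECDF:
    """Empirical CDFs of a feature for day vs night windows.

    ``max_gap`` is the Kolmogorov-style maximum vertical distance between
    the two eCDFs, reported descriptively.
    """
    h = _hours(times, utc_offset_h)
    v = np.asarray(values, dtype=float)
    fin = np.isfinite(v)
    is_day = (h >= day_window[0]) & (h < day_window[1])
    day = v[fin & is_day]
    night = v[fin & ~is_day]
    if day.size == 0 or night.size == 0:
        raise DataError("day or night side is empty")
    dx = np.sort(day)
    nx = np.sort(night)
    return DayNightECDF(
        day_x=dx, day_f=np.arange(1, dx.size + 1) / dx.size,
        night_x=nx, night_f=np.arange(1, nx.size + 1) / nx.size,
        max_gap=float(ks_2samp(day, night).statistic),
        n_day=day.size, n_night=night.size)


def time_budget(labels: pd.DataFrame, min_confidence: float | None = None
                ) -> pd.DataFrame:
    """Fraction of assigned windows per semantic tag.

    With ``min_confidence`` the budget is restricted to high-membership
    windows.  A zero denominator is flagged rather than an error.  A
    grouped ``bouts`` row aggregates deep + shallow bouts.
    """
    sel = labels["tag"].notna()
    if min_confidence is not None:
        sel &= labels["confidence"] >= min_confidence
    sub = labels[sel]
    n = len(sub)
    tags = [t for t in labels["tag"].dropna().unique()]
    rows = []
    for t in sorted(tags):
        c = int((sub["tag"] == t).sum())
        rows.append({"tag": t, "n": c,
                     "fraction": c / n if n else np.nan})
    bout_tags = {"deep-bout", "shallow-bout"}
    if bout_tags & set(tags):
        c = int(sub["tag"].isin(bout_tags).sum())
        rows.append({"tag": "bouts", "n": c,
                     "fraction": c / n if n else np.nan})
    out = pd.DataFrame(rows)
    out.attrs["n_windows"] = n
    out.attrs["zero_denominator"] = n == 0
    return out


def daypart_partition(labels: pd.DataFrame, bin_h: int = 3,
                      utc_offset_h: float = 0.0,
                      time_col: str = "window_mid") -> pd.DataFrame:
    """Per-daypart tag fractions; each populated bin row sums to 1."""
    if 24 % bin_h != 0:
        raise ConfigError("bin_h must divide 24")
    col = time_col if time_col in labels else "window_start"
    sub = labels[labels["tag"].notna()]
    h = _hours(sub[col], utc_offset_h)
    tags = sorted(sub["tag"].unique())
    edges = np.arange(0, 25, bin_h)
    rows = []
    for a, b in zip(edges[:-1], edges[1:]):
        m = (h >= a) & (h < b)
        n = int(m.sum())
        row = {"bin_start_h": a, "n": n}
        for t in tags:
            row[t] = float((sub["tag"][m] == t).sum() / n) if n else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def cumulative_tag_count(labels: pd.DataFrame, tag: str) -> pd.Series:
    """Non-decreasing cumulative count of windows carrying ``tag``."""
    known = set(labels["tag"].dropna().unique())
    if tag not in known:
        raise ConfigError(f"unknown tag {tag!r}; have {sorted(known)}")
    ind = (labels["tag"] == tag).astype(int)
    out = ind.cumsum()
    out.index = labels["window_start"] if "window_start" in labels else out.index
    out.name = f"cumulative_{tag}"
    return out


@dataclass
class BeforeAfter:
    median_before: float
    median_after: float
    difference: float
    ci_low: float
    ci_high: float
    n_before: int
    n_after: int
    truncated: bool


def before_after_median(times, values, split, span_days: float,
                        n_boot: int = 1000, seed: int = 0) -> BeforeAfter:
    """Median of a feature over [split - span, split) vs [split, split + span).

    The difference (after - before) carries a seeded bootstrap percentile
    interval (``n_boot`` resamples).  Spans exceeding the record are
    truncated and flagged; an empty side or a zero span is an error.
    """
    if span_days <= 0:
        raise ConfigError("span must be positive")
    t = pd.DatetimeIndex(times)
    v = np.asarray(values, dtype=float)
    split = pd.Timestamp(split)
    if split.tzinfo is None and t.tz is not None:
        split = split.tz_localize(t.tz)
    span = pd.Timedelta(days=span_days)
    before = v[(t >= split - span) & (t < split) & np.isfinite(v)]
    after = v[(t >= split) & (t < split + span) & np.isfinite(v)]
    if before.size == 0 or after.size == 0:
        raise DataError("before or after span is empty")
    truncated = (t.min() > split - span) or (t.max() < split + span)
    mb, ma = float(np.median(before)), float(np.median(after))
    rng = np.random.default_rng(seed)
    diffs = np.empty(n_boot)
    for i in range(n_boot):
        diffs[i] = (np.median(rng.choice(after, after.size))
                    - np.median(rng.choice(before, before.size)))
    lo, hi = np.percentile(diffs, [2.5, 97.5])
    return BeforeAfter(mb, ma, ma - mb, float(lo), float(hi),
                       before.size, after.size, truncated)
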