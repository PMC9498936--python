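"""Reading, validating and regularizing 1-Hz depth records.

A :class:`DepthRecord` holds the observable x(t): a uniformly sampled depth
series (metres, positive down) with an absolute UTC start time.  Everything
downstream (embedding, invariants, wavelets) assumes a strictly uniform grid,
so the reader either enforces uniformity or hands the irregular series to
:func:`regularize`.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError

#: negative sensor readings within this tolerance (m) are clipped to zero;
#: anything more negative is treated as corrupt.
NEGATIVE_DEPTH_TOL = 0.5


@dataclass
class DepthRecord:
    """Uniformly sampled depth series.

    Parameters
    ----------
    t0 : pandas.Timestamp
        Absolute start time (UTC).
    dt : float
        Sample interval in seconds (1.0 for the records this package targets).
    depth : ndarray
        Depth in metres, positive down.
    uniform : bool
        False only for records read with ``strict=False`` that still need
        :func:`regularize`; such records carry their own ``times_s``.
    times_s : ndarray, optional
        Sample times in seconds from ``t0`` (irregular records only).
    filled : ndarray of bool, optional
        Marks samples that were gap-filled by :func:`regularize`.
    """

    t0: pd.Timestamp
    dt: float
    depth: np.ndarray
    uniform: bool = True
    times_s: np.ndarray | None = None
    filled: np.ndarray | None = None
    gap_log: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth, dtype=float)
        self.t0 = pd.Timestamp(self.t0)
        if self.t0.tzinfo is None:
            self.t0 = self.t0.tz_localize("UTC")
        if self.dt <= 0:
            raise ConfigError("dt must be positive")
        if self.depth.ndim != 1 or self.depth.size == 0:
            raise DataError("empty record")
        if self.uniform:
            finite = self.depth[np.isfinite(self.depth)]
            if finite.size and finite.min() < -NEGATIVE_DEPTH_TOL:
                raise DataError(
                    f"negative depths beyond tolerance ({finite.min():.2f} m)"
                )
            np.clip(self.depth, 0.0, None, out=self.depth)

    @property
    def n(self) -> int:
        return self.depth.size

    @property
    def duration_s(self) -> float:
        return (self.n - 1) * self.dt

    def times(self) -> pd.DatetimeIndex:
        """Absolute UTC timestamps of every sample."""
        if self.uniform:
            offs = np.arange(self.n) * self.dt
        else:
            offs = self.times_s
        return self.t0 + pd.to_timedelta(offs, unit="s")


@dataclass
class SpeedSeries:
    """Instantaneous vertical speed dD/dt, positive on descent."""

    speed: np.ndarray
    dt: float

    @property
    def n(self) -> int:
        return self.speed.size


def _parse_time_column(col: pd.Series) -> tuple[pd.Timestamp, np.ndarray]:
    """Return (t0, seconds-from-t0) from a numeric or datetime-like column."""
    try:
        secs = col.astype(float).to_numpy()
        t0 = pd.Timestamp("1970-01-01", tz="UTC") + pd.to_timedelta(secs[0], unit="s")
        return t0, secs - secs[0]
    except (ValueError, TypeError):
        ts = pd.to_datetime(col, utc=True, format="ISO8601")
        secs = (ts - ts.iloc[0]).dt.total_seconds().to_numpy()
        return ts.iloc[0], secs


def read_depth_record(
    path,
    dialect: dict | None = None,
    strict: bool = True,
) -> DepthRecord:
    """Read a depth record from CSV.

    Accepts either a two-column file ``timestamp_utc,depth_m`` (header
    optional; timestamps numeric seconds or ISO-8601) or a single depth
    column with ``dialect={"t0": ..., "dt": ...}``.

    With ``strict=True`` (default) non-uniform sampling raises
    ``DataError("non-uniform sampling; regularize required")``; with
    ``strict=False`` the irregular record is returned for
    :func:`regularize`.  NaN depths are kept and flagged via ``gap_log``
    for regularization.
    """
    if isinstance(path, io.StringIO):
        text_src = path
    else:
        text_src = str(path)
    try:
        df = pd.read_csv(text_src, header=None, comment="#")
    except pd.errors.EmptyDataError:
        raise DataError("empty record") from None
    if df.empty:
        raise DataError("empty record")
    # sniff a header row
    first = df.iloc[0]
    if any(isinstance(v, str) and not _is_number(v) for v in first):
        df = df.iloc[1:].reset_index(drop=True)
        if df.empty:
            raise DataError("empty record")

    if df.shape[1] == 1:
        if not dialect or "dt" not in dialect:
            raise ConfigError("single-column input requires dialect with 't0' and 'dt'")
        depth = df.iloc[:, 0].astype(float).to_numpy()
        t0 = pd.Timestamp(dialect.get("t0", "1970-01-01"))
        dt = float(dialect["dt"])
        rec = DepthRecord(t0=t0, dt=dt, depth=depth)
        _log_nan_gaps(rec)
        return rec

    t0, secs = _parse_time_column(df.iloc[:, 0])
    depth = df.iloc[:, 1].astype(float).to_numpy()
    if np.any(np.diff(secs) <= 0):
        raise DataError("non-monotone timestamps")
    steps = np.diff(secs)
    # smallest step, not the median: a gappy record's median step is a gap
    dt = float(steps.min()) if steps.size else 1.0
    uniform = steps.size == 0 or np.allclose(steps, dt, rtol=0, atol=1e-9)
    if not uniform and strict:
        raise DataError("non-uniform sampling; regularize required")
    rec = DepthRecord(
        t0=t0, dt=dt, depth=depth, uniform=uniform,
        times_s=None if uniform else secs,
    )
    _log_nan_gaps(rec)
    return rec


def _is_number(s: str) -> bool:
    try:
        float(s)
        return True
    except ValueError:
        return False


def _log_nan_gaps(rec: DepthRecord) -> None:
    bad = ~np.isfinite(rec.depth)
    if bad.any():
        rec.gap_log.append(
            {"kind": "nan", "count": int(bad.sum()), "first_index": int(bad.argmax())}
        )


def write_depth_record(record: DepthRecord, path, state: np.ndarray | None = None) -> None:
    """Write ``timestamp_utc,depth_m`` CSV; round-trips bit-exactly.

    Depths are written with shortest round-trip ``repr`` so re-reading
    reproduces the float64 values exactly.  ``state`` (optional) adds a
    third column, used by the simulator to persist ground truth.
    """
    ts = record.times().strftime("%Y-%m-%dT%H:%M:%S")
    with open(path, "w") as fh:
        fh.write("timestamp_utc,depth_m" + (",state" if state is not None else "") + "\n")
        if state is not None:
            for t, d, s in zip(ts, record.depth, state):
                fh.write(f"{t},{float(d)!r},{s}\n")
        else:
            for t, d in zip(ts, record.depth):
                fh.write(f"{t},{float(d)!r}\n")


def regularize(
    record: DepthRecord,
    gap_policy: str = "linear",
    max_gap_s: float = 600.0,
) -> DepthRecord:
    """Return a strictly uniform record with gaps filled.

    ``gap_policy`` is ``"linear"`` (interpolate) or ``"hold"`` (carry last
    value forward).  Any gap longer than ``max_gap_s`` raises ``DataError``
    naming the gap span.  Idempotent on already-regular records.
    """
    if gap_policy not in ("linear", "hold"):
        raise ConfigError(f"unknown gap_policy {gap_policy!r}")
    dt = record.dt
    if record.uniform:
        secs = np.arange(record.n) * dt
    else:
        secs = record.times_s
    depth = record.depth
    ok = np.isfinite(depth)
    if record.uniform and ok.all():
        return record  # identity: nothing to fill

    # snap observed samples onto the uniform grid
    grid_n = int(round(secs[-1] / dt)) + 1
    idx = np.round(secs / dt).astype(int)
    if np.any(np.diff(idx) < 1):
        raise DataError("timestamps collide on the uniform grid")
    full = np.full(grid_n, np.nan)
    full[idx[ok]] = depth[ok]

    missing = ~np.isfinite(full)
    gap_log = list(record.gap_log)
    if missing.any():
        # contiguous gap runs
        edges = np.flatnonzero(np.diff(np.concatenate(([0], missing.view(np.int8), [0]))))
        for a, b in zip(edges[::2], edges[1::2]):
            span = (b - a) * dt
            if span > max_gap_s:
                raise DataError(
                    f"gap of {span:.0f} s at t={a * dt:.0f}..{b * dt:.0f} s "
                    f"exceeds max_gap_s={max_gap_s:.0f}"
                )
            gap_log.append({"kind": "filled", "start_s": a * dt, "span_s": span,
                            "policy": gap_policy})
        known = np.flatnonzero(~missing)
        if known.size == 0:
            raise DataError("record has no finite samples")
        if gap_policy == "linear":
            full = np.interp(np.arange(grid_n), known, full[known])
        else:  # hold
            last = np.maximum.accumulate(np.where(missing, -1, np.arange(grid_n)))
            last = np.where(last < 0, known[0], last)
            full = full[last]

    out = DepthRecord(t0=record.t0, dt=dt, depth=full, gap_log=gap_log)
    out.filled = np.zeros(out.n, dtype=bool)
    out.filled[np.setdiff1d(np.arange(grid_n), idx[ok])] = True
    return out


def vertical_speed(record: DepthRecord) -> SpeedSeries:
    """Central-difference dD/dt (one-sided at the edges), m/s.

    Positive on descent because depth is positive down.
    """
    if not record.uniform:
        raise DataError("vertical_speed requires a regularized record")
    if record.n < 3:
        raise DataError("need at least 3 samples for vertical speed")
    return SpeedSeries(speed=np.gradient(record.depth, record.dt), dt=record.dt)


def depth_quantiles(record: DepthRecord, probs) -> np.ndarray:
    """Empirical depth quantiles (linear interpolation between order stats)."""
    probs = np.atleast_1d(np.asarray(probs, dtype=float))
    if probs.size == 0 or np.any(probs <= 0) or np.any(probs > 1):
        raise ConfigError("probs must lie in (0, 1]")
    if record.n == 0:
        raise DataError("empty record")
    return np.quantile(record.depth, probs)
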