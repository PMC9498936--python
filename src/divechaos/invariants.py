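"""Attractor measures on the reconstructed state space.

Per-point / per-step measures:

* ``L`` — Euclidean distance of each embedded point from the origin, the
  magnitude of departure from the near-surface "core" of the attractor
  (metres, since every coordinate is a depth);
* ``E_k = v^2 / 2`` — an equivalent kinetic energy, where v is the speed
  of motion along the reconstructed trajectory (state-space metres per
  second), a measure of how energetic / engaged the behavior is.

Window-level invariants (30-min windows sliding in 10-min steps by
default):

* ``Lambda_m`` — maximum Lyapunov exponent by the Rosenstein small-data
  algorithm (mean log divergence of initially close, temporally separated
  trajectory pairs; least-squares slope of the early divergence curve);
* ``d`` — correlation dimension by the Grassberger–Procaccia pair-count
  scaling, with the scaling region selected automatically as the longest
  run of locally constant log-log slope.

These are treated as relative measures for comparing windows, not as
precision estimates of dynamical invariants.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .errors import ConfigError, DataError, NumericalError
from .embedding import EmbeddingParams, StateSpaceCloud, delay_embed
from .io_depth import DepthRecord
from .timescales import sliding_dominant_period

#: global fallback dominant period (s) when a window has none: the deep-bout
#: dive cycle of about 17 min.
FALLBACK_PERIOD_S = 1020.0


def euclidean_distance(cloud: StateSpaceCloud) -> np.ndarray:
    """Distance of every embedded point from the origin (m)."""
    if cloud.n == 0:
        raise DataError("empty cloud")
    return np.linalg.norm(cloud.points, axis=1)


def kinetic_energy(cloud: StateSpaceCloud, dt_step: float | None = None
                   ) -> tuple[np.ndarray, np.ndarray]:
    """State-space speed v and kinetic energy E_k = v^2/2 per step.

    ``v_i = ||y(i+1) - y(i)|| / dt_step`` with ``dt_step`` defaulting to the
    sampling interval; lengths are ``n - 1``.
    """
    if cloud.n < 2:
        raise DataError("need at least 2 points")
    dt_step = cloud.dt if dt_step is None else dt_step
    v = np.linalg.norm(np.diff(cloud.points, axis=0), axis=1) / dt_step
    return v, 0.5 * v ** 2


@dataclass
class LyapunovResult:
    lam: float                  # 1/s
    k_steps: np.ndarray
    mean_log_div: np.ndarray
    n_pairs: int
    degenerate: bool = False


def max_lyapunov(cloud: StateSpaceCloud, dt: float | None = None,
                 mean_period_s: float = FALLBACK_PERIOD_S,
                 fit_range: int | None = None,
                 theiler_s: float | None = None,
                 dists: np.ndarray | None = None) -> LyapunovResult:
    """Rosenstein maximum Lyapunov exponent.

    Each point is paired with its nearest neighbor at temporal separation
    greater than the Theiler constraint (one mean period by default); the
    mean log distance of the pairs is tracked over ``fit_range`` steps
    (default: half a mean period) and the exponent is the least-squares
    slope of that curve divided by ``dt``.

    A perfectly recurrent orbit (all pair distances exactly zero) is
    reported as ``lam = 0`` with ``degenerate=True`` rather than an error.
    """
    pts = cloud.points
    n = pts.shape[0]
    dt = cloud.dt if dt is None else dt
    if n < 50:
        raise DataError("too few points for a Lyapunov estimate")
    theiler_s = mean_period_s if theiler_s is None else theiler_s
    w = max(1, int(round(theiler_s / dt)))
    K = fit_range if fit_range is not None else max(3, int(round(0.5 * mean_period_s / dt)))
    K = int(min(K, n - 2))

    if dists is not None:
        nn = _nearest_from_matrix(dists, w)
    else:
        nn = _nearest_with_exclusion(pts, w)
    j = np.flatnonzero(nn >= 0)
    j = j[(j + K < n) & (nn[j] + K < n)]
    if j.size == 0:
        raise NumericalError("no valid neighbor pairs under the Theiler "
                             "constraint and fit horizon")
    # the mean log-divergence curve is smooth, so long fit horizons are
    # evaluated on a strided step grid (the fitted slope is unchanged)
    stride = max(1, K // 150)
    ks = np.arange(0, K + 1, stride)
    ia = j[:, None] + ks[None, :]
    ib = nn[j][:, None] + ks[None, :]
    d = np.linalg.norm(pts[ia] - pts[ib], axis=2)
    with np.errstate(divide="ignore"):
        logd = np.where(d > 0, np.log(np.maximum(d, 1e-300)), np.nan)
    counts = np.sum(~np.isnan(logd), axis=0)
    y = np.full(ks.size, np.nan)
    has = counts > 0
    y[has] = np.nanmean(logd[:, has], axis=0)
    fit_mask = has & (ks >= 1)
    if fit_mask.sum() < 3:
        if np.all(d == 0):
            return LyapunovResult(0.0, ks, y, int(j.size), degenerate=True)
        raise NumericalError("divergence curve too short to fit")
    slope = np.polyfit(ks[fit_mask] * dt, y[fit_mask], 1)[0]
    return LyapunovResult(float(slope), ks, y, int(j.size))


def _nearest_from_matrix(dists: np.ndarray, w: int) -> np.ndarray:
    """Nearest-neighbor indices from a precomputed square distance matrix."""
    n = dists.shape[0]
    idx = np.arange(n)
    d = dists.copy()
    d[np.abs(idx[None, :] - idx[:, None]) <= w] = np.inf
    best = np.argmin(d, axis=1)
    ok = np.isfinite(d[idx, best])
    out = np.where(ok, best, -1)
    return out


def _nearest_with_exclusion(pts: np.ndarray, w: int,
                            chunk: int = 512) -> np.ndarray:
    """Nearest neighbor index per point with |i-j| <= w excluded (-1 if none).

    Exact search via chunked distance matrices; ties break to the smaller
    index (argmin convention), keeping results reproducible.
    """
    n = pts.shape[0]
    nn = np.full(n, -1, dtype=int)
    idx = np.arange(n)
    for a in range(0, n, chunk):
        b = min(a + chunk, n)
        d = cdist(pts[a:b], pts)
        mask = np.abs(idx[None, :] - idx[a:b, None]) <= w
        d[mask] = np.inf
        best = np.argmin(d, axis=1)
        ok = np.isfinite(d[np.arange(b - a), best])
        nn[a:b][ok] = best[ok]
    return nn


@dataclass
class CorrDimResult:
    d: float
    r: np.ndarray
    c: np.ndarray
    region: tuple
    degenerate: bool = False


def correlation_dimension(cloud: StateSpaceCloud,
                          r_grid: np.ndarray | None = None,
                          theiler_s: float = 0.0,
                          n_r: int = 24,
                          min_region: int = 5,
                          slope_tol: float = 0.2,
                          dists: np.ndarray | None = None) -> CorrDimResult:
    """Grassberger–Procaccia correlation dimension.

    The correlation sum C(r) counts pairs with temporal separation beyond
    the Theiler window; radii default to 24 log-spaced values between the
    1st and 50th percentiles of the pair distances.  The dimension is the
    OLS slope of log C vs log r over the longest run of at least
    ``min_region`` consecutive local slopes whose spread stays within
    ``slope_tol``; no such run is an error carrying the diagnostic curve.
    The attractor dimension cannot exceed the embedding dimension m, but
    the estimated slope is reported as measured (it can fluctuate slightly
    above m on noise-dominated windows); hard-clipping it would pile an
    artificial atom of probability at exactly m.
    """
    pts = cloud.points
    n = pts.shape[0]
    if n < 50:
        raise DataError("too few points for a dimension estimate")
    w = int(round(theiler_s / cloud.dt))
    if dists is not None:
        iu = np.triu_indices(n, w + 1)
        dists = dists[iu]
    else:
        dists = _pair_distances(pts, w)
    if dists.size == 0:
        raise NumericalError("no pairs beyond the Theiler window")
    if np.all(dists == 0):
        return CorrDimResult(0.0, np.empty(0), np.empty(0), (0, 0),
                             degenerate=True)
    if r_grid is None:
        pos = dists[dists > 0]
        r_lo, r_hi = np.percentile(pos, [1, 50])
        if r_lo <= 0:
            r_lo = pos.min()
        if r_hi <= r_lo:
            r_hi = pos.max()
        r_grid = np.geomspace(r_lo, r_hi, n_r)
    hist, _ = np.histogram(dists, bins=np.concatenate(([0.0], r_grid)))
    c = np.cumsum(hist) / dists.size
    keep = c > 0
    r_grid, c = r_grid[keep], c[keep]
    if r_grid.size < min_region + 1:
        raise NumericalError("too few populated radii for a scaling region")
    lr, lc = np.log(r_grid), np.log(c)
    slopes = np.diff(lc) / np.diff(lr)
    a, b = _longest_constant_run(slopes, min_region, slope_tol)
    if a is None:
        raise NumericalError(
            f"no scaling region of locally constant slope; slopes="
            f"{np.round(slopes, 3).tolist()}")
    d = float(np.polyfit(lr[a:b + 2], lc[a:b + 2], 1)[0])
    return CorrDimResult(max(d, 0.0), r_grid, c, (a, b + 1))


def _pair_distances(pts: np.ndarray, w: int, chunk: int = 1024) -> np.ndarray:
    n = pts.shape[0]
    out = []
    for a in range(0, n, chunk):
        b = min(a + chunk, n)
        d = cdist(pts[a:b], pts)
        rows = np.arange(a, b)[:, None]
        cols = np.arange(n)[None, :]
        keep = cols - rows > w
        out.append(d[keep])
    return np.concatenate(out) if out else np.empty(0)


def _longest_constant_run(slopes: np.ndarray, min_len: int, tol: float):
    best = (None, None)
    best_len = 0
    best_spread = np.inf
    n = slopes.size
    for a in range(n):
        for b in range(a + min_len - 1, n):
            seg = slopes[a:b + 1]
            spread = seg.max() - seg.min()
            if spread <= tol:
                if (b - a > best_len) or (b - a == best_len and spread < best_spread):
                    best, best_len, best_spread = (a, b), b - a, spread
            else:
                break
    return best


# ------------------------------------------------------------- windows

def sliding_features(record: DepthRecord, params: EmbeddingParams,
                     window_s: float = 1800.0, step_s: float = 600.0,
                     estimators=("L", "Ek", "lyap", "dim", "period"),
                     period_range=(60.0, 3600.0),
                     fallback_period_s: float = FALLBACK_PERIOD_S,
                     theiler_cap_frac: float = 0.25,
                     gap_flag_frac: float = 0.10) -> pd.DataFrame:
    """Per-window invariants table.

    For every window the raw samples are embedded with the global ``tau``
    and ``m`` and the invariants are computed on that window's cloud.
    Within a window both the Theiler exclusion and the divergence-fit
    horizon are capped at ``theiler_cap_frac`` of the window (a 17-min
    separation inside a 30-min window would leave no admissible pairs).

    Estimators that fail on a window contribute NaN plus a flag naming the
    failure — never a fabricated value.  Windows with more than
    ``gap_flag_frac`` gap-filled samples are flagged ``gapfill``.
    """
    dt = record.dt
    w = int(round(window_s / dt))
    s = int(round(step_s / dt))
    if record.n < w:
        raise DataError("record shorter than one window")
    n_win = (record.n - w) // s + 1
    starts = np.arange(n_win) * s

    want = set(estimators)
    periods = np.full(n_win, np.nan)
    if "period" in want:
        periods = sliding_dominant_period(record, window_s, step_s,
                                          period_range=period_range)

    cap_s = theiler_cap_frac * window_s
    cols = {k: np.full(n_win, np.nan) for k in
            ("L_med", "L_mean", "Ek_med", "Ek_mean", "lyap", "dim")}
    flags = [""] * n_win
    times = record.t0 + pd.to_timedelta(starts * dt, unit="s")
    mids = record.t0 + pd.to_timedelta(starts * dt + window_s / 2.0, unit="s")

    for i, a in enumerate(starts):
        fl = []
        seg = record.depth[a: a + w]
        if record.filled is not None:
            if record.filled[a: a + w].mean() > gap_flag_frac:
                fl.append("gapfill")
        try:
            cloud = delay_embed(seg, params)
        except DataError:
            flags[i] = ";".join(fl + ["too_short"])
            continue
        if "L" in want:
            L = euclidean_distance(cloud)
            cols["L_med"][i] = np.median(L)
            cols["L_mean"][i] = L.mean()
        if "Ek" in want:
            _, ek = kinetic_energy(cloud)
            cols["Ek_med"][i] = np.median(ek)
            cols["Ek_mean"][i] = ek.mean()
        per = periods[i] if np.isfinite(periods[i]) else fallback_period_s
        eff = min(per, cap_s)
        D = None
        if {"lyap", "dim"} & want:
            D = cdist(cloud.points, cloud.points)
        if "lyap" in want:
            try:
                res = max_lyapunov(cloud, mean_period_s=per,
                                   theiler_s=eff,
                                   fit_range=max(3, int(eff / dt)),
                                   dists=D)
                cols["lyap"][i] = res.lam
            except (DataError, NumericalError):
                fl.append("lyap_failed")
        if "dim" in want:
            try:
                res = correlation_dimension(cloud, theiler_s=eff, dists=D)
                cols["dim"][i] = res.d
            except (DataError, NumericalError):
                fl.append("dim_failed")
        flags[i] = ";".join(fl)

    df = pd.DataFrame({"window_start": times, "window_mid": mids, **cols,
                       "period_s": periods, "flags": flags})
    return df
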