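"""State-space reconstruction by time-delay embedding.

A scalar observable x(t) sampled at interval ``dt`` is unfolded into
m-dimensional points

    y(i) = [x(i), x(i + tau), ..., x(i + (m-1) tau)],

which, for a deterministic system observed through one coordinate, is
diffeomorphic to the underlying attractor for suitable delay ``tau`` and
embedding dimension ``m``.  The delay is chosen at the first local minimum
of the auto-mutual-information curve (with the first zero crossing of the
autocorrelation as cross-check and fallback); the dimension is chosen where
the fraction of false nearest neighbors becomes negligible (Kennel
distance-ratio criterion).

For long, non-stationary biologging records the selection curves are
computed on non-overlapping 6-h segments and summarized by their pointwise
median, which keeps a few anomalous hours from dominating the choice.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree
from statsmodels.tsa.stattools import acf as _sm_acf

from .errors import ConfigError, DataError, NumericalError
from .io_depth import DepthRecord


@dataclass
class EmbeddingParams:
    """Delay ``tau_s`` (seconds) and embedding dimension ``m``."""

    tau_s: float
    m: int
    dt: float = 1.0

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ConfigError("embedding dimension m must be >= 1")
        if self.tau_s < self.dt:
            raise ConfigError("tau must be at least one sample")

    @property
    def tau_samples(self) -> int:
        return int(round(self.tau_s / self.dt))


@dataclass
class StateSpaceCloud:
    """Embedded points with the time index of their first coordinate."""

    points: np.ndarray          # (N, m)
    time_index: np.ndarray      # (N,) sample index of x(i)
    params: EmbeddingParams

    @property
    def n(self) -> int:
        return self.points.shape[0]

    @property
    def m(self) -> int:
        return self.points.shape[1]

    @property
    def dt(self) -> float:
        return self.params.dt


@dataclass
class DelaySelection:
    """Median AMI and ACF curves plus the chosen delay."""

    lags_s: np.ndarray
    ami: np.ndarray
    acf: np.ndarray | None = None
    ami_spread: np.ndarray | None = None
    n_segments: int = 1
    n_skipped: int = 0


@dataclass
class SelectedDelay:
    tau_s: float
    method: str                 # "ami_min" or "acf_zero" (fallback)
    acf_zero_s: float | None
    ami_peak_s: float | None = None


@dataclass
class FNNProfile:
    m_values: np.ndarray
    fnn_fraction: np.ndarray
    r_t: float
    strided: int = 1


# ------------------------------------------------------------------ embed

def delay_embed(data, params: EmbeddingParams) -> StateSpaceCloud:
    """Exact coordinate construction; no interpolation.

    ``data`` may be a :class:`DepthRecord` or a plain 1-D array (then
    ``params.dt`` defines the sampling).
    """
    if isinstance(data, DepthRecord):
        x = data.depth
        if abs(data.dt - params.dt) > 1e-12:
            params = EmbeddingParams(params.tau_s, params.m, data.dt)
    else:
        x = np.asarray(data, dtype=float)
    tau = params.tau_samples
    m = params.m
    span = (m - 1) * tau
    n_pts = x.size - span
    if n_pts < 1:
        raise DataError(
            f"series of length {x.size} too short for m={m}, tau={tau} samples; "
            f"need at least {span + 1}")
    cols = [x[j * tau: j * tau + n_pts] for j in range(m)]
    return StateSpaceCloud(points=np.column_stack(cols),
                           time_index=np.arange(n_pts), params=params)


# ------------------------------------------------------------------ curves

def lag_grid(max_lag_s: float, dt: float = 1.0, fine_until_s: float = 600.0,
             coarse_step_s: float = 5.0) -> np.ndarray:
    """Lag grid in samples: every sample up to 600 s, then 5-s steps."""
    fine_n = int(min(max_lag_s, fine_until_s) / dt)
    lags = list(range(0, fine_n + 1))
    step = max(1, int(round(coarse_step_s / dt)))
    lags += list(range(fine_n + step, int(max_lag_s / dt) + 1, step))
    return np.unique(np.asarray(lags, dtype=int))


def auto_mutual_information(series, max_lag_s: float, n_bins: int = 32,
                            dt: float = 1.0,
                            lags: np.ndarray | None = None,
                            bin_range: tuple | None = None
                            ) -> tuple[np.ndarray, np.ndarray]:
    """Histogram-based mutual information I(x(t); x(t+lag)) in nats.

    Equal-width bins over the observed range (or an explicit ``bin_range``,
    used to keep a common amplitude reference when comparing curves across
    segments); returns ``(lags_s, I)``.  A constant series yields an
    all-zero curve with a warning.
    """
    x = np.asarray(series, dtype=float)
    if lags is None:
        lags = lag_grid(max_lag_s, dt)
    lags = np.asarray(lags, dtype=int)
    if x.size <= lags.max():
        raise DataError("series shorter than the requested maximum lag")
    lo, hi = bin_range if bin_range is not None else (x.min(), x.max())
    if hi - lo <= 0:
        warnings.warn("constant series: mutual information is identically zero")
        return lags * dt, np.zeros(lags.size)
    codes = np.minimum((n_bins * (x - lo) / (hi - lo)).astype(np.int64),
                       n_bins - 1)
    out = np.empty(lags.size)
    for k, lag in enumerate(lags):
        a = codes[: x.size - lag] if lag else codes
        b = codes[lag:] if lag else codes
        joint = np.bincount(a * n_bins + b, minlength=n_bins * n_bins).astype(float)
        joint /= joint.sum()
        px = joint.reshape(n_bins, n_bins).sum(axis=1)
        py = joint.reshape(n_bins, n_bins).sum(axis=0)
        nz = joint > 0
        ij = np.flatnonzero(nz)
        out[k] = float(np.sum(joint[nz] * (np.log(joint[nz])
                                           - np.log(px[ij // n_bins])
                                           - np.log(py[ij % n_bins]))))
    return lags * dt, np.maximum(out, 0.0)


def autocorrelation(series, max_lag_s: float, dt: float = 1.0
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Biased sample autocorrelation with R(0) = 1."""
    x = np.asarray(series, dtype=float)
    if np.ptp(x) == 0:
        raise DataError("autocorrelation undefined for a constant series")
    nlags = int(max_lag_s / dt)
    if x.size <= nlags:
        raise DataError("series shorter than the requested maximum lag")
    r = _sm_acf(x, nlags=nlags, fft=True)
    return np.arange(nlags + 1) * dt, r


def segment_median_curve(record: DepthRecord, curve: str,
                         segment_s: float = 6 * 3600.0,
                         max_lag_s: float = 1800.0,
                         n_bins: int = 32) -> DelaySelection:
    """Pointwise median of per-6-h-segment AMI or ACF curves.

    Degenerate (zero-variance) segments are skipped and counted.  Fewer
    than two valid segments is an error.
    """
    if curve not in ("ami", "acf"):
        raise ConfigError("curve must be 'ami' or 'acf'")
    seg_n = int(segment_s / record.dt)
    n_seg = record.n // seg_n
    if n_seg < 2:
        raise DataError("record shorter than two segments")
    lags = lag_grid(max_lag_s, record.dt)
    bin_range = (float(record.depth.min()), float(record.depth.max()))
    rows = []
    skipped = 0
    for i in range(n_seg):
        seg = record.depth[i * seg_n: (i + 1) * seg_n]
        if np.ptp(seg) == 0:
            skipped += 1
            continue
        if curve == "ami":
            _, y = auto_mutual_information(seg, max_lag_s, n_bins=n_bins,
                                           dt=record.dt, lags=lags,
                                           bin_range=bin_range)
        else:
            _, r = autocorrelation(seg, max_lag_s, dt=record.dt)
            y = r[lags]
        rows.append(y)
    if len(rows) < 2:
        raise DataError("fewer than 2 valid (non-degenerate) segments")
    arr = np.vstack(rows)
    med = np.median(arr, axis=0)
    spread = np.subtract(*np.percentile(arr, [75, 25], axis=0))
    sel = DelaySelection(lags_s=lags * record.dt,
                         ami=med if curve == "ami" else np.empty(0),
                         acf=med if curve == "acf" else None,
                         ami_spread=spread if curve == "ami" else None,
                         n_segments=len(rows), n_skipped=skipped)
    return sel


def _smooth3(y: np.ndarray) -> np.ndarray:
    if y.size < 3:
        return y
    out = y.copy()
    out[1:-1] = (y[:-2] + y[1:-1] + y[2:]) / 3.0
    return out


def select_delay(selection: DelaySelection, smooth: bool = True,
                 min_window_s: float = 30.0) -> SelectedDelay:
    """Delay at the first local minimum of the (smoothed) median AMI curve.

    A local minimum must be the strict minimum of its +-``min_window_s``
    neighborhood (at least the immediate neighbors), which keeps
    sample-level jitter on a slowly decaying curve from producing spurious
    early minima.  Falls back, flagged, to the first negative lag of the
    median ACF when the AMI curve has no interior local minimum.  Also
    records the lag of the global AMI maximum over positive lags (a
    dominant-period proxy).
    """
    lags = selection.lags_s
    ami = selection.ami
    if ami is None or ami.size == 0:
        raise ConfigError("median AMI curve required")
    y = _smooth3(ami) if smooth else ami
    spacing = np.median(np.diff(lags)) if lags.size > 1 else 1.0
    order = max(1, int(round(min_window_s / spacing)))
    tau = None
    for i in range(1, y.size - 1):
        if lags[i] <= 0:
            continue
        a, b = max(0, i - order), min(y.size, i + order + 1)
        neigh = np.r_[y[a:i], y[i + 1:b]]
        if neigh.size and y[i] < neigh.min():
            # sub-grid refinement: the valley of a smooth AMI curve is
            # locally quadratic, so fit a parabola through a window of
            # twice the detection neighborhood and take its vertex
            # (estimator jitter otherwise limits the argmin to the grid)
            a2 = max(0, i - 2 * order)
            b2 = min(y.size, i + 2 * order + 1)
            if b2 - a2 >= 5:
                coef = np.polyfit(lags[a2:b2], y[a2:b2], 2)
                if coef[0] > 0:
                    vertex = -coef[1] / (2 * coef[0])
                    if lags[a2] <= vertex <= lags[b2 - 1]:
                        tau = float(vertex)
                        break
            tau = float(lags[i])
            break
    acf_zero = None
    if selection.acf is not None:
        neg = np.flatnonzero((selection.acf < 0) & (lags > 0))
        if neg.size:
            acf_zero = float(lags[neg[0]])
    # dominant-cycle proxy: the AMI maximum *beyond* the first minimum
    # (the curve always decays from lag 0, so the raw global maximum over
    # positive lags would trivially sit at the first lag)
    past = lags > (tau if tau is not None else 0)
    ami_peak = float(lags[past][np.argmax(ami[past])]) if past.any() else None
    if tau is not None:
        return SelectedDelay(tau, "ami_min", acf_zero, ami_peak)
    if acf_zero is not None:
        return SelectedDelay(acf_zero, "acf_zero", acf_zero, ami_peak)
    raise NumericalError("no AMI local minimum and no ACF zero crossing "
                         "within the lag range")


# ------------------------------------------------------------------ FNN

def _nn_excluding_theiler(pts: np.ndarray, theiler: int
                          ) -> tuple[np.ndarray, np.ndarray]:
    """Exact nearest neighbor of each point, excluding |i-j| <= theiler.

    Ties are broken toward the smaller time index.  Points with no
    admissible neighbor get index -1.
    """
    n = pts.shape[0]
    if (2 * theiler + 2) * 8 > n:
        # exclusion zone comparable to the data span: a k-NN query would
        # have to return most of the data anyway, so scan distances directly
        return _nn_bruteforce(pts, theiler)
    tree = cKDTree(pts)
    nn_idx = np.full(n, -1, dtype=int)
    nn_dist = np.full(n, np.inf)
    unresolved = np.arange(n)
    k = min(32, n)
    while unresolved.size:
        # bound k * rows-per-chunk so the query result stays ~tens of MB
        chunk = max(1, int(5e6 // k))
        for a in range(0, unresolved.size, chunk):
            rows_idx = unresolved[a: a + chunk]
            d, j = tree.query(pts[rows_idx], k=k)
            if k == 1:
                d, j = d[:, None], j[:, None]
            valid = np.abs(j - rows_idx[:, None]) > theiler
            has = valid.any(axis=1)
            first = np.argmax(valid, axis=1)
            rr = np.flatnonzero(has)
            nn_idx[rows_idx[rr]] = j[rr, first[rr]]
            nn_dist[rows_idx[rr]] = d[rr, first[rr]]
        unresolved = unresolved[nn_idx[unresolved] < 0]
        if k >= n:
            break
        k = min(4 * k, n)
    # brute-force stragglers (k exhausted but neighbors masked)
    for i in unresolved:
        dd = np.linalg.norm(pts - pts[i], axis=1)
        dd[np.abs(np.arange(n) - i) <= theiler] = np.inf
        j = int(np.argmin(dd))
        if np.isfinite(dd[j]):
            nn_idx[i], nn_dist[i] = j, dd[j]
    return nn_idx, nn_dist


def _nn_bruteforce(pts: np.ndarray, theiler: int,
                   chunk: int = 1024) -> tuple[np.ndarray, np.ndarray]:
    from scipy.spatial.distance import cdist
    n = pts.shape[0]
    nn_idx = np.full(n, -1, dtype=int)
    nn_dist = np.full(n, np.inf)
    idx = np.arange(n)
    for a in range(0, n, chunk):
        b = min(a + chunk, n)
        d = cdist(pts[a:b], pts)
        d[np.abs(idx[None, :] - idx[a:b, None]) <= theiler] = np.inf
        best = np.argmin(d, axis=1)
        ok = np.isfinite(d[np.arange(b - a), best])
        nn_idx[a:b][ok] = best[ok]
        nn_dist[a:b][ok] = d[np.arange(b - a), best][ok]
    return nn_idx, nn_dist


def false_nearest_fraction(series, tau: int, m_range,
                           r_t: float = 3.0, theiler: int = 1,
                           max_points: int = 200_000) -> FNNProfile:
    """Fraction of false nearest neighbors per embedding dimension.

    Kennel's first (distance-ratio) criterion: the nearest neighbor pair
    (i, j) in dimension m is false when the extra-coordinate separation
    |x(i+m*tau) - x(j+m*tau)| exceeds ``r_t`` times their m-dimensional
    distance.  Temporally adjacent samples are excluded via the Theiler
    window.  Series longer than ``max_points`` (after embedding) are
    strided, recorded in the profile.
    """
    x = np.asarray(series, dtype=float)
    tau = int(tau)
    m_values = np.asarray(list(m_range), dtype=int)
    if tau < 1 or np.any(m_values < 1):
        raise ConfigError("tau and m must be positive")
    fracs = np.empty(m_values.size)
    for k, m in enumerate(m_values):
        n_pts = x.size - m * tau          # points that also exist in m+1 dims
        if n_pts < 10:
            raise DataError(f"series too short for FNN at m={m}, tau={tau}")
        stride = max(1, int(np.ceil(n_pts / max_points)))
        idx = np.arange(0, n_pts, stride)
        pts = np.column_stack([x[idx + j * tau] for j in range(m)])
        extra = x[idx + m * tau]
        th = max(1, int(np.ceil(theiler / stride)))
        nn, dist = _nn_excluding_theiler(pts, th)
        ok = nn >= 0
        if not ok.any():
            raise NumericalError("no admissible neighbor pairs after Theiler "
                                 "exclusion")
        diff = np.abs(extra[ok] - extra[nn[ok]])
        d = dist[ok]
        # pairs identical to machine precision (exactly recurrent orbits)
        # are true neighbors, not candidates for the ratio test
        eps = 1e-9 * max(np.ptp(x), 1.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(d > eps, diff / np.where(d > eps, d, 1.0),
                             np.where(diff > eps, np.inf, 0.0))
        fracs[k] = float(np.mean(ratio > r_t))
    return FNNProfile(m_values=m_values, fnn_fraction=fracs, r_t=r_t,
                      strided=stride)


def select_dimension(profile: FNNProfile, threshold: float = 0.01) -> int:
    """Smallest m whose FNN fraction falls below ``threshold``."""
    below = profile.fnn_fraction < threshold
    if not below.any():
        raise NumericalError(
            "FNN fraction never fell below threshold "
            f"{threshold}: {dict(zip(profile.m_values.tolist(), np.round(profile.fnn_fraction, 4).tolist()))}")
    return int(profile.m_values[np.argmax(below)])
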