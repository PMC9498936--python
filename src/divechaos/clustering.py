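"""Behavioral-state decoding by Gaussian mixtures over window invariants.

Windows described by (L_med, Ek_med, lyap, dim) are clustered with
Gaussian mixture models using diagonal covariances, either per-component
("diag") or shared across components ("diag-shared"), fit by EM with
seeded restarts.  The number of components is chosen where the AIC stops
improving appreciably, and soft posterior memberships provide a confidence
for every window.  Components are given semantic tags by ordering their
mean distance-from-origin: the farthest component is the deep-bout state,
then shallow bouts, with the nearest component tagged near-surface.

The four states of a diving record are separated by *ratios* — rest sits
two decades below a deep bout in kinetic energy and almost two in distance
from the origin — so the strictly positive invariants (L, E_k, and the
dimension when positive throughout) enter the mixture as logarithms by
default; signed features (the Lyapunov exponent) stay raw.  On raw scales
a diagonal-Gaussian mixture spends components on linearly distinct but
behaviorally meaningless material (transition windows midway between
orbits) while merging the ratio-separated near-surface states.  A raw
option (``scale="raw"``) and a z-score switch are available.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .errors import ConfigError, DataError, NumericalError

DEFAULT_FEATURES = ("L_med", "Ek_med", "lyap", "dim")
#: features modeled on log scale under scale="log" (when strictly positive)
DEFAULT_LOG_FEATURES = ("L_med", "Ek_med")
STRUCTURES = ("diag", "diag-shared")

#: semantic tags for k = 4, from the largest component-mean L downwards
TAGS_K4 = ("deep-bout", "shallow-bout", "intermediate", "near-surface-shallow")


@dataclass
class MixtureFit:
    k: int
    structure: str
    weights: np.ndarray            # (k,), sums to 1
    means: np.ndarray              # (k, d)
    variances: np.ndarray          # (k, d) or (d,) when shared
    loglik: float
    aic: float
    n_params: int
    loglik_trace: np.ndarray
    feature_names: tuple
    converged: bool
    n_iter: int
    zscore: tuple | None = None    # (mean, sd) when standardized
    log_cols: tuple = ()           # feature columns modeled on log scale


@dataclass
class Memberships:
    posterior: np.ndarray          # (n, k), rows sum to 1 (NaN when unassigned)
    labels: np.ndarray             # argmax, -1 for unassigned rows
    confidence: np.ndarray         # max posterior


def _n_params(k: int, d: int, structure: str) -> int:
    if structure == "diag":
        return (k - 1) + k * d + k * d
    if structure == "diag-shared":
        return (k - 1) + k * d + d
    raise ConfigError(f"unknown covariance structure {structure!r}")


def _log_gauss_diag(X, means, variances):
    # variances broadcastable to (k, d)
    var = np.atleast_2d(variances)
    if var.shape[0] == 1 and means.shape[0] > 1:
        var = np.broadcast_to(var, means.shape)
    out = np.empty((X.shape[0], means.shape[0]))
    for j in range(means.shape[0]):
        out[:, j] = -0.5 * np.sum(
            np.log(2 * np.pi * var[j]) + (X - means[j]) ** 2 / var[j], axis=1)
    return out


def _init_transform(X):
    """Per-column transform used only to seed the restarts.

    The window invariants are separated by scale ratios (a resting window
    sits two orders of magnitude below a deep bout in kinetic energy), so
    seeding distances are measured in log space for strictly positive
    columns and in standardized units otherwise.  The EM itself always
    runs on the raw features.
    """
    T = np.empty_like(X)
    for j in range(X.shape[1]):
        col = X[:, j]
        if col.min() > 0:
            T[:, j] = np.log(col)
        else:
            sd = col.std()
            T[:, j] = col / sd if sd > 0 else col
        sd = T[:, j].std()
        if sd > 0:
            T[:, j] = T[:, j] / sd
    return T


def _kmeanspp(X, k, rng, Xt=None):
    """k-means++ seeding; returns rows of X (seed distances on Xt)."""
    Xt = X if Xt is None else Xt
    n = X.shape[0]
    idx = [int(rng.integers(n))]
    for _ in range(1, k):
        d2 = np.min([np.sum((Xt - Xt[i]) ** 2, axis=1) for i in idx], axis=0)
        tot = d2.sum()
        idx.append(int(rng.choice(n, p=d2 / tot)) if tot > 0
                   else int(rng.integers(n)))
    return X[idx].copy()


def _em_once(X, k, structure, rng, tol, max_iter, var_floor, Xt=None):
    n, d = X.shape
    means = _kmeanspp(X, k, rng, Xt=Xt)
    base_var = X.var(axis=0) + var_floor
    variances = np.tile(base_var, (k, 1))
    weights = np.full(k, 1.0 / k)
    trace = []
    prev = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        log_p = _log_gauss_diag(X, means, variances) + np.log(weights)
        norm = logsumexp(log_p, axis=1)
        ll = float(norm.sum())
        trace.append(ll)
        resp = np.exp(log_p - norm[:, None])
        if ll - prev < tol * max(abs(ll), 1.0) and it > 1:
            converged = True
            break
        prev = ll
        nk = resp.sum(axis=0) + 1e-12
        weights = nk / n
        means = (resp.T @ X) / nk[:, None]
        var_k = np.empty((k, d))
        for j in range(k):
            diff = X - means[j]
            var_k[j] = (resp[:, j] @ (diff ** 2)) / nk[j]
        if structure == "diag-shared":
            shared = (nk[:, None] * var_k).sum(axis=0) / n
            variances = np.tile(np.maximum(shared, var_floor), (k, 1))
        else:
            variances = np.maximum(var_k, var_floor)
    return weights, means, variances, trace, converged, it


def _complete_rows(features: pd.DataFrame, feature_names) -> tuple[np.ndarray, np.ndarray]:
    X = features.loc[:, list(feature_names)].to_numpy(dtype=float)
    ok = np.isfinite(X).all(axis=1)
    return X, ok


def _apply_log(X, log_cols, feature_names):
    X = X.copy()
    for c in log_cols:
        j = list(feature_names).index(c)
        X[:, j] = np.log(np.maximum(X[:, j], 1e-12))
    return X


def fit_gmm(features: pd.DataFrame, k: int, structure: str = "diag",
            n_init: int = 20, seed: int = 0,
            feature_names=DEFAULT_FEATURES,
            tol: float = 1e-6, max_iter: int = 500,
            zscore: bool = False, var_floor_frac: float = 1e-5,
            scale: str = "log",
            log_features=DEFAULT_LOG_FEATURES) -> MixtureFit:
    """EM fit of a diagonal Gaussian mixture; best of ``n_init`` restarts.

    Deterministic for a fixed seed.  Convergence: relative log-likelihood
    change below ``tol`` (max 500 iterations).  Rows with missing features
    are dropped from the fit (they stay assignable as unassigned later).
    Component variances are floored at ``var_floor_frac`` of each
    feature's overall variance, which blocks EM degeneracies (a component
    collapsing onto a handful of identical values).
    """
    if structure not in STRUCTURES:
        raise ConfigError(f"structure must be one of {STRUCTURES}")
    if scale not in ("log", "raw"):
        raise ConfigError("scale must be 'log' or 'raw'")
    X, ok = _complete_rows(features, feature_names)
    X = X[ok]
    log_cols = ()
    if scale == "log":
        log_cols = tuple(
            c for j, c in enumerate(feature_names)
            if c in log_features and X[:, j].min() > 0)
        X = _apply_log(X, log_cols, feature_names)
    n, d = X.shape
    if k < 1:
        raise ConfigError("k must be >= 1")
    if k > n // 10:
        raise ConfigError(f"k={k} too large for {n} complete rows (max {n // 10})")
    z = None
    if zscore:
        mu, sd = X.mean(axis=0), X.std(axis=0)
        sd[sd == 0] = 1.0
        X = (X - mu) / sd
        z = (mu, sd)
    var_floor = var_floor_frac * X.var(axis=0) + 1e-12
    Xt = _init_transform(X)
    rng_master = np.random.default_rng(seed)
    best = None
    for _ in range(max(1, n_init)):
        rng = np.random.default_rng(rng_master.integers(2 ** 31))
        w, m, v, trace, conv, it = _em_once(X, k, structure, rng, tol,
                                            max_iter, var_floor, Xt=Xt)
        if best is None or trace[-1] > best[3][-1]:
            best = (w, m, v, trace, conv, it)
    w, m, v, trace, conv, it = best
    if not conv and k > 1:
        # all restarts hit max_iter without meeting the tolerance
        raise NumericalError("EM failed to converge in all restarts")
    p = _n_params(k, d, structure)
    ll = trace[-1]
    fit = MixtureFit(
        k=k, structure=structure, weights=w, means=m,
        variances=v[0] if structure == "diag-shared" else v,
        loglik=ll, aic=2 * p - 2 * ll, n_params=p,
        loglik_trace=np.asarray(trace), feature_names=tuple(feature_names),
        converged=conv, n_iter=it, zscore=z, log_cols=log_cols)
    return fit


@dataclass
class ScanResult:
    table: pd.DataFrame
    k: int
    structure: str
    fit: MixtureFit
    epsilon: float


def model_scan(features: pd.DataFrame, k_range=range(1, 7),
               structures=STRUCTURES, epsilon: float = 0.08,
               n_init: int = 20, seed: int = 0,
               feature_names=DEFAULT_FEATURES, **fit_kw) -> ScanResult:
    """AIC over every (k, structure); pick where improvement levels off.

    "No obvious improvement" is operationalized scale-invariantly: per
    structure, components are added while each step still improves the AIC
    by at least ``epsilon`` of the total AIC drop across the scan.  (A
    threshold relative to |AIC| itself would depend on the measurement
    units of the features, since rescaling a feature shifts the
    log-likelihood by a constant per observation.)  The structure with the
    lower AIC at its selected k wins.  Failed cells propagate as NaN and
    the scan continues.
    """
    ks = list(k_range)
    rows = []
    fits: dict[tuple, MixtureFit] = {}
    for st in structures:
        for k in ks:
            try:
                f = fit_gmm(features, k, structure=st, n_init=n_init,
                            seed=seed, feature_names=feature_names, **fit_kw)
                fits[(st, k)] = f
                rows.append({"structure": st, "k": k, "aic": f.aic,
                             "loglik": f.loglik, "error": ""})
            except (ConfigError, DataError, NumericalError) as e:
                rows.append({"structure": st, "k": k, "aic": np.nan,
                             "loglik": np.nan, "error": str(e)})
    table = pd.DataFrame(rows)
    chosen: dict[str, tuple[int, float]] = {}
    for st in structures:
        sub = table[(table.structure == st) & np.isfinite(table.aic)]
        if sub.empty:
            continue
        aics = dict(zip(sub.k, sub.aic))
        total_drop = aics[min(aics)] - min(aics.values())
        d = len(feature_names)
        sel = min(aics)
        for k in sorted(aics):
            if k - 1 not in aics:
                continue
            improvement = aics[k - 1] - aics[k]
            # a step must matter relative to the whole scan AND clearly
            # beat the parameter cost of the added component (an AIC gain
            # of the order of the added parameters is indistinguishable
            # from overfitting noise)
            dp = _n_params(k, d, st) - _n_params(k - 1, d, st)
            if improvement < epsilon * max(total_drop, 1e-12) \
                    or improvement < 2 * dp:
                break
            sel = k
        chosen[st] = (sel, aics[sel])
    if not chosen:
        raise NumericalError("every (k, structure) cell failed")
    st_best = min(chosen, key=lambda s: chosen[s][1])
    k_best = chosen[st_best][0]
    return ScanResult(table=table, k=k_best, structure=st_best,
                      fit=fits[(st_best, k_best)], epsilon=epsilon)


def assign(fit: MixtureFit, features: pd.DataFrame) -> Memberships:
    """Posterior responsibilities; ties in the hard label go to the lower index.

    Rows with missing feature values are flagged unassigned (label -1,
    NaN posteriors).
    """
    X, ok = _complete_rows(features, fit.feature_names)
    n = X.shape[0]
    post = np.full((n, fit.k), np.nan)
    labels = np.full(n, -1, dtype=int)
    conf = np.full(n, np.nan)
    if ok.any():
        Xo = _apply_log(X[ok], fit.log_cols, fit.feature_names)
        if fit.zscore is not None:
            Xo = (Xo - fit.zscore[0]) / fit.zscore[1]
        log_p = _log_gauss_diag(Xo, fit.means, fit.variances) + np.log(fit.weights)
        log_post = log_p - logsumexp(log_p, axis=1)[:, None]
        p = np.exp(log_post)
        post[ok] = p
        labels[ok] = np.argmax(p, axis=1)
        conf[ok] = p.max(axis=1)
    return Memberships(posterior=post, labels=labels, confidence=conf)


def semantic_labels(fit: MixtureFit, features: pd.DataFrame,
                    memberships: Memberships | None = None,
                    l_feature: str = "L_med",
                    tie_tol: float = 1e-9) -> tuple[pd.DataFrame, dict]:
    """Windows labeled with semantic behavioral tags.

    Components are ordered by their mean distance-from-origin feature
    (descending).  For k = 4 the tags are deep-bout, shallow-bout,
    intermediate, near-surface-shallow; for other k, ``cluster-1..k`` in
    the same order.  Near-ties in mean L fall back, flagged, to ordering
    by mean kinetic energy.
    """
    if memberships is None:
        memberships = assign(fit, features)
    names = list(fit.feature_names)
    if l_feature not in names:
        raise ConfigError(f"{l_feature!r} not among fit features {names}")
    li = names.index(l_feature)
    # component means live on the fit's (possibly log) scale; both the log
    # and the z-score maps are monotone, so the ordering is unaffected
    key = fit.means[:, li]
    if fit.zscore is not None:
        key = key * fit.zscore[1][li] + fit.zscore[0][li]
    fallback = False
    if np.any(np.abs(np.subtract.outer(key, key))[~np.eye(fit.k, dtype=bool)] <= tie_tol):
        fallback = True
        ei = names.index("Ek_med") if "Ek_med" in names else li
        key = key + 1e-6 * fit.means[:, ei]
    order = np.argsort(-key, kind="stable")
    if fit.k == 4:
        tags = list(TAGS_K4)
    else:
        tags = [f"cluster-{i + 1}" for i in range(fit.k)]
    tag_of = {int(comp): tags[rank] for rank, comp in enumerate(order)}
    lab = pd.DataFrame({
        "window_start": features["window_start"].to_numpy()
        if "window_start" in features else np.arange(len(features)),
        "cluster": memberships.labels,
        "confidence": memberships.confidence,
        "tag": [tag_of.get(int(c)) if c >= 0 else None
                for c in memberships.labels],
    })
    if "window_mid" in features:
        lab.insert(1, "window_mid", features["window_mid"].to_numpy())
    info = {"tag_of_component": tag_of, "tie_fallback": fallback}
    return lab, info


def serialize_fit(fit: MixtureFit) -> dict:
    """JSON-ready mixture parameters for reuse."""
    return {
        "k": fit.k, "structure": fit.structure,
        "weights": fit.weights.tolist(), "means": fit.means.tolist(),
        "variances": np.asarray(fit.variances).tolist(),
        "loglik": fit.loglik, "aic": fit.aic, "n_params": fit.n_params,
        "feature_names": list(fit.feature_names),
        "log_cols": list(fit.log_cols),
    }
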