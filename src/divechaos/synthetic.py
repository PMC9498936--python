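"""Synthetic dive records with known behavioral ground truth.

The generator emulates the statistical structure the downstream analysis
assumes for a deep-diving odontocete depth record sampled at 1 Hz:

* a semi-Markov sequence over four behavioral states — prolonged
  near-surface rest (``R``), shallow dive bouts (``B_s``), deep dive bouts
  (``B_d``) and intermediate near-surface activity (``I``);
* within a bout, repeated quasi-periodic dive cycles (descent at bounded
  vertical speed, bottom phase with foraging wiggles, ascent, brief surface
  pause), with the deep-bout cycle near 17 min and the shallow-bout cycle
  near 8.5 min;
* diurnal modulation of the transition weights (more rest around the early
  afternoon solar culmination, shallow bouts favored at night);
* bounded vertical speeds (|dD/dt| essentially below ``max_speed``) and
  small Gaussian observation noise.

Ground truth is returned as a :class:`StateTrace` so that state decoding can
be scored against known labels.  All randomness flows through one explicit
``numpy.random.Generator``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .errors import ConfigError, DataError
from .io_depth import DepthRecord

STATES = ("R", "B_s", "B_d", "I")

#: local hour of the diurnal peak of the rest-favoring modulation; matches a
#: summer solar culmination shortly after 13:00 at high northern latitude.
NOON_HOUR = 13.5


def _default_transitions() -> dict:
    return {
        "R": {"B_d": 0.45, "B_s": 0.35, "I": 0.20},
        "B_d": {"R": 0.35, "B_s": 0.35, "I": 0.30},
        "B_s": {"B_d": 0.40, "R": 0.25, "I": 0.35},
        "I": {"R": 0.35, "B_d": 0.35, "B_s": 0.30},
    }


@dataclass
class SimConfig:
    """Study conditions for the simulator.

    Depth laws per state are (low, high) bounds in metres for the per-bout
    target depth (bouts) or the per-episode wander level (R/I).  Dive
    periods are the within-bout cycle lengths in seconds.  Durations are
    exponential with a floor: ``dur = min + Exp(mean - min)``.
    """

    states: tuple = STATES
    mean_duration: dict = field(default_factory=lambda: {
        "R": 10800.0, "B_s": 7200.0, "B_d": 12600.0, "I": 4500.0})
    min_duration: dict = field(default_factory=lambda: {
        "R": 1800.0, "B_s": 1530.0, "B_d": 3060.0, "I": 900.0})
    dive_period: dict = field(default_factory=lambda: {"B_d": 1020.0, "B_s": 510.0})
    depth_law: dict = field(default_factory=lambda: {
        "B_d": (250.0, 600.0), "B_s": (30.0, 100.0),
        "R": (1.0, 6.0), "I": (15.0, 30.0)})
    depth_drift: dict = field(default_factory=lambda: {"B_d": 0.0, "B_s": 0.0})
    transition_weights: dict = field(default_factory=_default_transitions)
    max_speed: float = 2.0
    diurnal_modulation: float = 0.3
    #: amplitude of the night-time shift toward shallow bouts; None means
    #: half the rest-favoring amplitude
    diurnal_shallow_modulation: float | None = None
    noise_sd: float = 0.04
    depth_cap: float = 900.0
    dt: float = 1.0
    t0: str = "2013-08-15T00:00:00"

    def __post_init__(self) -> None:
        for s in self.states:
            if s not in STATES:
                raise ConfigError(f"unknown state {s!r}")
            if self.mean_duration[s] <= 0 or self.min_duration[s] < 0:
                raise ConfigError("durations must be positive")
            lo, hi = self.depth_law[s]
            if lo < 0 or hi <= 0 or hi < lo:
                raise ConfigError(f"invalid depth law for {s}")
        if self.max_speed <= 0 or self.noise_sd < 0:
            raise ConfigError("max_speed must be > 0 and noise_sd >= 0")


@dataclass
class StateTrace:
    """Per-sample ground-truth labels plus per-episode metadata."""

    states: np.ndarray              # dtype '<U3', aligned with the depth record
    episodes: list                  # dicts: state, start_idx, n, target_depth, period

    @property
    def n(self) -> int:
        return self.states.size

    def fractions(self) -> dict:
        vals, counts = np.unique(self.states, return_counts=True)
        return {v: c / self.states.size for v, c in zip(vals, counts)}


# ---------------------------------------------------------------- segments

def _dive_cycle(depth: float, period: float, v_max: float, dt: float,
                wiggle_period: float = 90.0) -> np.ndarray:
    """One trapezoidal dive cycle with cosine-smoothed corners.

    Surface pause, descent at <= 0.9*v_max, bottom phase with a tapered
    sinusoidal foraging wiggle, ascent, surface pause; starts and ends at 0.
    """
    n = int(round(period / dt))
    ramp = 30.0
    # constant descent/ascent *time* (~35% of the cycle each): shallower
    # dives are slower, so every cycle has the same speed composition
    t_desc = 0.35 * period
    v_d = depth / (t_desc - ramp)
    if v_d > 0.9 * v_max:
        v_d = 0.9 * v_max
        t_desc = depth / v_d + ramp
        if 2 * t_desc > 0.8 * period:
            raise ConfigError(
                f"target depth {depth:.0f} m unreachable within a {period:.0f} s "
                f"cycle at max_speed {v_max} m/s")
    td = max(3, int(round(t_desc / dt)))
    remaining = n - 2 * td
    surf = max(15, remaining // 2)
    bot = remaining - surf
    if bot < 10:
        bot = max(0, remaining - 15)
        surf = remaining - bot

    rr = max(1, min(int(ramp / dt), td // 3))
    prof = np.ones(td)
    up = 0.5 * (1 - np.cos(np.pi * (np.arange(rr) + 0.5) / rr))
    prof[:rr] = up
    prof[-rr:] = up[::-1]
    prof *= depth / prof.sum()
    desc = np.cumsum(prof)
    asc = depth - np.cumsum(prof)

    t_b = np.arange(bot) * dt
    amp = min(0.06 * depth, 10.0)
    if bot > 0:
        env = np.sin(np.pi * (t_b + 0.5 * dt) / (bot * dt))
        bottom = depth + amp * np.sin(2 * np.pi * t_b / wiggle_period) * env
    else:
        bottom = np.empty(0)

    s1 = surf // 2
    s2 = surf - s1
    return np.concatenate([np.zeros(s1), desc, bottom, asc, np.zeros(s2)])


def _wander(level: float, spread: float, speed_sd: float, n: int, dt: float,
            rng: np.random.Generator, osc_amp: float = 0.8,
            osc_period: float = 90.0) -> np.ndarray:
    """Near-surface wander: slow OU drift plus a respiration oscillation.

    Resting and intermediate activity are not static: the animal surfaces
    to breathe on a roughly minute-scale cycle, which puts a small regular
    vertical oscillation on top of the slow drift.
    """
    theta = dt / 600.0
    eps = rng.standard_normal(n) * speed_sd * dt
    # x_k = (1 - theta) x_{k-1} + theta*level + eps  (AR(1) toward the level)
    drive = eps + theta * level
    x, _ = lfilter([1.0], [1.0, -(1.0 - theta)], drive,
                   zi=[level * (1.0 - theta)])
    phase = rng.uniform(0, 2 * np.pi)
    x = x + osc_amp * np.sin(2 * np.pi * np.arange(n) * dt / osc_period + phase)
    lo, hi = max(0.0, level - 3 * spread), level + 3 * spread
    return np.clip(x, lo, hi)


def _ramp(a: float, b: float, v_max: float, dt: float) -> np.ndarray:
    """Cosine ramp between depths a and b at peak speed <= 0.8*v_max."""
    delta = b - a
    if abs(delta) < 0.5:
        return np.empty(0)
    dur = max(10.0, np.pi * abs(delta) / (2 * 0.8 * v_max))
    k = int(np.ceil(dur / dt))
    u = (np.arange(1, k + 1)) / k
    return a + delta * 0.5 * (1 - np.cos(np.pi * u))


# ---------------------------------------------------------------- transitions

def _modulated_weights(config: SimConfig, current: str, hour: float) -> dict:
    """Transition weights out of ``current`` at local ``hour`` (0-24)."""
    base = config.transition_weights.get(current, {})
    allowed = [s for s in config.states if s != current]
    a_r = config.diurnal_modulation
    a_bs = (0.5 * a_r if config.diurnal_shallow_modulation is None
            else config.diurnal_shallow_modulation)
    phase = np.cos(2 * np.pi * (hour - NOON_HOUR) / 24.0)
    out = {}
    for s in allowed:
        w = float(base.get(s, 0.0))
        if s == "R":
            w *= max(0.0, 1.0 + a_r * phase)
        elif s == "B_s":
            w *= max(0.0, 1.0 - a_bs * phase)
        out[s] = w
    return out


def _draw_next_state(config: SimConfig, current: str, hour: float,
                     rng: np.random.Generator) -> str:
    if len(config.states) == 1:
        return current
    w = _modulated_weights(config, current, hour)
    total = sum(w.values())
    if total <= 0:
        raise ConfigError(f"unreachable state configuration out of {current!r}")
    names = list(w)
    p = np.array([w[s] for s in names]) / total
    return names[rng.choice(len(names), p=p)]


def _duration(config: SimConfig, state: str, rng: np.random.Generator) -> float:
    mn = config.min_duration[state]
    mean = config.mean_duration[state]
    extra = max(mean - mn, 0.0)
    return mn + (rng.exponential(extra) if extra > 0 else 0.0)


def stationary_fractions(config: SimConfig) -> dict:
    """Expected time-budget per state under the configured grammar.

    Quasi-static in the diurnal forcing: for each hour the embedded-chain
    stationary distribution is weighted by mean episode durations, then
    averaged over 24 h.  Exact when ``diurnal_modulation == 0``.
    """
    states = list(config.states)
    if len(states) == 1:
        return {states[0]: 1.0}
    acc = np.zeros(len(states))
    for h in np.arange(0.5, 24.0, 1.0):
        P = np.zeros((len(states), len(states)))
        for i, s in enumerate(states):
            w = _modulated_weights(config, s, h)
            total = sum(w.values())
            if total <= 0:
                raise ConfigError(f"unreachable state configuration out of {s!r}")
            for j, s2 in enumerate(states):
                P[i, j] = w.get(s2, 0.0) / total
        evals, evecs = np.linalg.eig(P.T)
        pi = np.real(evecs[:, np.argmin(np.abs(evals - 1.0))])
        pi = np.abs(pi) / np.abs(pi).sum()
        occ = pi * np.array([config.mean_duration[s] for s in states])
        acc += occ / occ.sum()
    acc /= acc.sum()
    return {s: float(f) for s, f in zip(states, acc)}


# ---------------------------------------------------------------- main entry

def simulate_dive_record(config: SimConfig, duration_s: float,
                         seed: int) -> tuple[DepthRecord, StateTrace]:
    """Generate a depth record and its ground-truth state trace.

    Fully reproducible for a fixed seed.  ``duration_s`` must be at least
    one hour.  Episode durations are exponential with a floor; bouts are
    rounded to whole dive cycles; transitions between episodes are joined
    by bounded-speed cosine ramps labeled with the destination state.
    """
    if duration_s < 3600:
        raise ConfigError("duration must be at least 1 h")
    rng = np.random.default_rng(seed)
    dt = config.dt
    n = int(round(duration_s / dt))
    t0 = pd.Timestamp(config.t0)
    hour0 = t0.hour + t0.minute / 60.0 + t0.second / 3600.0

    chunks: list[np.ndarray] = []
    labels: list[np.ndarray] = []
    episodes: list[dict] = []
    total = 0
    prev_depth = 0.0
    # start from the hour-0 embedded-chain stationary state (or single state)
    state = config.states[int(rng.integers(len(config.states)))]

    while total < n:
        hour = (hour0 + total * dt / 3600.0) % 24.0
        dur = _duration(config, state, rng)
        lo, hi = config.depth_law[state]
        if state in ("B_d", "B_s"):
            period = config.dive_period[state]
            n_cycles = max(1, int(round(dur / period)))
            # unimodal across bouts: most bouts target the mid-range depth
            base = float(np.clip(rng.normal(0.5 * (lo + hi), (hi - lo) / 6.0),
                                 lo, hi))
            drift = config.depth_drift.get(state, 0.0)
            cycles = []
            # deepest target reachable within one cycle at <=0.9*max_speed
            reachable = 0.9 * config.max_speed * (0.4 * period - 30.0)
            d_hi = min(config.depth_cap * 0.95, reachable)
            for c in range(n_cycles):
                d = base + drift * c + rng.normal(0.0, 0.04 * base)
                d = float(np.clip(d, max(lo * 0.5, 5.0), d_hi))
                cycles.append(_dive_cycle(d, period, config.max_speed, dt))
            seg = np.concatenate(cycles)
            meta_depth = base
        else:
            k = int(round(dur / dt))
            level = float(np.clip(rng.normal(0.5 * (lo + hi), (hi - lo) / 6.0),
                                  lo, hi))
            spread = max(0.25 * (hi - lo), 0.5)
            if state == "R":
                seg = _wander(level, spread, 0.02, k, dt, rng,
                              osc_amp=0.8, osc_period=90.0)
            else:
                # intermediate activity: regular shallow excursions with
                # little drift (a coherent near-surface orbit)
                seg = _wander(level, spread, 0.04, k, dt, rng,
                              osc_amp=4.0, osc_period=120.0)
            period = np.nan
            meta_depth = level

        ramp = _ramp(prev_depth, seg[0] if seg.size else prev_depth,
                     config.max_speed, dt)
        if ramp.size:
            chunks.append(ramp)
            labels.append(np.full(ramp.size, state, dtype="<U3"))
            total += ramp.size
        episodes.append({"state": state, "start_idx": total, "n": seg.size,
                         "target_depth": float(meta_depth),
                         "period": float(period)})
        chunks.append(seg)
        labels.append(np.full(seg.size, state, dtype="<U3"))
        total += seg.size
        prev_depth = float(seg[-1]) if seg.size else prev_depth
        hour_end = (hour0 + total * dt / 3600.0) % 24.0
        state = _draw_next_state(config, state, hour_end, rng)

    depth = np.concatenate(chunks)[:n]
    states = np.concatenate(labels)[:n]
    if config.noise_sd > 0:
        depth = depth + rng.normal(0.0, config.noise_sd, size=n)
    depth = np.clip(depth, 0.0, config.depth_cap)
    record = DepthRecord(t0=t0, dt=dt, depth=depth)
    return record, StateTrace(states=states, episodes=episodes)


def single_state_config(state: str, **overrides) -> SimConfig:
    """Convenience: a config confined to one behavioral state."""
    return replace(SimConfig(**overrides), states=(state,))


# ---------------------------------------------------------------- benchmarks

LORENZ_SIGMA, LORENZ_RHO, LORENZ_BETA = 10.0, 28.0, 8.0 / 3.0


def _lorenz_rk4(n: int, x0=(1.0, 1.0, 1.0), step: float = 0.01,
                discard: int = 0) -> np.ndarray:
    def f(u):
        x, y, z = u
        return np.array([LORENZ_SIGMA * (y - x),
                         x * (LORENZ_RHO - z) - y,
                         x * y - LORENZ_BETA * z])

    u = np.array(x0, dtype=float)
    out = np.empty(n)
    for i in range(n + discard):
        k1 = f(u)
        k2 = f(u + 0.5 * step * k1)
        k3 = f(u + 0.5 * step * k2)
        k4 = f(u + step * k3)
        u = u + (step / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        if i >= discard:
            out[i - discard] = u[0]
    return out


def benchmark_series(name: str, n: int, params: dict | None = None,
                     seed: int | None = None) -> np.ndarray:
    """Validation standards for the invariant estimators.

    ``sine`` (params: amplitude, period in samples, phase), ``white_noise``
    (sd), ``ar1`` (phi, sd), ``lorenz_x`` (x0, step, discard; classical
    parameters sigma=10, rho=28, beta=8/3, fixed-step RK4).
    """
    if n < 1000:
        raise ConfigError("benchmark series require n >= 1000")
    p = dict(params or {})
    rng = np.random.default_rng(seed)
    if name == "sine":
        a = p.get("amplitude", 1.0)
        period = p.get("period", 100.0)
        phase = p.get("phase", 0.0)
        return a * np.sin(2 * np.pi * np.arange(n) / period + phase)
    if name == "white_noise":
        return rng.normal(0.0, p.get("sd", 1.0), size=n)
    if name == "ar1":
        phi = p.get("phi", 0.9)
        eps = rng.normal(0.0, p.get("sd", 1.0), size=n)
        x, _ = lfilter([1.0], [1.0, -phi], eps, zi=[0.0])
        return x
    if name == "lorenz_x":
        return _lorenz_rk4(n, x0=tuple(p.get("x0", (1.0, 1.0, 1.0))),
                           step=p.get("step", 0.01),
                           discard=int(p.get("discard", 0)))
    raise ConfigError(f"unknown benchmark series {name!r}")
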