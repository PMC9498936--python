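import numpy as np
import pandas as pd
import pytest

from divechaos import (ConfigError, DataError, before_after_median,
                       cumulative_tag_count, day_night_ecdf,
                       daypart_partition, diurnal_percentiles, time_budget)
from conftest import make_labels


def hourly_times(n, t0="2013-09-01", freq="30min"):
    return pd.date_range(t0, periods=n, freq=freq, tz="UTC")


class TestDiurnalPercentiles:
    def test_constant_feature(self):
        t = hourly_times(400)
        tab = diurnal_percentiles(t, np.full(400, 3.3), bin_h=3)
        assert len(tab) == 8
        filled = tab.dropna()
        assert np.allclose(filled[["p5", "p50", "p75"]], 3.3)

    def test_bins_tile_24h(self):
        t = hourly_times(480)
        tab = diurnal_percentiles(t, np.arange(480.0), bin_h=6)
        assert list(tab.bin_start_h) == [0, 6, 12, 18]
        assert tab.n.sum() == 480

    def test_hour_feature_median_within_bin(self):
        t = hourly_times(960)
        hours = t.hour + t.minute / 60.0
        tab = diurnal_percentiles(t, hours.to_numpy(), bin_h=3)
        for _, row in tab.iterrows():
            assert row.bin_start_h <= row.p50 < row.bin_start_h + 3

    def test_percentile_columns_monotone(self):
        rng = np.random.default_rng(0)
        t = hourly_times(600)
        tab = diurnal_percentiles(t, rng.gamma(2, 2, 600), bin_h=3)
        ok = tab.dropna()
        assert np.all(ok.p5 <= ok.p50)
        assert np.all(ok.p50 <= ok.p75)

    def test_invalid_bin(self):
        with pytest.raises(ConfigError):
            diurnal_percentiles(hourly_times(10), np.zeros(10), bin_h=5)


class TestDayNightEcdf:
    def test_identical_distributions_small_gap(self):
        rng = np.random.default_rng(1)
        t = hourly_times(4000, freq="17min")
        v = rng.normal(size=4000)
        e = day_night_ecdf(t, v)
        bound = 2 * (1 / np.sqrt(e.n_day) + 1 / np.sqrt(e.n_night))
        assert e.max_gap <= bound

    def test_shifted_day_dominates(self):
        t = hourly_times(2000, freq="29min")
        hours = (t.hour + t.minute / 60.0).to_numpy()
        v = np.where((hours >= 6) & (hours < 18), 10.0, 0.0) + \
            np.random.default_rng(2).normal(0, 0.1, 2000)
        e = day_night_ecdf(t, v)
        assert e.max_gap > 0.95
        assert e.day_x.min() > e.night_x.max() - 1.0

    def test_empty_side_error(self):
        t = pd.date_range("2013-09-01 10:00", periods=10, freq="10min",
                          tz="UTC")
        with pytest.raises(DataError):
            day_night_ecdf(t, np.arange(10.0))


class TestTimeBudget:
    def test_equal_tags_quarter_each(self):
        tab = time_budget(make_labels(n=40))
        frac = dict(zip(tab.tag, tab.fraction))
        for tag in ("deep-bout", "shallow-bout", "intermediate",
                    "near-surface-shallow"):
            assert frac[tag] == pytest.approx(0.25)
        assert frac["bouts"] == pytest.approx(0.5)

    def test_fractions_sum_to_one(self):
        tab = time_budget(make_labels(n=37))
        core = tab[tab.tag != "bouts"]
        assert core.fraction.sum() == pytest.approx(1.0)

    def test_impossible_confidence_flagged_not_error(self):
        labels = make_labels(n=12, confidence=0.8)
        tab = time_budget(labels, min_confidence=1.0)
        assert tab.attrs["zero_denominator"]
        assert np.isnan(tab.fraction).all()


class TestDaypartPartition:
    def test_single_tag_everywhere(self):
        labels = make_labels(n=200, tags=("deep-bout",))
        tab = daypart_partition(labels, bin_h=3)
        ok = tab.dropna()
        assert np.allclose(ok["deep-bout"], 1.0)

    def test_rows_normalized(self):
        labels = make_labels(n=333)
        tab = daypart_partition(labels, bin_h=3)
        cols = [c for c in tab.columns if c not in ("bin_start_h", "n")]
        sums = tab[cols].sum(axis=1)
        ok = tab.n > 0
        np.testing.assert_allclose(sums[ok], 1.0)


class TestCumulativeTagCount:
    def test_absent_tag_is_error(self):
        with pytest.raises(ConfigError, match="unknown tag"):
            cumulative_tag_count(make_labels(n=8), "no-such-tag")

    def test_all_windows_of_tag(self):
        labels = make_labels(n=25, tags=("deep-bout",))
        out = cumulative_tag_count(labels, "deep-bout")
        np.testing.assert_array_equal(out.to_numpy(), np.arange(1, 26))

    def test_non_decreasing(self):
        out = cumulative_tag_count(make_labels(n=60), "intermediate")
        assert np.all(np.diff(out.to_numpy()) >= 0)


class TestBeforeAfterMedian:
    def test_identical_halves_zero_difference(self):
        t = hourly_times(200, freq="1h")
        v = np.tile([1.0, 2.0, 3.0, 4.0], 50)
        res = before_after_median(t, v, t[100], span_days=4)
        assert res.difference == 0.0

    def test_injected_step_recovered(self):
        rng = np.random.default_rng(5)
        t = hourly_times(2000, freq="1h")
        v = rng.normal(10, 1, 2000)
        split = t[1000]
        v[1000:] += 4.0
        res = before_after_median(t, v, split, span_days=30)
        assert res.difference == pytest.approx(4.0, abs=0.5)
        assert res.ci_low <= res.difference <= res.ci_high

    def test_zero_span_error(self):
        t = hourly_times(10, freq="1h")
        with pytest.raises(ConfigError):
            before_after_median(t, np.arange(10.0), t[5], span_days=0)

    def test_truncation_flagged(self):
        t = hourly_times(48, freq="1h")
        res = before_after_median(t, np.arange(48.0), t[24], span_days=10)
        assert res.truncated

    def test_bootstrap_deterministic(self):
        t = hourly_times(300, freq="1h")
        v = np.random.default_rng(0).normal(size=300)
        a = before_after_median(t, v, t[150], span_days=5, seed=3)
        b = before_after_median(t, v, t[150], span_days=5, seed=3)
        assert (a.ci_low, a.ci_high) == (b.ci_low, b.ci_high)


class TestNoonRestSignatures:
    """Constructed noon-rest forcing shows up in the diurnal summaries."""

    @pytest.fixture(scope="class")
    def noon_rest(self):
        from dataclasses import replace
        from divechaos import (EmbeddingParams, SimConfig,
                               simulate_dive_record, sliding_features)
        from divechaos.evaluation import window_true_states
        # constructed forcing scenario: strong noon-rest modulation with
        # short episodes, so every hour-of-day bin samples many episodes
        cfg = replace(
            SimConfig(), diurnal_modulation=0.9,
            diurnal_shallow_modulation=0.0,
            mean_duration={"R": 2700.0, "B_s": 2400.0, "B_d": 4080.0,
                           "I": 1500.0},
            min_duration={"R": 600.0, "B_s": 1020.0, "B_d": 2040.0,
                          "I": 450.0})
        out = []
        for seed in range(10):
            rec, trace = simulate_dive_record(cfg, 3 * 86400.0, seed=seed)
            feats = sliding_features(rec, EmbeddingParams(255, 3, 1.0),
                                     estimators=("L", "Ek"))
            truth = window_true_states(trace, 1.0, 1800, 600, len(feats))
            out.append((feats, truth))
        return out

    def test_noon_energy_below_midnight(self, noon_rest):
        """Diving activity is quietest around solar noon, not at night."""
        wins = 0
        for feats, _ in noon_rest:
            tab = diurnal_percentiles(feats.window_mid, feats.Ek_med, bin_h=3)
            noon = tab[tab.bin_start_h == 12].p50.iloc[0]
            midnight = tab[tab.bin_start_h == 0].p50.iloc[0]
            wins += noon < midnight
        assert wins > 5

    def test_day_ecdf_has_more_low_energy_mass(self, noon_rest):
        wins = 0
        for feats, _ in noon_rest:
            e = day_night_ecdf(feats.window_mid, feats.Ek_med)
            med = np.median(np.concatenate([e.day_x, e.night_x]))
            f_day = np.searchsorted(e.day_x, med) / e.n_day
            f_night = np.searchsorted(e.night_x, med) / e.n_night
            wins += f_day > f_night
        assert wins > 5

    def test_near_surface_fraction_peaks_at_noon(self, noon_rest):
        from divechaos.evaluation import TAG_TO_STATE
        state_to_tag = {v: k for k, v in TAG_TO_STATE.items()}
        wins = 0
        for feats, truth in noon_rest:
            labels = pd.DataFrame({
                "window_start": feats.window_start,
                "window_mid": feats.window_mid,
                "cluster": 0, "confidence": 1.0,
                "tag": [state_to_tag[s] for s in truth]})
            tab = daypart_partition(labels, bin_h=3)
            col = "near-surface-shallow"
            if col not in tab:
                continue
            noon = tab[tab.bin_start_h == 12][col].iloc[0]
            midnight = tab[tab.bin_start_h == 0][col].iloc[0]
            wins += noon > midnight
        assert wins > 5


class TestChangePointInNearSurfaceActivity:
    """A mid-record drop in rest probability bends the cumulative count."""

    def test_cumulative_slope_drops_after_changepoint(self):
        from dataclasses import replace
        from divechaos import SimConfig, simulate_dive_record
        base = SimConfig()
        # after the change point, transitions into rest are five times rarer
        reduced = {s: dict(w) for s, w in base.transition_weights.items()}
        for s in reduced:
            if "R" in reduced[s]:
                reduced[s]["R"] *= 0.2
        after_cfg = replace(SimConfig(), transition_weights=reduced)
        wins = 0
        for seed in range(10):
            _, tr_a = simulate_dive_record(base, 2 * 86400.0, seed=seed)
            _, tr_b = simulate_dive_record(after_cfg, 2 * 86400.0,
                                           seed=seed + 100)
            flags = np.concatenate([tr_a.states == "R", tr_b.states == "R"])
            # per-window (30-min) presence of the near-surface state
            w = 1800
            n_win = flags.size // w
            present = np.array([flags[i * w:(i + 1) * w].any()
                                for i in range(n_win)]).astype(int)
            cum = np.cumsum(present)
            half = n_win // 2
            slope_before = np.polyfit(np.arange(half), cum[:half], 1)[0]
            slope_after = np.polyfit(np.arange(half), cum[half:2 * half], 1)[0]
            wins += slope_after < slope_before
        assert wins > 5
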