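import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from divechaos import (DataError, DelaySelection, DepthRecord,
                       EmbeddingParams, FNNProfile, NumericalError,
                       auto_mutual_information, autocorrelation,
                       benchmark_series, delay_embed, false_nearest_fraction,
                       segment_median_curve, select_delay, select_dimension)
from divechaos.embedding import lag_grid


class TestDelayEmbed:
    def test_small_series_coordinates(self):
        cloud = delay_embed(np.array([1., 2, 3, 4, 5]),
                            EmbeddingParams(tau_s=1, m=3))
        np.testing.assert_array_equal(
            cloud.points, [[1, 2, 3], [2, 3, 4], [3, 4, 5]])
        np.testing.assert_array_equal(cloud.time_index, [0, 1, 2])

    def test_constant_series(self):
        cloud = delay_embed(np.full(10, 3.0), EmbeddingParams(tau_s=2, m=3))
        assert np.all(cloud.points == 3.0)

    @given(st.integers(1, 4), st.integers(1, 5), st.integers(0, 1000))
    @settings(max_examples=40, deadline=None)
    def test_coordinate_identity_exhaustive(self, m, tau, seed):
        x = np.random.default_rng(seed).normal(size=(m - 1) * tau + 7)
        cloud = delay_embed(x, EmbeddingParams(tau_s=tau, m=m))
        for i in range(cloud.n):
            for j in range(m):
                assert cloud.points[i, j] == x[i + j * tau]

    def test_too_short_reports_minimum(self):
        with pytest.raises(DataError, match="at least 21"):
            delay_embed(np.arange(10.0), EmbeddingParams(tau_s=10, m=3))


class TestAutoMutualInformation:
    def test_constant_series_zero_with_warning(self):
        with pytest.warns(UserWarning, match="constant"):
            _, I = auto_mutual_information(np.full(5000, 2.0), 50)
        assert np.all(I == 0)

    def test_iid_noise_small(self):
        x = benchmark_series("white_noise", 100000, seed=3)
        lags, I = auto_mutual_information(x, 50, n_bins=32)
        assert I[lags > 0].max() < 0.01  # bias bound 32^2/(2e5) < 0.01

    def test_sawtooth_recurrence(self):
        T = 100
        x = np.tile(np.arange(T, dtype=float), 500)
        lags, I = auto_mutual_information(x, 2 * T)
        i0 = np.flatnonzero(lags == 0)[0]
        iT = np.flatnonzero(lags == T)[0]
        assert I[iT] == pytest.approx(I[i0], rel=0.01)

    def test_time_reversal_symmetry(self):
        x = benchmark_series("ar1", 20000, {"phi": 0.8}, seed=1)
        _, a = auto_mutual_information(x, 30)
        _, b = auto_mutual_information(x[::-1], 30)
        np.testing.assert_allclose(a, b, atol=1e-3)


class TestAutocorrelation:
    def test_lag_zero_is_one(self):
        x = benchmark_series("ar1", 5000, {"phi": 0.3}, seed=0)
        _, r = autocorrelation(x, 20)
        assert r[0] == 1.0

    def test_sine_zero_crossing_at_quarter_period(self):
        x = benchmark_series("sine", 50000, {"period": 400.0})
        lags, r = autocorrelation(x, 300)
        first_neg = lags[np.flatnonzero(r < 0)[0]]
        assert abs(first_neg - 100.0) <= 1.0

    def test_ar1_matches_analytic(self):
        x = benchmark_series("ar1", 100000, {"phi": 0.9}, seed=7)
        lags, r = autocorrelation(x, 100)
        assert np.abs(r - 0.9 ** lags).max() < 0.05

    def test_constant_series_error(self):
        with pytest.raises(DataError):
            autocorrelation(np.full(1000, 1.0), 10)


class TestSegmentMedian:
    def test_identical_segments(self):
        seg = benchmark_series("sine", 21600, {"period": 600.0})
        rec = DepthRecord(t0="2013-01-01", dt=1.0,
                          depth=np.tile(seg, 3) + 10.0)
        sel = segment_median_curve(rec, "ami", max_lag_s=900)
        lags, single = auto_mutual_information(
            rec.depth[:21600], 900, bin_range=(rec.depth.min(), rec.depth.max()))
        np.testing.assert_allclose(sel.ami, single, atol=1e-9)
        assert sel.n_segments == 3

    def test_too_few_segments(self):
        rec = DepthRecord(t0="2013-01-01", dt=1.0, depth=np.arange(7200.0))
        with pytest.raises(DataError, match="two segments"):
            segment_median_curve(rec, "acf")


class TestSelectDelay:
    def test_first_local_minimum(self):
        sel = select_delay(DelaySelection(
            lags_s=np.array([0., 100, 200, 300, 400]),
            ami=np.array([3., 2, 1, 2, 3])), smooth=False)
        assert sel.tau_s == pytest.approx(200.0, abs=1e-6)
        assert sel.method == "ami_min"

    def test_fallback_to_acf_zero(self):
        lags = np.arange(0., 700, 100)
        sel = select_delay(DelaySelection(
            lags_s=lags, ami=7.0 - 0.01 * lags,
            acf=np.where(lags < 500, 0.5, -0.2)), smooth=False)
        assert sel.tau_s == 500.0
        assert sel.method == "acf_zero"

    def test_no_minimum_no_zero(self):
        lags = np.arange(0., 500, 100)
        with pytest.raises(NumericalError):
            select_delay(DelaySelection(lags_s=lags, ami=5.0 - 0.001 * lags,
                                        acf=np.full(lags.size, 0.9)))

    def test_scale_invariance(self):
        x = benchmark_series("ar1", 40000, {"phi": 0.95}, seed=2)
        def tau_of(series):
            lags, I = auto_mutual_information(series, 200)
            _, r = autocorrelation(series, 200)
            return select_delay(DelaySelection(
                lags_s=lags, ami=I,
                acf=r[lag_grid(200, 1).astype(int)])).tau_s
        assert tau_of(x) == tau_of(1000.0 * x + 77.0)


class TestFalseNearestNeighbors:
    def test_noise_free_sine_fnn2_negligible(self):
        x = benchmark_series("sine", 5000, {"period": 1433.7})
        prof = false_nearest_fraction(x, tau=358, m_range=[2], theiler=1434)
        assert prof.fnn_fraction[0] < 0.02

    def test_sine_needs_two_dimensions(self):
        x = benchmark_series("sine", 5000, {"period": 1433.7})
        prof = false_nearest_fraction(x, tau=358, m_range=range(1, 4),
                                      theiler=1434)
        assert select_dimension(prof, threshold=0.02) == 2

    def test_noise_stays_high(self):
        x = benchmark_series("white_noise", 5000, seed=2)
        prof = false_nearest_fraction(x, tau=1, m_range=range(1, 6), theiler=1)
        assert np.all(prof.fnn_fraction > 0.2)

    def test_fnn_scale_invariance(self):
        x = benchmark_series("lorenz_x", 3000, {"discard": 500})
        a = false_nearest_fraction(x, tau=17, m_range=[2, 3], theiler=75)
        b = false_nearest_fraction(50.0 * x + 3.0, tau=17, m_range=[2, 3],
                                   theiler=75)
        np.testing.assert_allclose(a.fnn_fraction, b.fnn_fraction, atol=1e-12)

    def test_monotone_on_deterministic_benchmarks(self):
        for series, tau, th in [
                (benchmark_series("sine", 5000, {"period": 1433.7}), 358, 1434),
                (benchmark_series("lorenz_x", 5000, {"discard": 500}), 17, 75)]:
            prof = false_nearest_fraction(series, tau=tau,
                                          m_range=range(1, 5), theiler=th)
            assert np.all(np.diff(prof.fnn_fraction) <= 1e-12)


class TestSelectDimension:
    def test_threshold_rule(self):
        prof = FNNProfile(m_values=np.arange(1, 5),
                          fnn_fraction=np.array([0.8, 0.3, 0.005, 0.004]),
                          r_t=3.0)
        assert select_dimension(prof, threshold=0.01) == 3

    def test_all_zero_profile(self):
        prof = FNNProfile(m_values=np.arange(1, 4),
                          fnn_fraction=np.zeros(3), r_t=3.0)
        assert select_dimension(prof) == 1

    def test_threshold_never_reached(self):
        prof = FNNProfile(m_values=np.arange(1, 4),
                          fnn_fraction=np.array([0.9, 0.5, 0.3]), r_t=3.0)
        with pytest.raises(NumericalError, match="never fell below"):
            select_dimension(prof)
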