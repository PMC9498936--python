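import numpy as np
import pandas as pd
import pytest

from divechaos import ConfigError, assign, fit_gmm, model_scan, semantic_labels
from divechaos.clustering import DEFAULT_FEATURES, MixtureFit, serialize_fit


def blob_frame(centers, n_per=80, sd=1.0, seed=0):
    """Gaussian blobs in the four standard feature columns."""
    rng = np.random.default_rng(seed)
    rows = []
    for c in centers:
        rows.append(rng.normal(c, sd, size=(n_per, len(c))))
    X = np.vstack(rows)
    return pd.DataFrame(X, columns=DEFAULT_FEATURES)


class TestFitGmm:
    def test_k1_matches_sample_moments(self):
        df = blob_frame([[10, 5, 0, 2]], n_per=300, sd=2.0)
        fit = fit_gmm(df, 1, scale="raw", n_init=1)
        X = df.to_numpy()
        np.testing.assert_allclose(fit.means[0], X.mean(axis=0), rtol=1e-6)
        np.testing.assert_allclose(fit.variances[0], X.var(axis=0), rtol=1e-4)

    def test_well_separated_blobs_recovered(self):
        centers = [[0, 0, 0, 0], [30, 30, 30, 30]]
        hits = 0
        for seed in range(10):
            df = blob_frame(centers, seed=seed)
            fit = fit_gmm(df, 2, scale="raw", seed=seed)
            order = np.argsort(fit.means[:, 0])
            err = np.abs(fit.means[order] - np.array(centers)).max()
            hits += err < 0.1 * 30
        assert hits >= 9

    def test_determinism(self):
        df = blob_frame([[0, 0, 0, 0], [5, 5, 5, 5]], seed=3)
        a = fit_gmm(df, 2, seed=42, scale="raw")
        b = fit_gmm(df, 2, seed=42, scale="raw")
        assert a.aic == b.aic
        np.testing.assert_array_equal(a.means, b.means)

    def test_loglik_monotone_over_em_iterations(self):
        df = blob_frame([[0, 0, 0, 0], [4, 1, 2, 3]], sd=1.5, seed=1)
        fit = fit_gmm(df, 2, scale="raw", seed=0)
        assert np.all(np.diff(fit.loglik_trace) >= -1e-6)

    def test_aic_formula(self):
        df = blob_frame([[0, 0, 0, 0]], n_per=200)
        fit = fit_gmm(df, 1, structure="diag", scale="raw", n_init=1)
        d = len(DEFAULT_FEATURES)
        assert fit.n_params == (1 - 1) + d + d
        assert fit.aic == pytest.approx(2 * fit.n_params - 2 * fit.loglik)

    def test_shared_structure_worse_on_unequal_covariances(self):
        wins = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            a = rng.normal(0, 0.5, size=(100, 4))
            b = rng.normal(8, 4.0, size=(100, 4))
            df = pd.DataFrame(np.vstack([a, b]), columns=DEFAULT_FEATURES)
            diag = fit_gmm(df, 2, structure="diag", scale="raw", seed=seed)
            shared = fit_gmm(df, 2, structure="diag-shared", scale="raw",
                             seed=seed)
            wins += shared.aic >= diag.aic
        assert wins >= 8

    def test_k_too_large(self):
        df = blob_frame([[0, 0, 0, 0]], n_per=30)
        with pytest.raises(ConfigError, match="too large"):
            fit_gmm(df, 5, scale="raw")

    def test_sklearn_cross_check(self):
        """Independent EM implementation agrees on a diagonal-covariance fit."""
        from sklearn.mixture import GaussianMixture
        df = blob_frame([[0, 0, 0, 0], [10, 10, 10, 10]], sd=1.0, seed=2)
        ours = fit_gmm(df, 2, structure="diag", scale="raw", seed=0)
        ref = GaussianMixture(2, covariance_type="diag", n_init=5,
                              random_state=0, reg_covar=1e-10,
                              tol=1e-8).fit(df.to_numpy())
        ref_ll = ref.score(df.to_numpy()) * len(df)
        assert ours.loglik == pytest.approx(ref_ll, rel=1e-3)
        ours_sorted = ours.means[np.argsort(ours.means[:, 0])]
        ref_sorted = ref.means_[np.argsort(ref.means_[:, 0])]
        np.testing.assert_allclose(ours_sorted, ref_sorted, atol=0.05)


class TestModelScan:
    def test_single_blob_selects_one(self):
        hits = 0
        for seed in range(10):
            df = blob_frame([[5, 5, 5, 5]], n_per=150, sd=1.0, seed=seed)
            scan = model_scan(df, k_range=range(1, 5), scale="raw",
                              n_init=5, seed=seed)
            hits += scan.k == 1
        assert hits >= 8

    def test_failed_cells_propagate(self):
        df = blob_frame([[0, 0, 0, 0]], n_per=45)
        scan = model_scan(df, k_range=range(1, 7), scale="raw", n_init=3)
        assert (scan.table.error != "").any()
        assert np.isfinite(scan.table.aic).any()


class TestAssign:
    def make_fit(self):
        d = len(DEFAULT_FEATURES)
        means = np.array([[0.0] * d, [10.0] * d])
        return MixtureFit(k=2, structure="diag", weights=np.array([0.5, 0.5]),
                          means=means, variances=np.ones((2, d)),
                          loglik=0.0, aic=0.0, n_params=0,
                          loglik_trace=np.zeros(1),
                          feature_names=DEFAULT_FEATURES, converged=True,
                          n_iter=1)

    def test_point_at_component_mean_is_confident(self):
        fit = self.make_fit()
        df = pd.DataFrame([[0.0] * 4], columns=DEFAULT_FEATURES)
        mem = assign(fit, df)
        assert mem.confidence[0] > 0.99
        assert mem.labels[0] == 0

    def test_equidistant_point_splits_evenly(self):
        fit = self.make_fit()
        df = pd.DataFrame([[5.0] * 4], columns=DEFAULT_FEATURES)
        mem = assign(fit, df)
        np.testing.assert_allclose(mem.posterior[0], [0.5, 0.5])
        assert mem.labels[0] == 0  # tie goes to the lower index

    def test_missing_row_unassigned(self):
        fit = self.make_fit()
        df = pd.DataFrame([[0, 0, np.nan, 0], [10, 10, 10, 10]],
                          columns=DEFAULT_FEATURES)
        mem = assign(fit, df)
        assert mem.labels[0] == -1
        assert np.isnan(mem.confidence[0])
        assert mem.labels[1] == 1

    def test_rows_sum_to_one(self):
        fit = self.make_fit()
        df = blob_frame([[2, 2, 2, 2]], n_per=50)
        mem = assign(fit, df)
        np.testing.assert_allclose(mem.posterior.sum(axis=1), 1.0, atol=1e-9)


class TestSemanticLabels:
    def make_fit(self, l_means):
        d = len(DEFAULT_FEATURES)
        means = np.zeros((len(l_means), d))
        means[:, 0] = l_means
        return MixtureFit(k=len(l_means), structure="diag",
                          weights=np.full(len(l_means), 1 / len(l_means)),
                          means=means, variances=np.ones((len(l_means), d)),
                          loglik=0.0, aic=0.0, n_params=0,
                          loglik_trace=np.zeros(1),
                          feature_names=DEFAULT_FEATURES, converged=True,
                          n_iter=1)

    def test_ordering_rule(self):
        fit = self.make_fit([500.0, 80.0, 5.0, 30.0])
        df = pd.DataFrame(fit.means, columns=DEFAULT_FEATURES)
        _, info = semantic_labels(fit, df)
        assert info["tag_of_component"] == {
            0: "deep-bout", 1: "shallow-bout", 3: "intermediate",
            2: "near-surface-shallow"}

    def test_permutation_invariance(self):
        fit = self.make_fit([500.0, 80.0, 5.0, 30.0])
        perm = [2, 0, 3, 1]
        fit_p = self.make_fit([fit.means[i, 0] for i in perm])
        df = pd.DataFrame(fit.means, columns=DEFAULT_FEATURES)
        _, a = semantic_labels(fit, df)
        _, b = semantic_labels(fit_p, df)
        tags_a = {round(fit.means[c, 0]): t
                  for c, t in a["tag_of_component"].items()}
        tags_b = {round(fit_p.means[c, 0]): t
                  for c, t in b["tag_of_component"].items()}
        assert tags_a == tags_b

    def test_general_k_uses_ordered_cluster_names(self):
        fit = self.make_fit([100.0, 10.0])
        df = pd.DataFrame(fit.means, columns=DEFAULT_FEATURES)
        _, info = semantic_labels(fit, df)
        assert info["tag_of_component"] == {0: "cluster-1", 1: "cluster-2"}

    def test_serialization_roundtrip(self):
        fit = self.make_fit([100.0, 10.0])
        blob = serialize_fit(fit)
        assert blob["k"] == 2
        assert blob["feature_names"] == list(DEFAULT_FEATURES)
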