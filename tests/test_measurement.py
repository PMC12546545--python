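"""Measurement models, factor scoring and cluster-mean reliability."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mlsam.measurement import (
    FactorModelFit,
    TwoLevelFactorFit,
    cluster_decompose,
    cluster_mean_reliability,
    compute_scores,
    fit_single_factor_ml,
    fit_two_level_measurement,
    regression_score_matrix,
    _ml_discrepancy,
)


def _clean_two_level_fit(psi_b=1.0, theta_b=0.2, psi_w=1.0, theta_w=0.8,
                         n1=50.0):
    """TwoLevelFactorFit at clean population values (no cluster-mean
    contamination)."""
    b = FactorModelFit(loadings=np.ones(3), theta=np.full(3, theta_b),
                       psi=psi_b, indicator_means=np.zeros(3), n=10 ** 6,
                       level="between")
    w = FactorModelFit(loadings=np.ones(3), theta=np.full(3, theta_w),
                       psi=psi_w, indicator_means=np.zeros(3), n=10 ** 6,
                       level="within")
    return TwoLevelFactorFit(between=b, within=w, n1=n1,
                             between_contaminated=False)


class TestClusterDecompose:
    def test_centering_and_reconstruction(self, within_ds):
        cols = ["x1", "x2", "x3"]
        between, within = cluster_decompose(within_ds.data, cols)
        assert len(between) == within_ds.n_clusters
        per_cluster = within.groupby(within_ds.data["cluster_id"]).mean()
        assert np.allclose(per_cluster.to_numpy(), 0.0, atol=1e-12)
        rebuilt = (within.to_numpy()
                   + between.loc[within_ds.data["cluster_id"]].to_numpy())
        assert np.allclose(rebuilt, within_ds.data[cols].to_numpy())

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            cluster_decompose(pd.DataFrame({"cluster_id": [], "x1": []}), ["x1"])


class TestFitSingleFactorML:
    def test_compound_symmetry_closed_form(self):
        """Equal-loading compound symmetry: S with unit off-diagonals and
        diagonal 1.8 gives Lambda=(1,1,1), Theta=0.8 under psi=1."""
        S = np.ones((3, 3)) + 0.8 * np.eye(3)
        fit = fit_single_factor_ml(S, np.zeros(3), n=1000,
                                   identification="variance")
        assert fit.status == "converged"
        assert np.allclose(fit.loadings, 1.0, atol=1e-8)
        assert np.allclose(fit.theta, 0.8, atol=1e-8)
        assert fit.psi == 1.0

    def test_identity_input_hits_boundary(self):
        fit = fit_single_factor_ml(np.eye(3), np.zeros(3), n=1000)
        assert fit.status == "boundary"
        # no common variance: loadings and/or factor variance driven to zero
        lam_v = np.asarray(fit.loadings) * np.sqrt(fit.psi)
        assert np.all(np.abs(lam_v[1:] * fit.psi) < 0.05) or fit.psi < 1e-5

    def test_non_pd_input_flagged_not_raised(self):
        S = np.array([[1.0, 0.99, 0.0], [0.99, 1.0, 0.99], [0.0, 0.99, 1.0]])
        assert np.linalg.eigvalsh(S).min() < 0
        fit = fit_single_factor_ml(S, np.zeros(3), n=100)
        assert fit.status == "non_PD"

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(lam2=st.floats(0.5, 1.5), lam3=st.floats(0.5, 1.5),
           psi=st.floats(0.3, 2.0), theta=st.floats(0.2, 1.5))
    def test_saturated_model_recovers_parameters(self, lam2, lam3, psi, theta):
        """With three indicators the single-factor model is just-identified,
        so ML recovers any admissible generating parameters exactly."""
        lam = np.array([1.0, lam2, lam3])
        S = psi * np.outer(lam, lam) + theta * np.eye(3)
        fit = fit_single_factor_ml(S, np.zeros(3), n=10 ** 4,
                                   identification="marker")
        assert fit.status == "converged"
        assert np.allclose(fit.loadings, lam, rtol=1e-6)
        assert fit.psi == pytest.approx(psi, rel=1e-6)
        assert np.allclose(fit.theta, theta, rtol=1e-6)

    def test_fixed_loadings_ml_optimality(self, rng):
        """The (psi, theta) fit given loadings attains a discrepancy no worse
        than the generating values on sampled covariances."""
        lam = np.ones(3)
        for _ in range(5):
            X = (rng.normal(0, 1, (200, 1)) * lam
                 + rng.normal(0, np.sqrt(0.8), (200, 3)))
            S = np.cov(X, rowvar=False)
            fit = fit_single_factor_ml(S, np.zeros(3), n=200,
                                       identification="marker",
                                       fixed_loadings=lam)
            f_hat = _ml_discrepancy(S, lam, fit.theta, fit.psi)
            f_true = _ml_discrepancy(S, lam, np.full(3, 0.8), 1.0)
            assert f_hat <= f_true + 1e-8


class TestScoring:
    def test_regression_score_matrix_oracle(self):
        """A = psi Lambda' (Lambda psi Lambda' + Theta)^{-1}: closed form
        1'(J + theta I)^{-1} for unit loadings."""
        fit = FactorModelFit(loadings=np.ones(3), theta=np.full(3, 0.8),
                             psi=1.0, indicator_means=np.zeros(3), n=100)
        sm = regression_score_matrix(fit)
        assert np.allclose(sm.weights, 1 / 3.8)
        assert sm.validity == pytest.approx(3 / 3.8)
        fit2 = FactorModelFit(loadings=np.ones(3), theta=np.full(3, 0.2),
                              psi=1.0, indicator_means=np.zeros(3), n=100)
        sm2 = regression_score_matrix(fit2)
        assert np.allclose(sm2.weights, 0.3125)
        assert sm2.validity == pytest.approx(0.9375)

    def test_error_free_limit_validity_one(self):
        fit = FactorModelFit(loadings=np.ones(3), theta=np.full(3, 1e-10),
                             psi=1.0, indicator_means=np.zeros(3), n=100)
        assert regression_score_matrix(fit).validity == pytest.approx(1.0, abs=1e-8)

    def test_inadmissible_fit_refused(self):
        fit = FactorModelFit(loadings=np.ones(3), theta=np.full(3, 0.8),
                             psi=1.0, indicator_means=np.zeros(3), n=100,
                             status="boundary")
        with pytest.raises(ValueError):
            regression_score_matrix(fit)

    def test_compute_scores_properties(self):
        fit = FactorModelFit(loadings=np.ones(3), theta=np.full(3, 0.8),
                             psi=1.0, indicator_means=np.zeros(3), n=100)
        sm = regression_score_matrix(fit)
        means = np.array([1.0, 2.0, 3.0])
        at_means = compute_scores(sm, means[None, :], means)
        assert at_means[0] == pytest.approx(0.0)
        one_up = compute_scores(sm, (means + 1.0)[None, :], means)
        assert one_up[0] == pytest.approx(3 / 3.8)
        doubled = compute_scores(sm, (means + 2.0)[None, :], means)
        assert doubled[0] == pytest.approx(2 * one_up[0])
        with_nan = compute_scores(sm, np.array([[1.0, np.nan, 3.0]]), means)
        assert np.isnan(with_nan[0])

    def test_validity_is_score_latent_covariance(self, big_within_ds):
        """c equals cov(score, true latent)/psi on simulated data."""
        fit = fit_two_level_measurement(big_within_ds, "x")
        sm = regression_score_matrix(fit.within)
        _, within_tab = cluster_decompose(big_within_ds.data, ["x1", "x2", "x3"])
        scores = within_tab.to_numpy() @ sm.weights
        truth = big_within_ds.sidecar["eta_x_w"].to_numpy()
        c_emp = np.cov(scores, truth)[0, 1] / fit.within.psi
        assert c_emp == pytest.approx(sm.validity, abs=0.02)


class TestTwoLevelMeasurement:
    def test_parameter_recovery(self, big_within_ds):
        fit = fit_two_level_measurement(big_within_ds, "x")
        assert fit.admissible
        assert np.allclose(fit.within.loadings, 1.0, atol=0.05)
        assert np.allclose(fit.within.theta, 0.8, atol=0.05)
        assert fit.within.psi == pytest.approx(1.0, abs=0.05)
        # contamination-adjusted between variance recovers psi_between
        assert fit.psi_between_adj == pytest.approx(1.0, abs=0.15)

    def test_between_fit_uses_cluster_means(self, within_ds):
        fit = fit_two_level_measurement(within_ds, "x")
        assert fit.between.n == within_ds.n_clusters

    def test_all_singleton_clusters_rejected(self):
        data = pd.DataFrame({"cluster_id": range(10),
                             "x1": np.random.default_rng(0).normal(size=10),
                             "x2": np.random.default_rng(1).normal(size=10),
                             "x3": np.random.default_rng(2).normal(size=10)})
        from mlsam.datagen import MultilevelDataset
        ds = MultilevelDataset(data=data, design="within")
        with pytest.raises(ValueError):
            fit_two_level_measurement(ds, "x")

    def test_collinear_cluster_means_flagged_non_pd(self, rng):
        """Cluster means that are exact copies of one indicator give a
        singular between covariance."""
        base = rng.normal(size=400)
        cluster = np.repeat(np.arange(100), 4)
        data = pd.DataFrame({"cluster_id": cluster, "x1": base,
                             "x2": base, "x3": base})
        from mlsam.datagen import MultilevelDataset
        ds = MultilevelDataset(data=data, design="within")
        fit = fit_two_level_measurement(ds, "x", tie_loadings=False)
        assert fit.between.status == "non_PD"


class TestClusterMeanReliability:
    def test_population_values(self):
        """R^B = 1.2/(1.2 + 1.8/n1) at the generating parameters."""
        fit = _clean_two_level_fit()
        assert np.allclose(cluster_mean_reliability(fit, 50), 1.2 / 1.236)
        assert np.allclose(cluster_mean_reliability(fit, 20), 1.2 / 1.29)

    def test_limit_and_contaminated_fit(self):
        fit = _clean_two_level_fit()
        assert np.allclose(cluster_mean_reliability(fit, 1e12), 1.0, atol=1e-9)
        # a fit estimated on raw cluster means absorbs the within term; the
        # adjusted numerator must reproduce the same reliability
        contaminated = _clean_two_level_fit(psi_b=1.0 + 1.0 / 50,
                                            theta_b=0.2 + 0.8 / 50)
        contaminated.between_contaminated = True
        assert np.allclose(cluster_mean_reliability(contaminated, 50),
                           1.2 / 1.236)

    def test_simulated_cluster_mean_regression(self, big_within_ds):
        """Cross-check: R^B estimated from data matches the regression of
        cluster means on the exact between components."""
        fit = fit_two_level_measurement(big_within_ds, "x")
        r_b = cluster_mean_reliability(fit, fit.n1)
        side = big_within_ds.sidecar
        data = big_within_ds.data
        xbar = data.groupby("cluster_id")["x1"].mean()
        eta_b = side.groupby("cluster_id")["eta_x_b"].first()
        # R^B is var(between part)/var(cluster mean); the between part is
        # eta_b plus the cluster-level indicator residual
        resid_b = xbar - eta_b - side.groupby("cluster_id")["eta_x_w"].mean()
        between_part = eta_b + resid_b
        r_emp = between_part.var() / xbar.var()
        assert r_b[0] == pytest.approx(r_emp, abs=0.02)
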