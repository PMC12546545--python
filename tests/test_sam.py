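"""SAM core: moment assembly, Croon correction, structural estimation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mlsam.measurement import FactorModelFit
from mlsam.sam import (
    MomentMatrix,
    assemble_score_moments,
    croon_correct,
    estimate_paths,
    population_score_moments,
    product_label,
    product_variance,
    sam_estimate,
    sam_estimate_many,
)

PROD = product_label("x", "z")


def _fit(theta, psi=1.0, level="single"):
    return FactorModelFit(loadings=np.ones(3), theta=np.full(3, theta),
                          psi=psi, indicator_means=np.zeros(3), n=10 ** 6,
                          level=level)


class TestProductVariance:
    @pytest.mark.parametrize("va,vb,cab,expected",
                             [(1.0, 1.0, 0.25, 1.0625),
                              (1.0, 1.0, 0.0, 1.0),
                              (0.2, 1.0, 0.0, 0.2)])
    def test_closed_form(self, va, vb, cab, expected):
        assert product_variance(va, vb, cab) == pytest.approx(expected)

    def test_cauchy_schwarz_guard(self):
        with pytest.raises(ValueError):
            product_variance(1.0, 1.0, 1.1)

    def test_monte_carlo_oracle(self, rng):
        """Sample variance of the product of 1e6 centred bivariate normals
        matches var(a)var(b) + cov(a,b)^2 within 4 SE."""
        n = 10 ** 6
        ab = rng.multivariate_normal([0, 0], [[1, 0.25], [0.25, 1]], size=n)
        prod = ab[:, 0] * ab[:, 1]
        v = prod.var(ddof=1)
        # var of the sample variance via the fourth moment
        se = np.sqrt((np.mean((prod - prod.mean()) ** 4) - v ** 2) / n)
        assert v == pytest.approx(1.0625, abs=4 * se)


class TestAssembleScoreMoments:
    def test_plain_covariance_without_products(self, rng):
        scores = pd.DataFrame(rng.normal(size=(500, 2)), columns=["a", "b"])
        mm = assemble_score_moments(scores)
        pd.testing.assert_frame_equal(mm.cov, scores.cov())
        assert not mm.corrected

    def test_self_product_matches_squared_moments(self, rng):
        """var((a - abar)^2) ~ 2 var(a)^2 for normal scores."""
        a = rng.normal(0, 1.3, size=200000)
        mm = assemble_score_moments(pd.DataFrame({"a": a}),
                                    products=[("a", "a")])
        v = a.var(ddof=1)
        assert mm.cov.loc["a:a", "a:a"] == pytest.approx(2 * v ** 2, rel=0.03)

    def test_population_attenuation_identity(self):
        """Raw score covariances are validity-attenuated latent covariances:
        0.25 * 0.7895^2 = 0.1558 for the within X-Z block."""
        raw_w, _, _ = population_score_moments(design="within", n1=50)
        c = 3 / 3.8
        assert raw_w.cov.loc["x", "z"] == pytest.approx(0.25 * c * c, abs=1e-10)
        assert raw_w.cov.loc[PROD, "y"] == pytest.approx(
            c * c * (3 * 1.2425 / (3 * 1.2425 + 0.8)) * 0.2125, abs=1e-10)


class TestCroonCorrect:
    def test_population_within_block_recovered(self):
        raw_w, _, fits = population_score_moments(design="within", n1=50)
        corrected = croon_correct(raw_w, fits)
        assert corrected.corrected
        assert corrected.cov.loc["x", "z"] == pytest.approx(0.25, abs=1e-12)
        # interaction-outcome covariance attenuated by all three validities;
        # the outcome's validity is 3*1.2425/(3*1.2425+0.8) = 0.8233 on the
        # indicator-anchored scale (its latent variance is 1.2425, not 1)
        c = 3 / 3.8
        c_y = 3 * 1.2425 / (3 * 1.2425 + 0.8)
        assert raw_w.cov.loc[PROD, "y"] == pytest.approx(c * c * c_y * 0.2125,
                                                         abs=1e-10)
        assert corrected.cov.loc[PROD, "y"] == pytest.approx(0.2125, abs=1e-12)
        assert corrected.cov.loc[PROD, PROD] == pytest.approx(1.0625, abs=1e-12)

    def test_perfect_measurement_is_identity(self, rng):
        """With error-free indicators (validity 1) the correction leaves the
        latent covariances unchanged."""
        scores = pd.DataFrame(rng.multivariate_normal(
            [0, 0], [[1, 0.3], [0.3, 1]], size=4000), columns=["x", "z"])
        mm = assemble_score_moments(scores)
        fits = {"x": _fit(1e-12), "z": _fit(1e-12)}
        corrected = croon_correct(mm, fits)
        assert corrected.cov.loc["x", "z"] == pytest.approx(
            mm.cov.loc["x", "z"], abs=1e-6)

    def test_zero_forcing_switch(self):
        """With zero_product_covariances the product row keeps only its
        outcome covariance; first-order entries go to the normal-theory 0."""
        raw_w, _, fits = population_score_moments(design="within", n1=50)
        raw = raw_w
        raw.cov.loc[PROD, "x"] = raw.cov.loc["x", PROD] = 0.01  # sampling noise
        out = croon_correct(raw, fits, zero_product_covariances=True)
        assert out.cov.loc[PROD, "x"] == 0.0
        assert out.cov.loc[PROD, "y"] == pytest.approx(0.2125, abs=1e-12)

    def test_double_correction_rejected(self):
        raw_w, _, fits = population_score_moments(design="within", n1=50)
        corrected = croon_correct(raw_w, fits)
        with pytest.raises(ValueError):
            croon_correct(corrected, fits)

    def test_inadmissible_fit_yields_non_convergence(self):
        raw_w, _, fits = population_score_moments(design="within", n1=50)
        fits["x"].within.status = "boundary"
        out = croon_correct(raw_w, fits)
        assert out.status == "non_convergence"
        fits["x"].within.status = "converged"

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(vx=st.floats(0.3, 2.0), vz=st.floats(0.3, 2.0),
           r=st.floats(-0.8, 0.8), cy=st.floats(-0.3, 0.3),
           tx=st.floats(0.1, 1.0), tz=st.floats(0.1, 1.0))
    def test_correction_inverts_attenuation(self, vx, vz, r, cy, tx, tz):
        """croon_correct(attenuate(M)) == M for any admissible latent moment
        matrix: the correction is the exact inverse of score attenuation."""
        cxz = r * np.sqrt(vx * vz)
        vy = 1.0
        labels = ["x", "z", PROD, "y"]
        vprod = vx * vz + cxz ** 2
        M = pd.DataFrame(
            [[vx, cxz, 0.0, cy], [cxz, vz, 0.0, cy],
             [0.0, 0.0, vprod, 0.1 * vprod], [cy, cy, 0.1 * vprod, vy]],
            index=labels, columns=labels)
        fits = {"x": _fit(tx, vx), "z": _fit(tz, vz), "y": _fit(0.5, vy)}
        from mlsam.sam import _variable_info
        c = {k: _variable_info(k, f, "single").validity for k, f in fits.items()}
        att = M.copy()
        for a in labels:
            for b in labels:
                ca = c["x"] * c["z"] if a == PROD else c[a]
                cb = c["x"] * c["z"] if b == PROD else c[b]
                att.loc[a, b] = M.loc[a, b] * ca * cb
        # raw score variances: psi * c for first-order, score-product var
        for k in ("x", "z", "y"):
            att.loc[k, k] = fits[k].psi * c[k]
        att.loc[PROD, PROD] = (att.loc["x", "x"] * att.loc["z", "z"]
                               + att.loc["x", "z"] ** 2)
        raw = MomentMatrix(cov=att, means=pd.Series(0.0, index=labels),
                           level="single", n=10 ** 6)
        out = croon_correct(raw, fits)
        assert np.allclose(out.cov.to_numpy(), M.to_numpy(), atol=1e-9)


class TestEstimatePaths:
    def test_population_consistency_exact(self):
        """SAM-Croon on analytic population score moments returns the
        generating coefficients to machine precision; SAM-FS returns the
        closed-form attenuated values."""
        raw_w, _, fits = population_score_moments(design="within", n1=50)
        corrected = croon_correct(raw_w, fits)
        fit = estimate_paths(corrected, "y", ["x", "z", PROD])
        assert np.allclose(fit.coefficients.to_numpy(), [0.4, 0.4, 0.2],
                           atol=1e-12)
        assert fit.residual_variance == pytest.approx(0.8, abs=1e-12)

    def test_simple_regression_identity(self):
        labels = ["x", "y"]
        cov = pd.DataFrame([[2.0, 0.6], [0.6, 1.0]], index=labels,
                           columns=labels)
        mm = MomentMatrix(cov=cov, means=pd.Series([0.5, 1.0], index=labels),
                          level="single", n=100)
        fit = estimate_paths(mm, "y", ["x"])
        assert fit.coefficients["x"] == pytest.approx(0.3)
        assert fit.intercept == pytest.approx(1.0 - 0.3 * 0.5)

    def test_uncorrelated_outcome(self):
        labels = ["x", "z", "y"]
        cov = pd.DataFrame(np.diag([1.0, 1.0, 2.5]), index=labels,
                           columns=labels)
        mm = MomentMatrix(cov=cov, means=pd.Series(0.0, index=labels),
                          level="single", n=100)
        fit = estimate_paths(mm, "y", ["x", "z"])
        assert np.allclose(fit.coefficients.to_numpy(), 0.0)
        assert fit.residual_variance == pytest.approx(2.5)

    def test_singular_block_flags_non_convergence(self):
        labels = ["x", "z", "y"]
        cov = pd.DataFrame([[1.0, 1.0, 0.3], [1.0, 1.0, 0.3],
                            [0.3, 0.3, 1.0]], index=labels, columns=labels)
        mm = MomentMatrix(cov=cov, means=pd.Series(0.0, index=labels),
                          level="single", n=100)
        fit = estimate_paths(mm, "y", ["x", "z"])
        assert fit.status == "non_convergence"


class TestSamEstimate:
    def test_estimation_is_deterministic(self, within_ds):
        a = sam_estimate(within_ds, estimator="croon")
        b = sam_estimate(within_ds, estimator="croon")
        pd.testing.assert_series_equal(a.within.coefficients,
                                       b.within.coefficients)
        pd.testing.assert_series_equal(a.between.coefficients,
                                       b.between.coefficients)

    def test_croon_consistency_large_sample(self, big_within_ds):
        res = sam_estimate(big_within_ds, estimator="croon")
        assert res.converged
        assert res.within.coefficients[PROD] == pytest.approx(0.2, abs=0.04)
        assert res.within.coefficients["x"] == pytest.approx(0.4, abs=0.05)

    def test_fs_attenuates_croon_corrects(self):
        """Averaged over replications, the FS interaction estimate sits below
        the Croon estimate (attenuation removal), and below truth."""
        from mlsam.datagen import generate_mlsem
        fs_vals, croon_vals = [], []
        for rep in range(40):
            ds = generate_mlsem(design="within", n2=90, n1=50, seed=5000 + rep)
            res = sam_estimate_many(ds)
            if all(r.converged for r in res.values()):
                fs_vals.append(res["fs"].within.coefficients[PROD])
                croon_vals.append(res["croon"].within.coefficients[PROD])
        assert np.mean(fs_vals) < np.mean(croon_vals)
        assert np.mean(fs_vals) < 0.2 - 0.02  # systematic underestimation

    def test_design_mismatch_rejected(self, within_ds):
        with pytest.raises(ValueError):
            sam_estimate(within_ds, design="between")

    @pytest.mark.parametrize("design", ["cross", "between"])
    def test_other_designs_population_consistency(self, design):
        raw_w, raw_b, fits = population_score_moments(design=design, n1=50)
        w_corr = croon_correct(raw_w, fits) if raw_w is not None else None
        b_corr = croon_correct(raw_b, fits, n1=50, within_corrected=w_corr)
        if design == "cross":
            fw = estimate_paths(w_corr, "y", ["x", "z", PROD])
            assert np.allclose(fw.coefficients.to_numpy(), [0.4, 0.4, 0.2],
                               atol=1e-12)
            fb = estimate_paths(b_corr, "y", ["x", "z"])
            assert np.allclose(fb.coefficients.to_numpy(), [0.4, 0.4],
                               atol=1e-12)
        else:
            fb = estimate_paths(b_corr, "y", ["x", "z", PROD])
            assert np.allclose(fb.coefficients.to_numpy(), [0.4, 0.4, 0.2],
                               atol=1e-12)
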