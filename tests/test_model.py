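import numpy as np
import pandas as pd
import pytest

from rnfltex.model import (
    RnflRegressor,
    fit_eq4,
    predict_eq4,
    spearman_by_image,
    spearman_pooled,
    within_eye_error,
)

from oracles import spearman_sort_oracle

# published coefficients used as a wiring reference for the polynomial
REFERENCE_BETA = np.array([80.53, 24.40, -3.87, 3.30, 0.29, -3.41])


def _paired(rng, n_eyes=8, n_per_eye=20, noise=5.0, beta=None):
    """Simulate a paired dataset straight from the quadratic model."""
    beta = REFERENCE_BETA if beta is None else np.asarray(beta, float)
    rows = []
    for e in range(n_eyes):
        mu = rng.normal(0.0, 1.0, n_per_eye)
        sigma = rng.normal(0.0, 1.0, n_per_eye)
        y = predict_eq4(beta, mu, sigma) + rng.normal(0, noise, n_per_eye)
        for i in range(n_per_eye):
            rows.append({
                "eye_id": f"eye{e}", "roi_id": i,
                "mu_GB": mu[i], "sigma_GB": sigma[i], "thickness_um": y[i],
            })
    return pd.DataFrame(rows)


class TestSpearman:
    def test_feature_equal_to_thickness_gives_unity_per_eye(self, rng):
        df = _paired(rng)
        df["self"] = df["thickness_um"]
        table, summary, skipped = spearman_by_image(df, "self")
        assert not skipped
        assert np.allclose(table.r_s, 1.0)
        assert summary["mean"] == pytest.approx(1.0)

    def test_antimonotone_pooled_is_minus_one(self, rng):
        df = _paired(rng)
        df["neg"] = -df["thickness_um"]
        r, p = spearman_pooled(df, "neg")
        assert r == pytest.approx(-1.0)
        assert p < 1e-10

    def test_permuted_feature_near_zero(self, rng):
        df = _paired(rng, n_eyes=10, n_per_eye=40)
        df["perm"] = rng.permutation(df["thickness_um"].to_numpy())
        _, summary, _ = spearman_by_image(df, "perm")
        # null sd of R_S per eye is ~1/sqrt(n-1) ≈ 0.16; across-eye mean
        # shrinks by sqrt(10); allow 4 null sd
        assert abs(summary["mean"]) < 4 * 0.16 / np.sqrt(10)

    def test_pooled_matches_rank_then_pearson_oracle(self, rng):
        df = _paired(rng, n_eyes=3, n_per_eye=15)
        df.loc[:5, "mu_GB"] = 0.5  # inject ties to exercise midranks
        r, _ = spearman_pooled(df, "mu_GB")
        want = spearman_sort_oracle(df.mu_GB.tolist(), df.thickness_um.tolist())
        assert r == pytest.approx(want, abs=1e-12)

    def test_invariant_under_monotone_transform(self, rng):
        df = _paired(rng, n_eyes=2)
        df["pos"] = df["mu_GB"] - df["mu_GB"].min() + 1.0
        r0, _ = spearman_pooled(df, "pos")
        df["logpos"] = np.log(df["pos"])
        r1, _ = spearman_pooled(df, "logpos")
        assert r0 == pytest.approx(r1, abs=1e-12)

    def test_small_eyes_skipped_and_reported(self, rng):
        df = _paired(rng, n_eyes=3)
        extra = df.iloc[:3].copy()
        extra["eye_id"] = "tiny"
        table, _, skipped = spearman_by_image(pd.concat([df, extra]), "mu_GB")
        assert ("tiny", "only 3 rows (< 5)") in skipped
        assert "tiny" not in set(table.eye_id)

    def test_constant_feature_flagged(self, rng):
        df = _paired(rng, n_eyes=2)
        df.loc[df.eye_id == "eye0", "mu_GB"] = 7.0
        _, _, skipped = spearman_by_image(df, "mu_GB")
        assert skipped and skipped[0][0] == "eye0"


class TestPredictEq4:
    def test_reference_beta_at_normalized_origin(self):
        assert predict_eq4(REFERENCE_BETA, 0.0, 0.0) == 80.53

    def test_zero_beta_is_identically_zero(self, rng):
        z = np.zeros(6)
        pts = rng.normal(size=(10, 2))
        assert np.all(predict_eq4(z, pts[:, 0], pts[:, 1]) == 0.0)

    def test_matches_term_by_term_hand_evaluation(self, rng):
        beta = rng.normal(size=6)
        for mu, sigma in rng.normal(size=(20, 2)):
            hand = (beta[0] + beta[1] * mu + beta[2] * sigma
                    + beta[3] * mu * sigma + beta[4] * mu**2 + beta[5] * sigma**2)
            assert predict_eq4(beta, mu, sigma) == pytest.approx(hand, abs=1e-12)

    def test_pure_function_repeated_calls_identical(self):
        a = predict_eq4(REFERENCE_BETA, 0.3, -1.2)
        b = predict_eq4(REFERENCE_BETA, 0.3, -1.2)
        assert a == b


class TestRnflRegressor:
    def test_noiseless_recovery_and_perfect_fit(self, rng):
        df = _paired(rng, noise=0.0)
        m = fit_eq4(df, normalization="none")
        assert np.abs(m.beta_ - REFERENCE_BETA).max() <= 1e-8
        assert m.mae_ == pytest.approx(0.0, abs=1e-8)
        assert m.r2_ == pytest.approx(1.0, abs=1e-12)

    def test_matches_independent_normal_equations_solve(self, rng):
        df = _paired(rng, noise=4.0)
        m = fit_eq4(df, normalization="none")
        mu, sg = df.mu_GB.to_numpy(), df.sigma_GB.to_numpy()
        D = np.column_stack([np.ones_like(mu), mu, sg, mu * sg, mu**2, sg**2])
        y = df.thickness_um.to_numpy()
        beta_ne = np.linalg.solve(D.T @ D, D.T @ y)
        np.testing.assert_allclose(m.beta_, beta_ne, atol=1e-8)

    def test_residuals_orthogonal_to_design_columns(self, rng):
        df = _paired(rng, noise=6.0)
        m = fit_eq4(df)
        X = df[["mu_GB", "sigma_GB"]].to_numpy()
        resid = df.thickness_um.to_numpy() - m.predict(X)
        Z = (X - m.norm_center_) / m.norm_scale_
        D = np.column_stack([np.ones(len(Z)), Z[:, 0], Z[:, 1],
                             Z[:, 0] * Z[:, 1], Z[:, 0] ** 2, Z[:, 1] ** 2])
        np.testing.assert_allclose(D.T @ resid, 0.0, atol=1e-7)

    def test_iterative_method_reaches_linear_optimum(self, rng):
        df = _paired(rng, noise=5.0)
        lin = fit_eq4(df, method="linear")
        itr = fit_eq4(df, method="iterative")
        np.testing.assert_allclose(itr.beta_, lin.beta_, atol=1e-7)

    def test_pure_noise_response_has_low_r2(self, rng):
        df = _paired(rng, n_eyes=10, n_per_eye=40)
        df["thickness_um"] = rng.normal(80.0, 10.0, len(df))
        m = fit_eq4(df)
        assert m.r2_ < 0.1
        # slope-like coefficients stay within ~3 standard errors of zero
        assert np.all(np.abs(m.beta_[1:]) < 4 * m.beta_se_[1:])

    def test_coefficient_rmse_shrinks_with_sample_size(self):
        sizes = (50, 200, 800)
        rmse = []
        for n in sizes:
            errs = []
            for seed in range(8):
                rng = np.random.default_rng(1000 + seed)
                mu, sigma = rng.normal(size=n), rng.normal(size=n)
                y = predict_eq4(REFERENCE_BETA, mu, sigma) + rng.normal(0, 8.0, n)
                m = RnflRegressor(normalization="none").fit(
                    np.column_stack([mu, sigma]), y)
                errs.append(np.mean((m.beta_ - REFERENCE_BETA) ** 2))
            rmse.append(np.sqrt(np.mean(errs)))
        assert rmse[0] > rmse[1] > rmse[2]
        # ~1/sqrt(n) scaling: 16x data -> ~4x smaller error, allow slack
        assert rmse[0] / rmse[2] > 2.0

    def test_constant_predictor_rejected(self, rng):
        df = _paired(rng)
        df["sigma_GB"] = 3.0
        with pytest.raises(ValueError, match="constant|singular"):
            fit_eq4(df)

    def test_too_few_rows_rejected(self, rng):
        df = _paired(rng, n_eyes=1, n_per_eye=10)
        with pytest.raises(ValueError, match="12"):
            fit_eq4(df)

    def test_zscore_normalization_stored_and_used(self, rng):
        df = _paired(rng, noise=2.0)
        m = fit_eq4(df, normalization="zscore")
        X = df[["mu_GB", "sigma_GB"]].to_numpy()
        np.testing.assert_allclose(m.norm_center_, X.mean(axis=0))
        np.testing.assert_allclose(m.norm_scale_, X.std(axis=0))
        # predicting at the training mean equals the intercept evaluation
        assert m.predict(m.norm_center_[None, :])[0] == pytest.approx(m.beta_[0])

    def test_sklearn_params_roundtrip(self):
        m = RnflRegressor(normalization="minmax", ci_level=0.9)
        assert RnflRegressor(**m.get_params()).get_params() == m.get_params()

    def test_diagnostics_present_after_fit(self, rng):
        m = fit_eq4(_paired(rng, noise=5.0))
        assert m.mae_ > 0 and m.mci_ > 0 and 0 < m.r2_ <= 1
        d = m.to_dict()
        assert set(d) >= {"beta", "norm_center", "norm_scale", "mae", "mci", "r2"}


class TestWithinEyeError:
    def test_perfect_model_gives_zero_medians(self, rng):
        df = _paired(rng, noise=0.0)
        m = fit_eq4(df, normalization="none")
        table, mean, sd = within_eye_error(df, m)
        assert np.allclose(table.median_rel_error, 0.0, atol=1e-10)
        assert mean == pytest.approx(0.0, abs=1e-10)

    def test_constant_multiplicative_bias_closed_form(self, rng):
        # if ŷ = 1.1·y then |ŷ−y|/y = 0.1 for every sample... but here the
        # *truth* is 1.1× the model's output, so the relative error is
        # 0.1/1.1 ≈ 9.09% relative to the true y
        df = _paired(rng, noise=0.0)
        m = fit_eq4(df, normalization="none")
        df = df.assign(thickness_um=df.thickness_um * 1.1)
        # guard against negative thickness flipping relative errors
        df = df[df.thickness_um > 1.0]
        table, mean, _ = within_eye_error(df, m)
        np.testing.assert_allclose(table.median_rel_error, 0.1 / 1.1, atol=1e-9)
        assert mean == pytest.approx(0.1 / 1.1, abs=1e-9)

    def test_single_roi_eye_rejected(self, rng):
        df = _paired(rng, noise=0.0)
        df = pd.concat([df, df.iloc[[0]].assign(eye_id="lonely")])
        m = fit_eq4(df, normalization="none")
        with pytest.raises(ValueError, match="fewer than 2"):
            within_eye_error(df, m)
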