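"""Feature encoding and the prediction-model family: clinical baseline,
C+T polygenic score, joint regression and LASSO."""

import numpy as np
import pandas as pd
import pytest

from prsport import models
from prsport.evaluate import r_squared
from conftest import make_gm


def clinical_frame(rng, n):
    co = pd.DataFrame(
        {
            "age": rng.uniform(40, 70, n),
            "sex": rng.integers(0, 2, n),
            "height": rng.normal(170, 8, n),
            "weight": rng.normal(75, 12, n),
            "smoking": rng.integers(0, 2, n),
            "drinking": rng.integers(0, 2, n),
            "exercise": rng.integers(0, 2, n),
        }
    )
    co.insert(1, "age2", co["age"] ** 2)
    for j in range(10):
        co[f"pc{j + 1}"] = rng.standard_normal(n)
    return co


class TestEncoding:
    def test_snp_one_hot_rows(self, rng):
        gm = make_gm(np.array([[0.0], [1.0], [2.0]]))
        co = clinical_frame(rng, 3)
        spec = models.EncodingSpec.fit(co, gm, ["v0"])
        X = models.encode_features(co, gm, spec)
        snp = X[:, -3:]
        assert np.array_equal(snp, [[1, 0, 0], [0, 1, 0], [0, 0, 1]])

    def test_eighteen_clinical_features(self, rng):
        co = clinical_frame(rng, 50)
        spec = models.EncodingSpec.fit(co)
        assert spec.n_clinical == 18  # 4 continuous + 10 PCs + 4 binary

    def test_constant_covariate_encodes_to_zeros(self, rng):
        co = clinical_frame(rng, 20)
        co["height"] = 170.0
        spec = models.EncodingSpec.fit(co)
        X = models.encode_features(co, None, spec)
        j = list(spec.continuous).index("height")
        assert np.all(X[:, j] == 0.0)

    def test_training_reencoding_is_standardized(self, rng):
        co = clinical_frame(rng, 200)
        spec = models.EncodingSpec.fit(co)
        X = models.encode_features(co, None, spec)
        k = len(spec.continuous)
        assert np.all(np.abs(X[:, :k].mean(axis=0)) < 1e-10)
        assert np.allclose(X[:, :k].std(axis=0), 1.0, atol=1e-10)

    def test_unseen_level_warns_and_zeroes(self, rng):
        co = clinical_frame(rng, 30)
        spec = models.EncodingSpec.fit(co)
        co2 = co.copy()
        co2.loc[0, "smoking"] = 7
        with pytest.warns(UserWarning, match="unseen"):
            X = models.encode_features(co2, None, spec)
        names = spec.feature_names
        j = names.index("smoking=1")
        assert X[0, j] == 0.0


class TestClinicalModel:
    def test_exact_linear_target_fits_perfectly(self, rng):
        co = clinical_frame(rng, 300)
        spec = models.EncodingSpec.fit(co)
        X = models.encode_features(co, None, spec)
        w = rng.standard_normal(X.shape[1])
        y = 1.5 + X @ w
        model = models.fit_clinical_model(co, y, encoding=spec)
        assert r_squared(y, model.predict(co)) > 1 - 1e-10

    def test_null_outcome_out_of_sample_r2_near_zero(self, rng):
        co = clinical_frame(rng, 5000)
        y = rng.standard_normal(5000)
        model = models.fit_clinical_model(co.iloc[:2500], y[:2500])
        r2 = r_squared(y[2500:], model.predict(co.iloc[2500:]))
        assert abs(r2) < 0.02

    def test_duplicate_feature_rejected(self, rng):
        co = clinical_frame(rng, 100)
        co["weight"] = co["height"]  # exact collinearity
        with pytest.raises(np.linalg.LinAlgError):
            models.fit_clinical_model(co, rng.standard_normal(100))


class TestPRS:
    def test_single_snp_scores(self, rng):
        gm = make_gm(np.array([[0.0], [1.0], [2.0]]))
        ss = pd.DataFrame(
            {"CHR": ["1"], "POS": [1], "ID": ["v0"], "A1": ["G"], "A2": ["A"],
             "BETA": [0.1], "SE": [0.01], "STAT": [10.0], "P": [1e-10],
             "N": [100], "MAF": [0.3]}
        )
        scores, recipe, n = models.compute_prs(ss, gm, 5e-8, ["v0"])
        assert np.allclose(scores, [0.0, 0.1, 0.2])
        assert n == 1

    def test_no_passing_snps_warns_and_zeroes(self, rng):
        gm = make_gm(rng.integers(0, 3, (10, 2)).astype(float))
        ss = pd.DataFrame(
            {"CHR": ["1"] * 2, "POS": [1, 5001], "ID": ["v0", "v1"],
             "A1": ["G"] * 2, "A2": ["A"] * 2, "BETA": [0.1, 0.2],
             "SE": [0.01] * 2, "STAT": [1.0] * 2, "P": [0.5, 0.9],
             "N": [10] * 2, "MAF": [0.3] * 2}
        )
        with pytest.warns(UserWarning, match="zero"):
            scores, _, n = models.compute_prs(ss, gm, 5e-8, ["v0", "v1"])
        assert n == 0 and np.all(scores == 0)

    def test_matches_brute_force_summation(self, rng):
        n, m = 200, 50
        g = rng.integers(0, 3, (n, m)).astype(float)
        gm = make_gm(g)
        betas = rng.standard_normal(m) * 0.05
        ss = pd.DataFrame(
            {"CHR": ["1"] * m, "POS": gm.variants["pos"],
             "ID": gm.variants["id"], "A1": ["G"] * m, "A2": ["A"] * m,
             "BETA": betas, "SE": [0.01] * m, "STAT": [5.0] * m,
             "P": [1e-9] * m, "N": [n] * m, "MAF": [0.3] * m}
        )
        scores, _, _ = models.compute_prs(ss, gm, 5e-8, list(gm.variants["id"]))
        brute = np.array([sum(betas[j] * g[i, j] for j in range(m))
                          for i in range(n)])
        np.testing.assert_allclose(scores, brute, atol=1e-12)


class TestCTPRSModel:
    def test_prs_equal_to_outcome_dominates(self, rng):
        co = clinical_frame(rng, 400)
        y = rng.standard_normal(400)
        model = models.fit_ct_prs_model(y, co, y)
        assert model.weights[1] == pytest.approx(1.0, abs=1e-6)
        assert r_squared(y, model.predict_from_prs(y, co)) > 0.999

    def test_constant_prs_reduces_to_clinical(self, rng):
        co = clinical_frame(rng, 400)
        spec = models.EncodingSpec.fit(co)
        X = models.encode_features(co, None, spec)
        y = X @ rng.standard_normal(X.shape[1]) + rng.standard_normal(400)
        prs = np.full(400, 3.0)
        m_prs = models.fit_ct_prs_model(prs, co, y, encoding=spec)
        m_clin = models.fit_clinical_model(co, y, encoding=spec)
        r2a = r_squared(y, m_prs.predict_from_prs(prs, co))
        r2b = r_squared(y, m_clin.predict(co))
        assert abs(r2a - r2b) < 1e-6

    def test_permutation_invariance(self, rng):
        co = clinical_frame(rng, 300)
        y = rng.standard_normal(300)
        prs = rng.standard_normal(300)
        m1 = models.fit_ct_prs_model(prs, co, y)
        perm = rng.permutation(300)
        m2 = models.fit_ct_prs_model(prs[perm],
                                     co.iloc[perm].reset_index(drop=True),
                                     y[perm])
        np.testing.assert_allclose(m1.weights, m2.weights, atol=1e-10)


class TestLasso:
    def test_lambda_zero_matches_ols(self, rng):
        n, p = 300, 10
        X = rng.standard_normal((n, p))
        y = X @ (rng.standard_normal(p) * 0.3) + rng.standard_normal(n)
        b0, b, _ = models._lasso_cd(X, y, 0.0, np.ones(p, bool), 1e-8)
        coef, *_ = np.linalg.lstsq(np.column_stack([np.ones(n), X]), y,
                                   rcond=None)
        np.testing.assert_allclose(b, coef[1:], atol=1e-4)

    def test_lambda_max_zeroes_everything(self, rng):
        n, p = 200, 8
        X = rng.standard_normal((n, p))
        X = (X - X.mean(0)) / X.std(0)
        y = X @ rng.standard_normal(p) + rng.standard_normal(n)
        pen = np.ones(p, bool)
        lmax = models.lasso_lambda_max(X, y, pen)
        _, b, _ = models._lasso_cd(X, y, lmax * 1.001, pen, 1e-10)
        assert np.all(b == 0.0)

    def test_single_predictor_soft_threshold_closed_form(self, rng):
        n = 500
        x = rng.standard_normal(n)
        x = (x - x.mean()) / x.std()
        y = 0.4 * x + rng.standard_normal(n)
        rho = x @ (y - y.mean()) / n
        lam = abs(rho) / 3
        _, b, _ = models._lasso_cd(x[:, None], y, lam, np.array([True]), 1e-12)
        expected = np.sign(rho) * max(abs(rho) - lam, 0.0)
        assert b[0] == pytest.approx(expected, abs=1e-8)

    def test_negative_lambda_rejected(self, rng):
        co = clinical_frame(rng, 50)
        spec = models.EncodingSpec.fit(co)
        with pytest.raises(ValueError):
            models.fit_lasso(co, None, rng.standard_normal(50), -0.1, spec)

    def test_objective_decreases_over_sweeps(self, rng):
        n, p = 200, 15
        X = rng.standard_normal((n, p))
        y = X @ rng.standard_normal(p) + rng.standard_normal(n)
        pen = np.ones(p, bool)
        lam = 0.05

        def objective(b0, b):
            r = y - b0 - X @ b
            return 0.5 * np.mean(r**2) + lam * np.abs(b[pen]).sum()

        prev = np.inf
        for sweeps in (1, 2, 4, 8, 16):
            b0, b, _ = models._lasso_cd(X, y, lam, pen, 0.0, max_sweeps=sweeps)
            cur = objective(b0, b)
            assert cur <= prev + 1e-12
            prev = cur

    def test_optimizers_agree_on_predictions(self):
        # coordinate descent (reference) vs mini-batch Adam at matched lambda
        rng = np.random.default_rng(909)
        n, m = 500, 15
        g = rng.integers(0, 3, (n, m)).astype(float)
        gm = make_gm(g)
        co = clinical_frame(rng, n)
        spec = models.EncodingSpec.fit(co, gm, list(gm.variants["id"][:10]))
        Xtmp = models.encode_features(co, gm, spec)
        w = rng.standard_normal(Xtmp.shape[1]) * 0.2
        y = Xtmp @ w + 0.5 * rng.standard_normal(n)
        lam = 0.01
        cfg_cd = models.TrainingConfig(optimizer="coordinate_descent")
        cfg_adam = models.TrainingConfig(optimizer="mbgd_adam", epochs=800,
                                         learning_rate=3e-3, seed=5)
        m_cd = models.fit_lasso(co, gm, y, lam, spec, cfg_cd)
        m_ad = models.fit_lasso(co, gm, y, lam, spec, cfg_adam)
        a = m_cd.predict(co, gm)
        b = m_ad.predict(co, gm)
        rmse = np.sqrt(np.mean((a - b) ** 2))
        assert rmse < 0.05 * y.std()

    def test_prediction_invariant_to_sample_order(self, rng):
        n, m = 150, 5
        g = rng.integers(0, 3, (n, m)).astype(float)
        gm = make_gm(g)
        co = clinical_frame(rng, n)
        spec = models.EncodingSpec.fit(co, gm, list(gm.variants["id"]))
        y = rng.standard_normal(n)
        model = models.fit_lasso(co, gm, y, 0.02, spec)
        perm = rng.permutation(n)
        gm_p = gm.subset_samples(perm)
        co_p = co.iloc[perm].reset_index(drop=True)
        np.testing.assert_allclose(model.predict(co_p, gm_p),
                                   model.predict(co, gm)[perm], atol=1e-12)
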