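import numpy as np
import pytest
from scipy.linalg import subspace_angles
from scipy.optimize import approx_fprime

from emgsel.classifier import evaluate_cv
from emgsel.dimred import (
    ParameterError,
    SingularScatterError,
    _gplvm_obj_grad,
    evaluate_reduction,
    gplvm_fit,
    lasso_select,
    lda_fit,
    pca_fit,
    ppca_em,
    relieff,
)
from emgsel.features import extract_features
from emgsel.preprocess import segment
from emgsel.synth import SynthConfig, generate_recording

from .conftest import make_feature_matrix


def _factor_data(n=500, p=10, d=2, sigma=0.1, seed=0):
    rng = np.random.default_rng(seed)
    W0 = rng.standard_normal((p, d))
    z = rng.standard_normal((n, d))
    X = z @ W0.T + sigma * rng.standard_normal((n, p))
    return X, W0


class TestPCA:
    def test_degenerate_covariance(self):
        rng = np.random.default_rng(0)
        X = np.zeros((100, 2))
        X[:, 0] = rng.standard_normal(100)
        emb = pca_fit(X, 2)
        load = emb.diagnostics["components"][0]
        assert abs(abs(load[0]) - 1.0) < 1e-10
        assert emb.diagnostics["explained_variance_ratio"][1] < 1e-10

    def test_full_rank_reconstruction(self):
        X, _ = _factor_data(n=50, p=6, d=3, sigma=0.5, seed=1)
        emb = pca_fit(X, 6)
        Xhat = emb.latent @ emb.diagnostics["components"] + emb.diagnostics["mean"]
        np.testing.assert_allclose(Xhat, X, atol=1e-8)

    def test_projection_variance_equals_top_eigenvalues(self):
        X, _ = _factor_data(n=100, p=10, d=10, sigma=1.0, seed=2)
        emb = pca_fit(X, 3)
        Xc = X - X.mean(axis=0)
        evals = np.sort(np.linalg.eigvalsh(Xc.T @ Xc / (len(X) - 1)))[::-1]
        proj_var = emb.latent.var(axis=0, ddof=1)
        np.testing.assert_allclose(proj_var, evals[:3], rtol=1e-8)

    def test_d_too_large_raises(self):
        with pytest.raises(ParameterError):
            pca_fit(np.zeros((5, 3)), 4)


class TestLDA:
    def test_duplicate_columns_raise_singular_scatter(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((60, 4))
        X = np.c_[X, X[:, 1]]            # exact collinearity, like IAV vs IEMG
        y = np.repeat([0, 1, 2], 20)
        with pytest.raises(SingularScatterError) as exc:
            lda_fit(X, y, 2)
        assert 1 in exc.value.collinear_columns
        assert 4 in exc.value.collinear_columns

    def test_two_spherical_classes_recover_separation_axis(self):
        rng = np.random.default_rng(4)
        X = rng.standard_normal((1000, 5))
        y = np.repeat([0, 1], 500)
        X[y == 1, 0] += 5.0
        emb = lda_fit(X, y, 1)
        w = emb.diagnostics["directions"][:, 0]
        cos = abs(w[0]) / np.linalg.norm(w)
        assert cos > 0.99

    def test_d_above_rank_bound_raises(self):
        with pytest.raises(ParameterError):
            lda_fit(np.zeros((10, 3)), np.repeat([0, 1], 5), 2)

    def test_ridge_rescues_singular_scatter(self):
        rng = np.random.default_rng(5)
        X = rng.standard_normal((60, 3))
        X = np.c_[X, X[:, 0]]
        y = np.repeat([0, 1], 30)
        emb = lda_fit(X, y, 1, ridge=1e-6)
        assert emb.latent.shape == (60, 1)


class TestPPCA:
    def test_parameter_recovery(self):
        X, W0 = _factor_data(n=500, p=10, d=2, sigma=0.1, seed=0)
        with pytest.warns(UserWarning):
            emb = ppca_em(X, 2, seed=0)
        sigma2 = emb.diagnostics["sigma2"]
        assert abs(sigma2 - 0.01) / 0.01 < 0.20
        angle = subspace_angles(emb.diagnostics["W"], W0).max()
        assert angle < 0.05

    def test_loglik_trace_monotone_on_seeded_datasets(self):
        for seed in range(10):
            X, _ = _factor_data(n=120, p=8, d=3, sigma=0.5, seed=seed)
            emb = ppca_em(X, 3, seed=seed, max_iter=200)
            ll = emb.diagnostics["loglik_trace"]
            assert np.all(np.diff(ll) >= -1e-9)

    def test_small_noise_limit_agrees_with_pca(self):
        X, _ = _factor_data(n=400, p=8, d=2, sigma=1e-4, seed=6)
        emb = ppca_em(X, 2, seed=0)
        pca = pca_fit(X, 2)
        angle = subspace_angles(emb.diagnostics["W"],
                                pca.diagnostics["components"].T).max()
        assert angle < 1e-2

    def test_transform_matches_posterior_mean(self):
        X, _ = _factor_data(n=100, p=6, d=2, sigma=0.3, seed=7)
        emb = ppca_em(X, 2, seed=0, max_iter=200)
        W, s2, mu = (emb.diagnostics[k] for k in ("W", "sigma2", "mu"))
        M = W.T @ W + s2 * np.eye(2)
        expected = np.linalg.solve(M, W.T @ (X[:5] - mu).T).T
        np.testing.assert_allclose(emb.transform(X[:5]), expected, atol=1e-10)

    def test_bad_dimension_raises(self):
        with pytest.raises(ParameterError):
            ppca_em(np.zeros((10, 4)), 4)


class TestGPLVM:
    def test_analytic_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(8)
        Y = rng.standard_normal((12, 4))
        n, q = 12, 2
        z0 = np.concatenate([rng.standard_normal(n * q) * 0.5,
                             np.log([1.0, 0.7, 0.3])])
        for kernel in ("rbf", "linear"):
            f = lambda z: _gplvm_obj_grad(z, n, q, Y, kernel)[0]
            g_num = approx_fprime(z0, f, 1e-6)
            g_ana = _gplvm_obj_grad(z0, n, q, Y, kernel)[1]
            np.testing.assert_allclose(g_ana, g_num, rtol=1e-4, atol=1e-4)

    def test_objective_never_worse_than_pca_init(self):
        for seed in range(10):
            X, _ = _factor_data(n=60, p=8, d=2, sigma=0.5, seed=seed)
            emb = gplvm_fit(X, 2, max_iter=50, seed=seed)
            assert emb.diagnostics["final_objective"] <= emb.diagnostics["init_objective"]
            tr = emb.diagnostics["objective_trace"]
            assert np.all(np.diff(tr) <= 1e-6)

    def test_linear_kernel_latent_matches_pca_subspace(self):
        X, _ = _factor_data(n=80, p=10, d=2, sigma=0.1, seed=9)
        emb = gplvm_fit(X, 2, kernel="linear", max_iter=100, seed=0)
        pca = pca_fit(X, 2)
        angle = subspace_angles(emb.latent, pca.latent).max()
        assert angle < 0.05

    def test_nonlinear_curve_beats_pca_reconstruction(self):
        wins = 0
        for seed in range(10):
            rng = np.random.default_rng(40 + seed)
            t = rng.uniform(0, 3 * np.pi, 80)
            Y = np.c_[t, np.sin(t), np.cos(t)] + 0.05 * rng.standard_normal((80, 3))
            emb = gplvm_fit(Y, 1, max_iter=150, seed=seed)
            # GP reconstruction of Y from the fitted 1-D latent
            from emgsel.dimred import _gplvm_kernel
            lat = emb.latent
            params = np.log([emb.diagnostics["sf2"], emb.diagnostics["ell2"],
                             emb.diagnostics["sn2"]])
            K, E, _ = _gplvm_kernel(lat, params, "rbf")
            Yc = Y - Y.mean(axis=0)
            Yhat = E @ np.linalg.solve(K, Yc)
            gp_err = np.mean((Yhat - Yc) ** 2)
            pca = pca_fit(Y, 1)
            Ypca = pca.latent @ pca.diagnostics["components"]
            pca_err = np.mean((Ypca - Yc) ** 2)
            wins += gp_err < pca_err
        assert wins >= 8

    def test_too_many_rows_guarded(self):
        with pytest.raises(ParameterError, match="max_points"):
            gplvm_fit(np.zeros((50, 4)), 2, max_points=40)


class TestReliefF:
    def test_planted_relevance_wins_every_seed(self):
        for seed in range(20):
            rng = np.random.default_rng(seed)
            y = np.repeat([0, 1, 2], 30)
            X = rng.standard_normal((90, 6))
            X[:, 2] = y + 0.05 * rng.standard_normal(90)
            mask = relieff(X, y, n_select=1, seed=seed)
            assert mask.weights[2] > max(w for i, w in enumerate(mask.weights) if i != 2)

    def test_duplicated_informative_features_share_weight(self):
        rng = np.random.default_rng(10)
        y = np.repeat([0, 1], 40)
        info = y + 0.05 * rng.standard_normal(80)
        X = np.c_[info, info, rng.standard_normal((80, 3))]
        mask = relieff(X, y, n_select=2)
        w0, w1 = mask.weights[0], mask.weights[1]
        assert abs(w0 - w1) / max(abs(w0), abs(w1)) < 0.10

    def test_select_all_columns(self):
        rng = np.random.default_rng(11)
        X = rng.standard_normal((60, 4))
        y = np.repeat([0, 1], 30)
        mask = relieff(X, y, n_select=4)
        np.testing.assert_array_equal(mask.selected, np.arange(4))

    def test_small_class_raises(self):
        X = np.zeros((12, 3))
        y = np.repeat([0, 1], 6)
        with pytest.raises(ParameterError):
            relieff(X, y, k_neighbors=10)


class TestLasso:
    def test_planted_single_column_recovery(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            y = np.repeat([0, 1], 30)
            X = rng.standard_normal((60, 21))
            X[:, 7] = (y - 0.5) * 2 + 0.05 * rng.standard_normal(60)
            mask = lasso_select(X, y, lambda_grid=[2.0, 5.0, 10.0], seed=seed)
            hits += list(mask.selected) == [7]
        assert hits >= 18

    def test_weak_penalty_selects_everything(self):
        rng = np.random.default_rng(12)
        X = rng.standard_normal((80, 5))
        y = (X[:, 0] + 0.3 * rng.standard_normal(80) > 0).astype(int)
        mask = lasso_select(X, y, lambda_grid=[1e-6], seed=0)
        assert len(mask.selected) == 5

    def test_overwhelming_penalty_triggers_fallback_warning(self):
        rng = np.random.default_rng(13)
        X = rng.standard_normal((60, 4))
        y = np.repeat([0, 1], 30)
        with pytest.warns(UserWarning):
            lasso_select(X, y, lambda_grid=[1e9], seed=0)


class TestEvaluateReduction:
    FEATURES = ("RMS", "MAV", "IEMG", "WL", "STD", "DAMV", "DASDV", "MFL")

    @pytest.fixture(scope="class")
    def emg_fm(self):
        cfg = SynthConfig(n_channels=6, n_reps=1, rep_duration=5.0,
                          rest_duration=0.5, seed=31, baseline_sd=0.3)
        rec = generate_recording(cfg)
        return extract_features(segment(rec), self.FEATURES)

    def test_identity_reduction_reproduces_plain_cv(self, emg_fm, fast_ann):
        rep_none, _ = evaluate_reduction(emg_fm, "none", None, fast_ann, seed=0)
        rep_plain = evaluate_cv(emg_fm.values, emg_fm.labels, fast_ann, seed=0)
        assert rep_none.fold_accuracies == pytest.approx(rep_plain.fold_accuracies)

    def test_full_rank_pca_matches_identity_within_a_point(self, emg_fm, fast_ann):
        rep_none, _ = evaluate_reduction(emg_fm, "none", None, fast_ann, seed=0)
        rep_pca, _ = evaluate_reduction(
            emg_fm, "pca", {"d": emg_fm.values.shape[1]}, fast_ann, seed=0)
        assert abs(rep_pca.mean_accuracy - rep_none.mean_accuracy) <= 0.01 + 1e-9

    def test_unknown_method_raises(self, emg_fm, fast_ann):
        with pytest.raises(ParameterError):
            evaluate_reduction(emg_fm, "umap", None, fast_ann)

    def test_all_methods_close_to_identity_accuracy(self, fast_ann):
        """No reduction method moves accuracy by more than 5 points."""
        methods = ("pca", "ppca", "gplvm", "relieff", "lasso")
        for seed in (0, 1, 2):
            cfg = SynthConfig(n_channels=6, n_reps=2, rep_duration=5.0,
                              rest_duration=0.5, seed=50 + seed, baseline_sd=0.3)
            fm = extract_features(segment(generate_recording(cfg)), self.FEATURES)
            base, _ = evaluate_reduction(fm, "none", None, fast_ann, seed=seed)
            for method in methods:
                rep, _ = evaluate_reduction(fm, method, None, fast_ann, seed=seed)
                assert abs(rep.mean_accuracy - base.mean_accuracy) <= 0.05, (
                    f"{method} seed {seed}: {rep.mean_accuracy} vs "
                    f"{base.mean_accuracy}")

    def test_lda_fails_on_duplicate_catalog_features(self, fast_ann):
        cfg = SynthConfig(n_channels=3, n_reps=1, rep_duration=2.0,
                          rest_duration=0.5, seed=60, baseline_sd=0.5)
        fm = extract_features(segment(generate_recording(cfg)),
                              ("RMS", "IEMG", "IAV"))
        with pytest.raises(SingularScatterError):
            evaluate_reduction(fm, "lda", None, fast_ann, seed=0)
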