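"""Kernel construction, KRLS / kernel LMM, and the Monte Carlo CV engine."""

import numpy as np
import pandas as pd
import pytest

import omnikernel as ok
from omnikernel.datatypes import LayerKind, OmicsLayer
from omnikernel.kernels import (
    KRLS,
    KernelLMM,
    aggregate_kernels,
    build_cross_kernel,
    build_kernel,
    residualize_kernel,
)


class TestBuildKernel:
    def test_gaussian_unit_diagonal(self, rng):
        K = build_kernel(rng.normal(size=(20, 7)), "gaussian")
        np.testing.assert_allclose(np.diag(K.values), 1.0, atol=1e-12)
        assert K.eigenvalue_floor_ok()

    def test_gaussian_wide_bandwidth_limit(self, rng):
        K = build_kernel(rng.normal(size=(15, 4)), "gaussian", bandwidth=1e12)
        assert np.abs(K.values - 1.0).max() < 1e-6

    def test_linear_orthonormal_rows(self):
        K = build_kernel(np.eye(5), "linear", standardization=False)
        np.testing.assert_allclose(K.values, np.eye(5) / 5, atol=1e-12)

    def test_zero_variance_feature_dropped(self, rng):
        X = rng.normal(size=(12, 4))
        X[:, 2] = 3.0
        with pytest.warns(UserWarning, match="zero-variance"):
            K = build_kernel(X, "linear")
        assert K.values.shape == (12, 12)

    def test_empty_and_nonfinite_rejected(self, rng):
        with pytest.raises(ValueError):
            build_kernel(np.empty((5, 0)), "linear")
        X = rng.normal(size=(8, 3))
        X[0, 0] = np.nan
        with pytest.raises(ValueError):
            build_kernel(X, "linear")

    def test_cross_kernel_consistent_with_square(self, rng):
        X = rng.normal(size=(25, 6))
        K = build_kernel(pd.DataFrame(X), "gaussian")
        Kc = build_cross_kernel(
            pd.DataFrame(X[:5]), pd.DataFrame(X), "gaussian",
            bandwidth=K.bandwidth, standardization=K.standardization,
        )
        np.testing.assert_allclose(Kc, K.values[:5], atol=1e-12)


class TestResidualizeKernel:
    def test_intercept_only_double_centers(self, rng):
        K = build_kernel(rng.normal(size=(20, 5)), "linear")
        R = residualize_kernel(K, covariate_design=np.ones((20, 1)))
        assert np.abs(R.values.mean(axis=0)).max() < 1e-9
        assert np.abs(R.values.mean(axis=1)).max() < 1e-9

    def test_exact_covariate_kernel_annihilated(self, rng):
        C = np.column_stack([np.ones(30), rng.normal(size=(30, 2))])
        X = C @ rng.normal(size=(3, 10))  # features are exact covariate functions
        K = build_kernel(X, "linear", standardization=False)
        R = residualize_kernel(K, covariate_design=C)
        assert np.abs(R.values).max() < 1e-8

    def test_psd_preserved(self, rng):
        C = np.column_stack([np.ones(25), rng.normal(size=(25, 3))])
        K = build_kernel(rng.normal(size=(25, 40)), "gaussian")
        assert residualize_kernel(K, covariate_design=C).eigenvalue_floor_ok()


class TestAggregate:
    def _k(self, rng, p):
        return build_kernel(rng.normal(size=(18, p)), "linear")

    def test_single_and_duplicate(self, rng):
        K = self._k(rng, 9)
        agg1 = aggregate_kernels([K])
        np.testing.assert_allclose(agg1.values, K.trace_normalized().values)
        agg2 = aggregate_kernels([K, K])
        np.testing.assert_allclose(agg2.values, agg1.values)

    def test_mean_of_psd_is_psd(self, rng):
        ks = [self._k(rng, p) for p in (5, 30, 100)]
        assert aggregate_kernels(ks).eigenvalue_floor_ok()

    def test_sample_mismatch_rejected(self, rng):
        K1 = self._k(rng, 5)
        X = rng.normal(size=(18, 5))
        K2 = build_kernel(pd.DataFrame(X, index=[f"other{i}" for i in range(18)]), "linear")
        with pytest.raises(ValueError):
            aggregate_kernels([K1, K2])


class TestKRLS:
    def test_ridge_duality(self, rng):
        X = rng.normal(size=(50, 20))
        y = X[:, 0] * 0.5 + rng.normal(size=50)
        from sklearn.linear_model import Ridge

        K = build_kernel(X, "linear")
        Z = (X - X.mean(0)) / X.std(0)
        lam = 0.7
        m = KRLS(lambda_reg=lam).fit(K, y)
        oracle = Ridge(alpha=lam * Z.shape[1], fit_intercept=True).fit(Z, y)
        assert np.abs(m.predict(K.values) - oracle.predict(Z)).max() < 1e-6

    def test_loo_matches_bruteforce_refits(self, rng):
        n = 30
        X = rng.normal(size=(n, 5))
        y = X[:, 0] + rng.normal(size=n)
        K = build_kernel(X, "gaussian")
        m = KRLS(lambda_reg=0.3).fit(K, y)
        sse = 0.0
        for i in range(n):
            tr = np.delete(np.arange(n), i)
            mi = KRLS(lambda_reg=0.3).fit(K.values[np.ix_(tr, tr)], y[tr])
            sse += (y[i] - mi.predict(K.values[i, tr])) ** 2
        assert abs(m.loo_sse_ - sse) < 1e-6

    def test_tuned_lambda_locally_optimal(self, rng):
        X = rng.normal(size=(40, 8))
        y = X[:, 0] + rng.normal(size=40)
        m = KRLS().fit(build_kernel(X, "linear"), y)
        assert m.loo_sse_ <= m._loo_sse(0.5 * m.lambda_) + 1e-10
        assert m.loo_sse_ <= m._loo_sse(2.0 * m.lambda_) + 1e-10

    def test_infinite_penalty_predicts_mean(self, rng):
        X = rng.normal(size=(20, 4))
        y = rng.normal(size=20)
        K = build_kernel(X, "gaussian")
        m = KRLS(lambda_reg=1e12).fit(K, y)
        np.testing.assert_allclose(m.predict(K.values), y.mean(), atol=1e-9)

    def test_monotone_regularization_shrinks_predictions(self, rng):
        X = rng.normal(size=(40, 6))
        y = X[:, 0] + rng.normal(size=40)
        K = build_kernel(X, "linear")
        variances = [
            KRLS(lambda_reg=lam).fit(K, y).predict(K.values).var()
            for lam in (0.01, 0.1, 1.0, 10.0, 100.0)
        ]
        assert all(a >= b - 1e-12 for a, b in zip(variances, variances[1:]))

    def test_zero_cross_kernel_gives_intercept(self, rng):
        X = rng.normal(size=(15, 3))
        y = rng.normal(size=15)
        m = KRLS(lambda_reg=1.0).fit(build_kernel(X, "linear"), y)
        np.testing.assert_allclose(m.predict(np.zeros((4, 15))), m.intercept_)

    def test_sklearn_param_interface(self):
        m = KRLS(lambda_reg=2.0)
        assert m.get_params()["lambda_reg"] == 2.0
        m.set_params(lambda_reg=3.0)
        assert m.lambda_reg == 3.0


class TestKernelLMM:
    def test_blup_equals_krls_at_delta(self, rng):
        X = rng.normal(size=(35, 10))
        y = X[:, 0] + rng.normal(size=35)
        K = build_kernel(X, "gaussian")
        lmm = KernelLMM().fit(K, y)
        kr = KRLS(lambda_reg=lmm.delta_).fit(K, y)
        assert np.abs(lmm.predict(K.values) - kr.predict(K.values)).max() < 1e-8

    def test_null_heritability_small(self):
        hits = 0
        for seed in range(10):
            r = np.random.default_rng(seed)
            K = build_kernel(r.normal(size=(300, 50)), "linear").trace_normalized()
            y = r.normal(size=300)  # independent of the kernel structure
            hits += KernelLMM().fit(K, y).ratio_ < 0.1
        assert hits >= 9

    def test_structured_outcome_recovered(self, rng):
        K = build_kernel(rng.normal(size=(200, 40)), "gaussian").trace_normalized()
        d, U = np.linalg.eigh(K.values)
        u = U @ (np.sqrt(np.maximum(d, 0)) * rng.normal(size=200))
        y = u + 0.05 * rng.normal(size=200)
        assert KernelLMM().fit(K, y).ratio_ > 0.8


class TestAdjustedR2:
    def test_perfect_prediction(self, rng):
        y = rng.normal(size=30)
        assert ok.adjusted_r2(y, y) == pytest.approx(1.0)

    def test_closed_form_case(self, rng):
        # n=100, R^2=0.5, one predictor: 1 - 0.5*99/98
        for _ in range(200):
            y = rng.normal(size=100)
            x = y + rng.normal(size=100) * y.std()
            if abs(np.corrcoef(y, x)[0, 1] ** 2 - 0.5) < 1e-3:
                assert ok.adjusted_r2(y, x) == pytest.approx(1 - 0.5 * 99 / 98, abs=2e-3)
                return
        # deterministic fallback: build exact R^2 = 0.5 by Gram-Schmidt
        y = rng.normal(size=100)
        e = rng.normal(size=100)
        e -= e @ y / (y @ y) * y
        yc, ec = y - y.mean(), e - e.mean()
        x = yc / yc.std() + ec / ec.std()
        assert ok.adjusted_r2(y, x) == pytest.approx(1 - 0.5 * 99 / 98, abs=1e-3)

    def test_null_mean_near_zero(self, rng):
        vals = [ok.adjusted_r2(rng.normal(size=100), rng.normal(size=100)) for _ in range(1000)]
        assert abs(np.mean(vals)) < 0.02

    def test_zero_variance_warns(self, rng):
        with pytest.warns(UserWarning):
            assert ok.adjusted_r2(rng.normal(size=20), np.ones(20)) == 0.0


class TestFeatureSelection:
    def test_planted_feature_ranked_first(self, rng):
        n = 200
        y = rng.normal(size=n)
        M = rng.normal(size=(n, 50))
        M[:, 7] += 2.0 * y  # overwhelming effect
        layer = OmicsLayer(
            values=pd.DataFrame(M, columns=[f"cg{j:03d}" for j in range(50)]),
            kind=LayerKind.methylation_m,
        )
        sel = ok.select_top_features(layer, y, None, n_top=5, train_index=np.arange(n))
        assert sel[0] == "cg007"

    def test_selection_ignores_test_samples(self, small_cohort, srs, cov_design):
        layer = small_cohort.layers["cpg"]
        train = np.arange(100)
        sel1 = ok.select_top_features(layer, srs, cov_design, 30, train)
        corrupted = layer.values.copy()
        corrupted.iloc[100:] = 99.0 * np.random.default_rng(1).random(corrupted.iloc[100:].shape)
        layer2 = OmicsLayer(values=corrupted.clip(1e-6, 1 - 1e-6), kind=layer.kind)
        sel2 = ok.select_top_features(layer2, srs, cov_design, 30, train)
        assert list(sel1) == list(sel2)

    def test_n_top_capped_with_warning(self, small_cohort, srs, cov_design):
        with pytest.warns(UserWarning, match="all features"):
            sel = ok.select_top_features(
                small_cohort.layers["mirna"], srs, cov_design, 10**6, np.arange(150)
            )
        assert len(sel) == small_cohort.layers["mirna"].n_features


@pytest.fixture(scope="module")
def cv_args(small_cohort, srs, cov_design):
    return dict(
        layers=small_cohort.layers, outcome=srs, covariates=cov_design,
        feature_counts={"cpg": 40, "mrna": 30, "mirna": 20}, n_folds=4, seed=3,
    )


class TestMonteCarloCV:
    def test_deterministic_given_seed(self, cv_args):
        a = ok.monte_carlo_cv(**cv_args)
        b = ok.monte_carlo_cv(**cv_args)
        assert a.fold_r2 == b.fold_r2 and a.fold_seeds == b.fold_seeds

    def test_sample_order_invariance(self, cv_args, small_cohort, srs, cov_design, rng):
        base = ok.monte_carlo_cv(**cv_args)
        perm = rng.permutation(150)
        layers_p = {
            k: OmicsLayer(values=v.values.iloc[perm], kind=v.kind)
            for k, v in small_cohort.layers.items()
        }
        shuffled = ok.monte_carlo_cv(
            layers=layers_p, outcome=srs[perm], covariates=cov_design.iloc[perm],
            feature_counts=cv_args["feature_counts"], n_folds=4, seed=3,
        )
        np.testing.assert_allclose(base.fold_r2, shuffled.fold_r2, atol=1e-9)

    def test_fold_sizes(self, cv_args):
        rep = ok.monte_carlo_cv(**cv_args)
        for ix in rep.fold_test_indices:
            assert len(ix) == pytest.approx(0.25 * 150, abs=1)

    def test_signal_detected(self, cv_args):
        rep = ok.monte_carlo_cv(**cv_args)
        assert rep.mean_r2 > 0.05  # planted-signal cohort

    def test_empty_combination_rejected(self, cv_args):
        bad = dict(cv_args, combination=())
        with pytest.raises(ValueError):
            ok.monte_carlo_cv(**bad)


class TestTuneFeatureCounts:
    def test_grid_of_one_returns_it(self, small_cohort, srs, cov_design):
        best, curve = ok.tune_feature_counts(
            {"mirna": small_cohort.layers["mirna"]}, srs, cov_design,
            grid={"mirna": [25]}, n_folds=3, seed=1,
        )
        assert best == {"mirna": 25} and len(curve) == 1

    def test_curve_has_interior_optimum_with_noise_beyond_signal(self, small_cohort,
                                                                 srs, cov_design):
        best, curve = ok.tune_feature_counts(
            {"cpg": small_cohort.layers["cpg"]}, srs, cov_design,
            grid={"cpg": [10, 40, 300]}, n_folds=5, seed=2,
        )
        tab = curve.set_index("n_features")["mean_r2"]
        assert best["cpg"] == tab.idxmax()
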