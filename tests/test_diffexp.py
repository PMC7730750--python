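"""Per-feature association tests, deconvolution and multiple testing."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import omnikernel as ok
from omnikernel.datatypes import LayerKind, OmicsLayer


def _layer(arr, kind=LayerKind.mrna_counts, prefix="g"):
    arr = np.asarray(arr)
    return OmicsLayer(
        values=pd.DataFrame(
            arr,
            index=[f"s{i}" for i in range(arr.shape[0])],
            columns=[f"{prefix}{j}" for j in range(arr.shape[1])],
        ),
        kind=kind,
    )


class TestBH:
    def test_stepup_hand_computed(self):
        np.testing.assert_allclose(ok.bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_all_equal_and_single(self):
        np.testing.assert_allclose(ok.bh_adjust([0.2, 0.2, 0.2]), 0.2)
        np.testing.assert_allclose(ok.bh_adjust([0.7]), [0.7])

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            ok.bh_adjust([0.5, 1.5])

    def test_nan_passthrough(self):
        out = ok.bh_adjust([0.01, np.nan, 0.5])
        assert np.isnan(out[1]) and not np.isnan(out[[0, 2]]).any()

    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=40))
    @settings(max_examples=50, deadline=None)
    def test_never_below_raw_p(self, p):
        fdr = ok.bh_adjust(p)
        assert (fdr >= np.asarray(p) - 1e-12).all()
        assert (fdr <= 1.0 + 1e-12).all()


class TestNBDifferential:
    def test_matches_statsmodels_oracle(self, rng):
        """Slopes agree with per-gene statsmodels NB GLM at the same dispersion."""
        import statsmodels.api as sm

        n, f = 200, 6
        x = rng.normal(size=n)
        mu = 60.0 * np.exp(0.4 * x)[:, None] * np.ones((1, f))
        phi = 0.15
        Y = rng.negative_binomial(1 / phi, 1 / (1 + phi * mu)).astype(float)
        layer = _layer(Y)
        tab = ok.nb_differential(layer, x, size_factors=np.ones(n))
        X = np.column_stack([np.ones(n), x])
        for j in range(f):
            fit = sm.GLM(Y[:, j], X, family=sm.families.NegativeBinomial(alpha=phi)).fit()
            assert tab.effect.iloc[j] * np.log(2) == pytest.approx(fit.params[1], abs=0.02)

    def test_constant_outcome_rejected(self, small_cohort):
        with pytest.raises(ValueError, match="constant"):
            ok.nb_differential(small_cohort.layers["mrna"], np.ones(150))

    def test_effect_recovery(self, rng):
        """log2FC-per-unit effects of 0.5 recovered within +-0.15 in most runs."""
        hits = 0
        for seed in range(10):
            r = np.random.default_rng(seed)
            n = 400
            x = r.normal(size=n)
            b = 0.5 * np.log(2)  # natural-log slope 0.5 log2 units
            mu = 80.0 * np.exp(b * x)
            phi = 0.1
            Y = r.negative_binomial(1 / phi, 1 / (1 + phi * mu)).astype(float)[:, None]
            pad = r.negative_binomial(1 / 0.2, 1 / (1 + 0.2 * 50.0), size=(n, 30)).astype(float)
            tab = ok.nb_differential(_layer(np.column_stack([Y, pad])), x, size_factors=np.ones(n))
            hits += abs(tab.effect.iloc[0] - 0.5) < 0.15
        assert hits >= 9

    def test_quasi_poisson_limit(self, rng):
        """At dispersion ~0 the NB fit collapses onto the Poisson slope."""
        import statsmodels.api as sm

        n = 300
        x = rng.normal(size=n)
        mu = 40.0 * np.exp(0.3 * x)
        Y = rng.poisson(mu, size=(n,)).astype(float)[:, None]
        from omnikernel import _fastglm

        X = np.column_stack([np.ones(n), x])
        fit = _fastglm.nb_irls(X, Y, np.zeros(n), phi=np.array([1e-8]))
        pois = sm.GLM(Y[:, 0], X, family=sm.families.Poisson()).fit()
        assert fit["beta"][0, 1] == pytest.approx(pois.params[1], abs=1e-3)


class TestEWAS:
    def test_matches_rlm_oracle_without_moderation(self, rng):
        """Huber slopes agree with statsmodels RLM per CpG."""
        import statsmodels.api as sm

        n, f = 120, 5
        x = rng.normal(size=n)
        Y = 0.3 * x[:, None] + rng.normal(0, 0.7, size=(n, f))
        Y[0, 0] += 8.0  # one gross outlier
        layer = _layer(Y, kind=LayerKind.methylation_m, prefix="cg")
        tab = ok.ewas_robust(layer, x, n_surrogates=0)
        X = np.column_stack([np.ones(n), x])
        for j in range(f):
            rlm = sm.RLM(Y[:, j], X, M=sm.robust.norms.HuberT(t=1.345)).fit()
            assert tab.effect.iloc[j] == pytest.approx(rlm.params[1], abs=0.02)

    def test_outlier_resistance_vs_ols(self, rng):
        n = 100
        x = rng.normal(size=n)
        y0 = rng.normal(0, 0.5, size=n)
        clean = _layer(y0[:, None], kind=LayerKind.methylation_m, prefix="cg")
        slope_clean = ok.ewas_robust(clean, x, n_surrogates=0).effect.iloc[0]
        y1 = y0.copy()
        y1[np.argmax(x)] += 50.0  # gross high-leverage outlier
        dirty = _layer(y1[:, None], kind=LayerKind.methylation_m, prefix="cg")
        slope_rob = ok.ewas_robust(dirty, x, n_surrogates=0).effect.iloc[0]
        ols_clean = np.polyfit(x, y0, 1)[0]
        ols_dirty = np.polyfit(x, y1, 1)[0]
        assert abs(slope_rob - slope_clean) < 0.2 * abs(ols_dirty - ols_clean)

    def test_identical_variances_collapse_to_common_prior(self, rng):
        from omnikernel._fastglm import moderate_variances

        s2 = np.full(50, 0.37)
        post, d0, s0 = moderate_variances(s2, df_resid=90)
        assert np.isinf(d0)
        assert np.abs(post - post[0]).max() < 1e-6

    def test_requires_enough_samples(self, rng):
        layer = _layer(rng.normal(size=(6, 4)), kind=LayerKind.methylation_m, prefix="cg")
        with pytest.raises(ValueError, match="10 samples"):
            ok.ewas_robust(layer, rng.normal(size=6))


class TestSurrogateVariables:
    def test_exact_rank2_residual_recovered(self, rng):
        n = 60
        design = np.column_stack([np.ones(n), rng.normal(size=n)])
        hidden = rng.normal(size=(n, 2))
        hidden -= design @ np.linalg.lstsq(design, hidden, rcond=None)[0]
        Y = hidden @ rng.normal(size=(2, 80))
        sv = ok.surrogate_variables(Y, design, k=2)
        # principal angles between recovered and true residual spaces ~ 0
        q1, _ = np.linalg.qr(sv)
        q2, _ = np.linalg.qr(hidden)
        angles = np.linalg.svd(q1.T @ q2, compute_uv=False)
        assert np.abs(angles - 1.0).max() < 1e-6

    def test_hidden_batch_detected(self, rng):
        n = 150
        batch = (rng.random(n) < 0.5).astype(float)
        design = np.column_stack([np.ones(n), rng.normal(size=n)])
        Y = rng.normal(size=(n, 200))
        Y[:, :100] += np.outer(batch, rng.normal(1.5, 0.2, 100))
        sv = ok.surrogate_variables(Y, design, k=1)
        assert abs(np.corrcoef(sv[:, 0], batch)[0, 1]) > 0.9

    def test_k_zero_and_k_too_large(self, rng):
        Y = rng.normal(size=(20, 30))
        design = np.ones((20, 1))
        assert ok.surrogate_variables(Y, design, k=0).shape == (20, 0)
        with pytest.raises(ValueError):
            ok.surrogate_variables(Y, design, k=19)


@pytest.fixture(scope="module")
def reference():
    return ok.generate_reference_profiles(150, 4, separation=3.0, seed=3)


class TestDeconvolution:
    def test_pure_column_is_one_hot(self, reference):
        props = ok.deconvolve(reference.iloc[:, 2], reference)
        expect = np.zeros(4)
        expect[2] = 1.0
        np.testing.assert_allclose(props.to_numpy(), expect, atol=1e-6)

    def test_exact_mixture_recovered(self, reference):
        w = np.array([0.5, 0.5, 0.0, 0.0])
        bulk = pd.Series(reference.to_numpy() @ w, index=reference.index)
        props = ok.deconvolve(bulk, reference)
        np.testing.assert_allclose(props.to_numpy(), w, atol=1e-4)

    def test_noisy_mixtures_mae(self, reference, rng):
        true = rng.dirichlet(np.ones(4), size=100)
        signal = true @ reference.to_numpy().T
        noisy = signal + rng.normal(0, 0.1 * signal.mean(), size=signal.shape)
        bulk = pd.DataFrame(np.clip(noisy, 0, None), columns=reference.index)
        est = ok.deconvolve(bulk, reference)
        assert np.abs(est.to_numpy() - true).mean() < 0.05

    def test_scale_invariance(self, reference, rng):
        w = rng.dirichlet(np.ones(4))
        bulk = pd.Series(reference.to_numpy() @ w + 0.1, index=reference.index)
        a = ok.deconvolve(bulk, reference)
        b = ok.deconvolve(37.0 * bulk, reference)
        np.testing.assert_allclose(a.to_numpy(), b.to_numpy(), atol=1e-8)

    def test_non_identifiable_reference_rejected(self, reference):
        dup = reference.copy()
        dup.iloc[:, 1] = dup.iloc[:, 0]
        with pytest.raises(ValueError, match="identifiable"):
            ok.deconvolve(reference.iloc[:, 0], dup)


class TestCellTypeInteraction:
    def test_zero_proportion_reduces_to_main_effects(self, small_cohort, srs, cov_design):
        layer = small_cohort.layers["mirna"]
        main = ok.nb_differential(layer, srs, cov_design, fast=True)
        _, main_from_interaction = ok.celltype_interaction_de(
            layer, srs, cov_design, proportions=np.zeros(150), fast=True
        )
        np.testing.assert_allclose(
            main.effect.to_numpy(), main_from_interaction.effect.to_numpy(), atol=1e-10
        )

    def test_constant_nonzero_proportion_rejected(self, small_cohort, srs, cov_design):
        with pytest.raises(ValueError, match="unidentifiable"):
            ok.celltype_interaction_de(
                small_cohort.layers["mirna"], srs, cov_design, proportions=np.full(150, 0.5)
            )

    def test_near_constant_warns(self, small_cohort, srs, cov_design, rng):
        prop = 0.5 + 1e-5 * rng.normal(size=150)
        with pytest.warns(UserWarning, match="near-constant"):
            ok.celltype_interaction_de(
                small_cohort.layers["mirna"], srs, cov_design,
                proportions=np.clip(prop, 0, 1), fast=True,
            )

    def test_interaction_recovery(self, rng):
        """A purely cell-type-specific effect lands on the interaction term."""
        n = 400
        x = rng.normal(size=n)
        prop = rng.beta(2, 2, size=n)
        b = 0.8
        mu = 60.0 * np.exp(b * x * prop)
        phi = 0.1
        Y = rng.negative_binomial(1 / phi, 1 / (1 + phi * mu)).astype(float)[:, None]
        pad = rng.negative_binomial(1 / 0.2, 1 / (1 + 0.2 * 40.0), size=(n, 30)).astype(float)
        inter, main = ok.celltype_interaction_de(
            _layer(np.column_stack([Y, pad])), x, proportions=prop, size_factors=np.ones(n)
        )
        assert inter.effect.iloc[0] * np.log(2) == pytest.approx(b, rel=0.30)
        assert abs(main.effect.iloc[0] * np.log(2)) < 0.25


class TestPower:
    def test_size_and_monotonicity(self):
        tab = ok.simulate_power("counts", [0.0, 0.25, 0.5, 1.0], mean=100, dispersion=0.1,
                                n=300, n_reps=150, seed=4)
        # size: power at zero effect stays near alpha
        se = np.sqrt(0.05 * 0.95 / 150)
        assert tab.power.iloc[0] == pytest.approx(0.05, abs=2.5 * se + 0.01)
        assert (np.diff(tab.power) >= -2 * np.sqrt(tab.power.iloc[1] / 150)).all()
        assert tab.power.iloc[-1] > 0.99

    def test_methylation_kind(self):
        tab = ok.simulate_power("methylation", [0.0, 1.0], m_sd=0.5, n=200, n_reps=100, seed=2)
        assert tab.power.iloc[1] > 0.95


class TestCovariateRegression:
    def test_null_outcome_low_r2(self, small_cohort, rng):
        ph = ok.PhenotypeTable(
            data=small_cohort.phenotypes.data.assign(
                SRS=rng.normal(size=150), IQ=rng.normal(size=150)
            )
        )
        res = ok.covariate_regression(ph)
        assert abs(res["SRS_adj_r2"]) < 0.06

    def test_exact_linear_outcome(self, small_cohort):
        design = small_cohort.phenotypes.covariate_design(add_intercept=False)
        y = design["birthweight_Z"] * 2.0 - design["sex_Male"]
        ph = ok.PhenotypeTable(data=small_cohort.phenotypes.data.assign(SRS=y, IQ=y))
        res = ok.covariate_regression(ph)
        assert res["SRS_adj_r2"] == pytest.approx(1.0, abs=1e-10)
        row = res["SRS"].set_index("term").loc["birthweight_Z"]
        assert row.estimate == pytest.approx(2.0, abs=1e-8) and row.p < 1e-12

    def test_recovers_injected_sign_pattern(self):
        cfg = ok.SimulationConfig(
            n_samples=1500, n_cpg=20, n_mrna=20, n_mirna=20,
            n_causal={"cpg": 0, "mrna": 0, "mirna": 0},
            latent_effect=0.3, outcome_noise_sd=0.3, seed=21,
        )
        coh = ok.generate_cohort(cfg)
        res = ok.covariate_regression(coh.phenotypes)
        effects = ok.simulate.DEFAULT_COVARIATE_EFFECTS
        for outcome, col in (("SRS", 0), ("IQ", 1)):
            tab = res[outcome].set_index("term")
            for term, eff in effects.items():
                true = eff[col]
                if abs(true) >= 3 * tab.loc[term, "se"]:
                    assert np.sign(tab.loc[term, "estimate"]) == np.sign(true)

    def test_fdr_ci_wider_than_nominal_only_when_correcting(self, small_cohort):
        res = ok.covariate_regression(small_cohort.phenotypes)
        tab = res["IQ"]
        assert (tab.ci_high > tab.ci_low).all()
        assert (tab.fdr >= tab.p - 1e-12).all()
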