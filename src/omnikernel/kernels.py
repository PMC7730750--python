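"""Kernel construction, aggregation and kernel-regression models.

This is the predictive core: each omic layer's selected features are
standardized and turned into a sample-similarity kernel (linear inner
product or Gaussian RBF), clinical covariates are projected out of both
the outcomes and the kernels, kernels are trace-normalized and averaged
across layers, and kernel regularized least squares (KRLS, with a
leave-one-out-tuned ridge penalty) or a single-component kernel linear
mixed model predicts the held-out samples. Performance is scored with
adjusted R-squared under Monte Carlo cross-validation with feature
selection strictly inside each training fold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.base import BaseEstimator, RegressorMixin

from . import _fastglm
from .datatypes import KernelMatrix, LayerKind, OmicsLayer, check_aligned_samples
from .preprocess import beta_to_m

# --------------------------------------------------------------------------
# kernel construction


def _standardize(X: np.ndarray, mean=None, sd=None):
    if mean is None:
        mean = X.mean(axis=0)
        sd = X.std(axis=0)
    keep = sd > 0
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} zero-variance features from the kernel")
    return (X[:, keep] - mean[keep]) / sd[keep], mean, sd, keep


def build_kernel(
    X,
    family: str = "linear",
    bandwidth: float | None = None,
    standardization: dict | bool | None = None,
) -> KernelMatrix:
    """Build a sample-similarity kernel from a samples x features matrix.

    Features are standardized to mean 0 / SD 1 with the supplied training
    statistics (``standardization`` dict), the matrix's own statistics
    (None), or not at all (False). Linear: K = X X' / p. Gaussian:
    K_ij = exp(-||x_i - x_j||^2 / sigma^2) with sigma^2 defaulting to the
    feature count p.
    """
    df = X if isinstance(X, pd.DataFrame) else pd.DataFrame(X)
    if df.shape[1] == 0:
        raise ValueError("empty feature set")
    vals = df.to_numpy(dtype=float)
    if not np.all(np.isfinite(vals)):
        raise ValueError("kernel input contains missing or non-finite values")
    if standardization is False:
        Z, mean, sd = vals, None, None
    elif standardization is None:
        Z, mean, sd, keep = _standardize(vals)
    else:
        feats = pd.Index(standardization["features"])
        if not feats.equals(df.columns):
            raise ValueError("standardization feature list does not match X")
        Z, mean, sd, keep = _standardize(
            vals, np.asarray(standardization["mean"]), np.asarray(standardization["sd"])
        )
    p = Z.shape[1]
    if family == "linear":
        K = Z @ Z.T / p
        bw = None
    elif family == "gaussian":
        bw = float(bandwidth) if bandwidth is not None else float(p)
        sq = np.sum(Z**2, axis=1)
        d2 = np.maximum(sq[:, None] + sq[None, :] - 2.0 * Z @ Z.T, 0.0)
        np.fill_diagonal(d2, 0.0)
        K = np.exp(-d2 / bw)
    else:
        raise ValueError(f"unknown kernel family {family!r}")
    stats_out = None
    if standardization is not False:
        stats_out = {"features": df.columns, "mean": mean, "sd": sd}
    return KernelMatrix(
        values=K,
        sample_ids=df.index,
        family=family,
        bandwidth=bw,
        source=[("matrix", list(df.columns))],
        standardization=stats_out,
    )


def build_cross_kernel(X_new, X_train, family="linear", bandwidth=None, standardization=None):
    """new x train kernel block using *training* standardization statistics."""
    dn = X_new if isinstance(X_new, pd.DataFrame) else pd.DataFrame(X_new)
    dt = X_train if isinstance(X_train, pd.DataFrame) else pd.DataFrame(X_train)
    if standardization is not None:
        feats = pd.Index(standardization["features"])
        mean, sd = np.asarray(standardization["mean"]), np.asarray(standardization["sd"])
    else:
        feats = dt.columns
        mean, sd = dt.to_numpy(dtype=float).mean(axis=0), dt.to_numpy(dtype=float).std(axis=0)
    keep = sd > 0
    zn = (dn[feats].to_numpy(dtype=float)[:, keep] - mean[keep]) / sd[keep]
    zt = (dt[feats].to_numpy(dtype=float)[:, keep] - mean[keep]) / sd[keep]
    p = zn.shape[1]
    if family == "linear":
        return zn @ zt.T / p
    bw = float(bandwidth) if bandwidth is not None else float(p)
    d2 = np.maximum(
        np.sum(zn**2, 1)[:, None] + np.sum(zt**2, 1)[None, :] - 2.0 * zn @ zt.T, 0.0
    )
    return np.exp(-d2 / bw)


def covariate_projector(design) -> np.ndarray:
    """Annihilator matrix P = I - C (C'C)^-1 C' for a full-rank design."""
    C = np.asarray(design, dtype=float)
    if np.linalg.matrix_rank(C) < C.shape[1]:
        raise ValueError("rank-deficient covariate design")
    return np.eye(C.shape[0]) - C @ np.linalg.solve(C.T @ C, C.T)


def residualize_kernel(K: KernelMatrix, covariate_design=None, projector=None) -> KernelMatrix:
    """Project clinical covariates out of a kernel: K -> P K P.

    Equivalent to residualizing the underlying standardized feature matrix
    on the covariates; keeps the kernel symmetric PSD. Pass ``projector``
    to re-apply a stored projection.
    """
    P = projector if projector is not None else covariate_projector(covariate_design)
    vals = P @ K.values @ P
    return KernelMatrix(
        values=0.5 * (vals + vals.T),
        sample_ids=K.sample_ids,
        family=K.family,
        bandwidth=K.bandwidth,
        source=list(K.source) + [("covariates_removed", None)],
        standardization=K.standardization,
    )


def aggregate_kernels(kernels: list) -> KernelMatrix:
    """Element-wise mean of trace-normalized kernels.

    Trace normalization (trace = n for each input) stops a 5000-feature
    layer from dominating the average by scale alone; the mean of PSD
    matrices stays PSD.
    """
    if not kernels:
        raise ValueError("no kernels to aggregate")
    ids = check_aligned_samples(*[pd.Index(k.sample_ids) for k in kernels])
    normed = [k.trace_normalized() for k in kernels]
    vals = np.mean([k.values for k in normed], axis=0)
    return KernelMatrix(
        values=vals,
        sample_ids=ids,
        family=normed[0].family,
        bandwidth=normed[0].bandwidth,
        source=[s for k in normed for s in k.source],
        standardization=None,
    )


# --------------------------------------------------------------------------
# models


class KRLS(BaseEstimator, RegressorMixin):
    """Kernel regularized least squares with closed-form LOO-tuned penalty.

    Minimizes ||y - b 1 - K alpha||^2 + lambda alpha' K alpha jointly over
    the unpenalized intercept b and dual coefficients alpha, so alpha =
    (K + lambda I)^-1 (y - b 1) with b the generalized-least-squares mean.
    Because the fit is a linear smoother from one quadratic objective, the
    leave-one-out residuals have the exact closed form e_i / (1 - S_ii)
    with S the full influence matrix; unless ``lambda_reg`` is fixed,
    lambda minimizes the closed-form LOO SSE by bounded search on
    log10 lambda, reusing one eigendecomposition of K across candidates.
    """

    def __init__(self, lambda_reg: float | None = None, log10_lambda_bounds=(-6.0, 6.0)):
        self.lambda_reg = lambda_reg
        self.log10_lambda_bounds = log10_lambda_bounds

    def _solve(self, lam: float):
        """Intercept, LOO SSE and rotated residuals at one penalty."""
        w = 1.0 / (self._d + lam)  # eigenvalues of (K + lam I)^-1
        denom = float(np.sum(self._u1**2 * w))
        b = float(np.sum(self._u1 * self._uy * w) / denom)
        yt = self._uy - b * self._u1  # rotated centered outcome
        # e = lam (K+lam I)^-1 (y - b1);  S_ii = H_ii + m1_i^2 / (1'M1)
        e = self._U @ (lam * w * yt)
        h = (self._U**2) @ (self._d * w)
        m1 = self._U @ (lam * w * self._u1)
        s_diag = h + m1**2 / (lam * denom)
        loo = e / np.maximum(1.0 - s_diag, 1e-12)
        return b, float(loo @ loo), yt, w

    def _loo_sse(self, lam: float) -> float:
        return self._solve(lam)[1]

    def fit(self, K, y):
        Kv = K.values if isinstance(K, KernelMatrix) else np.asarray(K, dtype=float)
        y = np.asarray(y, dtype=float)
        if not np.all(np.isfinite(y)):
            raise ValueError("outcome contains non-finite values")
        n = Kv.shape[0]
        if n < 10:
            raise ValueError("need at least 10 training samples")
        if y.shape != (n,):
            raise ValueError("kernel size and outcome length differ")
        self._d, self._U = np.linalg.eigh(Kv)
        self._d = np.maximum(self._d, 0.0)
        self._u1 = self._U.T @ np.ones(n)
        self._uy = self._U.T @ y
        if self.lambda_reg is not None:
            lam = float(self.lambda_reg)
        else:
            lo, hi = self.log10_lambda_bounds
            res = optimize.minimize_scalar(
                lambda t: self._loo_sse(10.0**t),
                bounds=(lo, hi),
                method="bounded",
                options={"xatol": 1e-6},
            )
            lam = 10.0**res.x
        b, loo, yt, w = self._solve(lam)
        self.lambda_ = lam
        self.loo_sse_ = loo
        self.intercept_ = b
        self.alpha_ = self._U @ (w * yt)
        self.n_train_ = n
        return self

    def predict(self, K_cross):
        Kc = K_cross.values if isinstance(K_cross, KernelMatrix) else np.asarray(K_cross)
        if Kc.shape[-1] != self.alpha_.shape[0]:
            raise ValueError("cross-kernel column count does not match training samples")
        return Kc @ self.alpha_ + self.intercept_


class KernelLMM(BaseEstimator, RegressorMixin):
    """Single-component kernel linear mixed model with BLUP prediction.

    y = mu + u + e with u ~ (0, sigma2_g K), e ~ (0, sigma2_e I); the
    variance ratio delta = sigma2_e / sigma2_g is profiled out by
    eigen-rotating K, so the likelihood maximization is one-dimensional;
    mu is the GLS mean at each candidate delta. Predictions are the BLUP
    K_cross (K + delta I)^-1 (y - mu) + mu, algebraically identical to
    KRLS at lambda = delta.
    """

    def __init__(self, log10_delta_bounds=(-6.0, 8.0)):
        self.log10_delta_bounds = log10_delta_bounds

    def fit(self, K, y):
        Kv = K.values if isinstance(K, KernelMatrix) else np.asarray(K, dtype=float)
        y = np.asarray(y, dtype=float)
        n = Kv.shape[0]
        if n < 10:
            raise ValueError("need at least 10 training samples")
        d, U = np.linalg.eigh(Kv)
        d = np.maximum(d, 0.0)
        u1 = U.T @ np.ones(n)
        uy = U.T @ y

        def profile(delta):
            w = 1.0 / (d + delta)
            mu = float(np.sum(u1 * uy * w) / np.sum(u1**2 * w))
            yt = uy - mu * u1
            s2g = float(np.sum(yt**2 * w) / n)
            return mu, yt, w, s2g

        def nll(t):
            delta = 10.0**t
            _, _, w, s2g = profile(delta)
            return 0.5 * (n * np.log(max(s2g, 1e-300)) - np.sum(np.log(w)) + n)

        lo, hi = self.log10_delta_bounds
        res = optimize.minimize_scalar(nll, bounds=(lo, hi), method="bounded")
        self.delta_ = 10.0**res.x
        mu, yt, w, s2g = profile(self.delta_)
        self.mu_ = mu
        self.sigma2_g_ = s2g
        self.sigma2_e_ = self.delta_ * s2g
        self.ratio_ = self.sigma2_g_ / (self.sigma2_g_ + self.sigma2_e_)
        self.pinned_ = res.x >= hi - 1e-3
        if self.pinned_:
            warnings.warn("genetic variance pinned at ~0; returning intercept-only predictions")
        self.alpha_ = U @ (w * yt)
        return self

    def predict(self, K_cross):
        Kc = K_cross.values if isinstance(K_cross, KernelMatrix) else np.asarray(K_cross)
        return Kc @ self.alpha_ + self.mu_


def krls_fit(K, y, lambda_reg=None) -> KRLS:
    return KRLS(lambda_reg=lambda_reg).fit(K, y)


def krls_predict(fit: KRLS, K_cross):
    return fit.predict(K_cross)


def kernel_lmm_fit(K, y) -> KernelLMM:
    return KernelLMM().fit(K, y)


def adjusted_r2(observed, predicted, p_adjust: int = 1) -> float:
    """Adjusted R-squared of predictions: squared Pearson correlation,
    penalized as 1 - (1 - R^2)(n - 1)/(n - p_adjust - 1). May be negative."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    n = obs.size
    if n < p_adjust + 2:
        raise ValueError("need at least p_adjust + 2 samples")
    if pred.std() == 0 or obs.std() == 0:
        warnings.warn("zero-variance vector in adjusted R^2; defining the value as 0")
        return 0.0
    r2 = float(np.corrcoef(obs, pred)[0, 1] ** 2)
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p_adjust - 1)


# --------------------------------------------------------------------------
# training-fold feature selection and the Monte Carlo CV engine


@dataclass
class _PreparedLayer:
    """Per-layer matrices precomputed once per CV run."""

    name: str
    is_counts: bool
    assoc_values: np.ndarray  # counts (raw) or M-values, for association scans
    kernel_values: np.ndarray  # VST expression or M-values, for kernels
    feature_ids: pd.Index
    uq_quantile: np.ndarray | None  # per-sample upper-quartile, counts only


def _prepare_layer(name: str, layer: OmicsLayer) -> _PreparedLayer:
    if layer.kind in (LayerKind.methylation_beta, LayerKind.methylation_m):
        if layer.kind is LayerKind.methylation_beta:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                m = beta_to_m(layer.values).to_numpy(dtype=float)
        else:
            m = layer.values.to_numpy(dtype=float)
        return _PreparedLayer(name, False, m, m, layer.feature_ids, None)
    counts = layer.values.to_numpy(dtype=float)
    uq = np.array([np.quantile(row[row > 0], 0.75) if (row > 0).any() else np.nan for row in counts])
    if np.isnan(uq).any():
        raise ValueError("sample with all-zero counts in layer " + name)
    return _PreparedLayer(name, True, counts, np.empty(0), layer.feature_ids, uq)


def _selection_pvalues(prep: _PreparedLayer, train_idx, y_train, cov_train) -> np.ndarray:
    """Raw association p per feature, computed on training samples only."""
    n = len(train_idx)
    cols = [np.ones(n)]
    if cov_train is not None:
        cols.extend(np.asarray(cov_train, dtype=float).T)
    cols.append(np.asarray(y_train, dtype=float))
    X = np.column_stack(cols)
    if prep.is_counts:
        Y = prep.assoc_values[train_idx]
        offset = np.log(prep.uq_quantile[train_idx] / np.exp(np.mean(np.log(prep.uq_quantile[train_idx]))))
        pois = _fastglm.nb_irls(X, Y, offset, phi=np.zeros(Y.shape[1]), max_iter=8)
        phi = _fastglm.nb_moment_dispersion(Y, pois["mu"], n_params=X.shape[1])
        phi = _fastglm.shrink_dispersion_to_trend(phi, Y.mean(axis=0), n_samples=Y.shape[0])
        fit = _fastglm.nb_irls(X, Y, offset, phi=phi, beta0=pois["beta"], max_iter=8)
        inv_diag, _ = _fastglm._inv_diag(fit["gram"])
        z = fit["beta"][:, -1] / np.sqrt(np.maximum(inv_diag[:, -1], 1e-300))
        p = 2.0 * stats.norm.sf(np.abs(z))
        p[~np.isfinite(z)] = 1.0
    else:
        Y = prep.assoc_values[train_idx]
        fit = _fastglm.huber_fit(X, Y, max_iter=8)
        s2_post, d0, _ = _fastglm.moderate_variances(fit["s2"], fit["df_resid"])
        t = fit["beta"][:, -1] / np.sqrt(s2_post * fit["inv_gram_diag"][:, -1])
        df = fit["df_resid"] if np.isinf(d0) else fit["df_resid"] + d0
        p = 2.0 * stats.t.sf(np.abs(t), df=df)
    return p


def select_top_features(layer: OmicsLayer, outcome, covariates, n_top: int, train_index):
    """Rank features by raw association p on the *training* samples only.

    Counts use the NB Wald path, methylation the robust moderated-t path;
    ties break deterministically by feature identifier. Returns an ordered
    feature Index of length ``n_top`` (or all features, with a warning, if
    the layer is smaller).
    """
    prep = _prepare_layer("layer", layer)
    train_idx = np.asarray(train_index)
    y = np.asarray(outcome, dtype=float)[train_idx]
    cov = None if covariates is None else np.asarray(covariates, dtype=float)[train_idx]
    p = _selection_pvalues(prep, train_idx, y, cov)
    order = pd.DataFrame({"p": p, "fid": prep.feature_ids}).sort_values(
        ["p", "fid"], kind="mergesort"
    )
    if n_top > layer.n_features:
        warnings.warn("n_top exceeds the layer feature count; returning all features")
        n_top = layer.n_features
    return pd.Index(order["fid"].iloc[:n_top])


def _fold_seed(seed: int, fold: int) -> int:
    return int((seed * 100_003 + 7_919 * fold + 1) % 2_147_483_647)


def _vst_counts(prep: _PreparedLayer, train_idx) -> np.ndarray:
    """UQ-normalize (training geometric mean) + variance stabilize counts."""
    factors = prep.uq_quantile / np.exp(np.mean(np.log(prep.uq_quantile[train_idx])))
    return np.log2(prep.assoc_values / factors[:, None] + 0.5)


def _fold_model(
    prepared: dict,
    y: np.ndarray,
    C: np.ndarray,
    train_idx: np.ndarray,
    test_idx: np.ndarray,
    combination,
    feature_counts: dict,
    family: str,
    model: str,
    bandwidth=None,
):
    """Run the full training pipeline on one train/test split.

    Returns (test predictions, residualized test outcome, per-layer fit
    details) with every data-dependent choice made on the training rows.
    """
    coef, *_ = np.linalg.lstsq(C[train_idx], y[train_idx], rcond=None)
    y_resid = y - C @ coef
    n = y.shape[0]
    n_train = len(train_idx)

    K_full = None
    details = {"outcome_coef": coef, "layers": {}}
    for name in combination:
        prep = prepared[name]
        p_vals = _selection_pvalues(
            prep, train_idx, y_resid[train_idx], np.delete(C, 0, axis=1)[train_idx]
        )
        order = pd.DataFrame({"p": p_vals, "fid": prep.feature_ids}).sort_values(
            ["p", "fid"], kind="mergesort"
        )
        n_top = min(feature_counts.get(name, prep.feature_ids.size), prep.feature_ids.size)
        sel_ids = pd.Index(order["fid"].iloc[:n_top])
        sel_pos = prep.feature_ids.get_indexer(sel_ids)

        base = _vst_counts(prep, train_idx) if prep.is_counts else prep.kernel_values
        X = base[:, sel_pos]
        mean = X[train_idx].mean(axis=0)
        sd = X[train_idx].std(axis=0)
        keep = sd > 0
        Z = (X[:, keep] - mean[keep]) / sd[keep]
        B, *_ = np.linalg.lstsq(C[train_idx], Z[train_idx], rcond=None)
        Z = Z - C @ B
        p_sel = Z.shape[1]
        if family == "linear":
            K = Z @ Z.T / p_sel
            bw = None
        else:
            bw = float(bandwidth) if bandwidth is not None else float(p_sel)
            sq = np.sum(Z**2, axis=1)
            K = np.exp(-np.maximum(sq[:, None] + sq[None, :] - 2.0 * Z @ Z.T, 0.0) / bw)
        tr = np.trace(K[np.ix_(train_idx, train_idx)])
        K = K * (n_train / tr)
        K_full = K if K_full is None else K_full + K
        details["layers"][name] = {
            "selected": sel_ids,
            "mean": mean,
            "sd": sd,
            "keep": keep,
            "covariate_coef": B,
            "trace_factor": n_train / tr,
            "bandwidth": bw,
            "Z_train": Z[train_idx],
        }
    K_full = K_full / len(list(combination))

    est = KRLS() if model == "krls" else KernelLMM()
    est.fit(K_full[np.ix_(train_idx, train_idx)], y_resid[train_idx])
    pred = est.predict(K_full[np.ix_(test_idx, train_idx)])
    details["estimator"] = est
    return pred, y_resid[test_idx], details


def monte_carlo_cv(
    layers: dict,
    outcome,
    covariates,
    combination=("cpg", "mrna", "mirna"),
    family: str = "linear",
    feature_counts: dict | None = None,
    n_folds: int = 50,
    train_fraction: float = 0.75,
    seed: int = 0,
    model: str = "krls",
    bandwidth=None,
):
    """Monte Carlo cross-validated adjusted R-squared for one model configuration.

    Per fold: draw a train/test split from a fold-specific seed,
    residualize the outcome on training covariates, select features per
    layer on training samples, standardize with training statistics, build
    per-layer kernels, remove covariates, aggregate, fit KRLS (or the
    kernel LMM), predict the test fold, and score adjusted R-squared.
    Fold membership is derived from sample identifiers, so permuting input
    row order permutes nothing but labels.
    """
    from .datatypes import CVReport

    combination = tuple(combination)
    if not combination:
        raise ValueError("combination must name at least one layer")
    check_aligned_samples(*[layers[c] for c in combination])
    feature_counts = dict(feature_counts or {})
    prepared = {name: _prepare_layer(name, layers[name]) for name in combination}
    y = np.asarray(outcome, dtype=float)
    C = np.column_stack([np.ones(y.size), np.asarray(covariates, dtype=float)])
    n = y.size
    n_test = max(1, int(round((1.0 - train_fraction) * n)))
    id_order = np.argsort(np.asarray(layers[combination[0]].sample_ids).astype(str))

    fold_r2, fold_seeds, fold_tests, failures = [], [], [], []
    for fold in range(n_folds):
        fs = _fold_seed(seed, fold)
        rng = np.random.default_rng(fs)
        perm = id_order[rng.permutation(n)]
        test_idx, train_idx = np.sort(perm[:n_test]), np.sort(perm[n_test:])
        try:
            pred, y_test, _ = _fold_model(
                prepared, y, C, train_idx, test_idx, combination,
                feature_counts, family, model, bandwidth,
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                r2 = adjusted_r2(y_test, pred, p_adjust=1)
        except Exception as exc:  # noqa: BLE001 - fold errors are data, not bugs
            failures.append({"fold": fold, "error": str(exc)})
            if len(failures) > 0.2 * n_folds:
                raise RuntimeError(f"more than 20% of folds failed: {failures}") from exc
            continue
        fold_r2.append(r2)
        fold_seeds.append(fs)
        fold_tests.append(test_idx)
    return CVReport(
        model_spec={
            "combination": list(combination),
            "family": family,
            "feature_counts": feature_counts,
            "model": model,
            "n_folds": n_folds,
            "train_fraction": train_fraction,
            "seed": seed,
        },
        fold_r2=fold_r2,
        fold_seeds=fold_seeds,
        fold_test_indices=fold_tests,
        failures=failures,
    )


def tune_feature_counts(
    layers: dict,
    outcome,
    covariates,
    grid: dict | None = None,
    n_folds: int = 50,
    seed: int = 0,
    family: str = "linear",
    model: str = "krls",
):
    """Tune the per-layer feature count by single-layer Monte Carlo CV.

    Runs ``monte_carlo_cv`` for each grid value in each layer separately
    and returns (best count per layer, full performance curve). The
    default grid {100, 500, 1000, 5000, 10000} is intersected with each
    layer's feature count.
    """
    default = (100, 500, 1000, 5000, 10000)
    rows = []
    best = {}
    for name, layer in layers.items():
        values = grid.get(name, default) if grid else default
        values = sorted({min(v, layer.n_features) for v in values if v > 0})
        if not values:
            raise ValueError(f"empty tuning grid for layer {name!r}")
        means = []
        for v in values:
            rep = monte_carlo_cv(
                layers, outcome, covariates, combination=(name,), family=family,
                feature_counts={name: v}, n_folds=n_folds, seed=seed, model=model,
            )
            means.append(rep.mean_r2)
            rows.append({"layer": name, "n_features": v, "mean_r2": rep.mean_r2, "sd_r2": rep.sd_r2})
        best[name] = values[int(np.argmax(means))]
    return best, pd.DataFrame(rows)


# --------------------------------------------------------------------------
# whole-data model bundle (for validation / external application)


@dataclass
class KernelModelBundle:
    """A kernel model trained on a full cohort, portable to new samples."""

    combination: tuple
    family: str
    feature_counts: dict
    estimator: object
    layer_details: dict
    outcome_coef: np.ndarray
    sample_ids: pd.Index
    model: str = "krls"
    fitted_values_: np.ndarray | None = None


def fit_kernel_model(
    layers: dict,
    outcome,
    covariates,
    combination=("cpg",),
    feature_counts: dict | None = None,
    family: str = "linear",
    model: str = "krls",
    bandwidth=None,
) -> KernelModelBundle:
    """Train the full pipeline on all samples and keep everything needed to
    predict new samples (selected features, standardization, covariate
    projections, dual coefficients)."""
    combination = tuple(combination)
    prepared = {name: _prepare_layer(name, layers[name]) for name in combination}
    y = np.asarray(outcome, dtype=float)
    C = np.column_stack([np.ones(y.size), np.asarray(covariates, dtype=float)])
    all_idx = np.arange(y.size)
    pred, _, details = _fold_model(
        prepared, y, C, all_idx, all_idx, combination,
        dict(feature_counts or {}), family, model, bandwidth,
    )
    return KernelModelBundle(
        combination=combination,
        family=family,
        feature_counts=dict(feature_counts or {}),
        estimator=details["estimator"],
        layer_details=details["layers"],
        outcome_coef=details["outcome_coef"],
        sample_ids=layers[combination[0]].sample_ids,
        model=model,
        fitted_values_=pred,
    )
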