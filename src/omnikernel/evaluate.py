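"""Validation of the kernel prediction models.

Reproduces the study's validation logic: correlative statistics among the
outcomes, 10-fold in-sample predicted scores, association of predicted
scores with the binary ASD label, and application of a methylation-only
model bundle to an external M-value dataset (with feature intersection
and training-mean imputation).
"""

from __future__ import annotations

import itertools
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import LayerKind, OmicsLayer, check_aligned_samples
from .kernels import KernelModelBundle, _fold_model, _fold_seed, _prepare_layer, adjusted_r2
from .preprocess import beta_to_m

#: Tuned feature counts carried into validation by default: 5000 CpGs and
#: 1000 features for each expression layer.
DEFAULT_FEATURE_COUNTS = {"cpg": 5000, "mrna": 1000, "mirna": 1000}


def rank_sum_test(x, y, alternative: str = "two-sided"):
    """Wilcoxon rank-sum (Mann-Whitney) test of two samples.

    Exact enumeration when both groups have at most 10 observations,
    normal approximation with continuity correction otherwise. Returns
    (W statistic of the first sample, p-value).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    method = "exact" if max(x.size, y.size) <= 10 else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative=alternative, method=method)
    return float(res.statistic), float(res.pvalue)


def pearson_ci(x, y, level: float = 0.95):
    """Pearson correlation with a Fisher-z confidence interval."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 4:
        raise ValueError("need at least 4 samples for a Fisher-z interval")
    r = float(np.corrcoef(x, y)[0, 1])
    if abs(r) >= 1.0:
        return r, (r, r)
    z = np.arctanh(r)
    half = stats.norm.ppf(0.5 + level / 2.0) / np.sqrt(x.size - 3)
    return r, (float(np.tanh(z - half)), float(np.tanh(z + half)))


def _group_difference(values, labels, level: float = 0.95):
    """Case-minus-control mean difference with a Welch normal-theory CI."""
    v = np.asarray(values, dtype=float)
    lab = np.asarray(labels)
    case, ctrl = v[lab == 1], v[lab == 0]
    diff = case.mean() - ctrl.mean()
    se = np.sqrt(case.var(ddof=1) / case.size + ctrl.var(ddof=1) / ctrl.size)
    half = stats.norm.ppf(0.5 + level / 2.0) * se
    return float(diff), (float(diff - half), float(diff + half))


def outcome_correlations(phenotypes) -> dict:
    """Correlative statistics among SRS, IQ and ASD.

    Pearson r(SRS, IQ) with 95% Fisher-z CI, and for each outcome the
    Wilcoxon rank-sum test across ASD case/control groups with the
    case-control mean difference and CI.
    """
    srs = phenotypes.outcome("SRS").to_numpy(dtype=float)
    iq = phenotypes.outcome("IQ").to_numpy(dtype=float)
    asd = phenotypes.data["ASD"].to_numpy()
    if len(np.unique(asd)) < 2:
        raise ValueError("both ASD classes must be present")
    r, ci = pearson_ci(srs, iq)
    out = {"srs_iq_pearson": {"r": r, "ci": ci, "n": srs.size}}
    for name, vals in (("SRS", srs), ("IQ", iq)):
        w, p = rank_sum_test(vals[asd == 1], vals[asd == 0])
        diff, dci = _group_difference(vals, asd)
        out[f"{name.lower()}_by_asd"] = {"W": w, "p": p, "mean_difference": diff, "ci": dci}
    return out


def insample_predict(
    layers: dict,
    outcome,
    covariates,
    combination=("cpg", "mrna", "mirna"),
    feature_counts: dict | None = None,
    family: str = "linear",
    model: str = "krls",
    k: int = 10,
    seed: int = 0,
):
    """Out-of-fold predicted scores from a k-fold partition (default 10).

    Each sample is predicted exactly once, by a model whose feature
    selection, standardization, covariate projections and penalty were all
    fitted on the other k-1 folds. Returns (scores frame with columns
    predicted / observed_residual / fold, summary statistics dict).
    """
    combination = tuple(combination)
    check_aligned_samples(*[layers[c] for c in combination])
    feature_counts = dict(feature_counts or DEFAULT_FEATURE_COUNTS)
    prepared = {name: _prepare_layer(name, layers[name]) for name in combination}
    y = np.asarray(outcome, dtype=float)
    C = np.column_stack([np.ones(y.size), np.asarray(covariates, dtype=float)])
    n = y.size
    sample_ids = pd.Index(layers[combination[0]].sample_ids)
    id_order = np.argsort(np.asarray(sample_ids).astype(str))
    rng = np.random.default_rng(_fold_seed(seed, 0))
    perm = id_order[rng.permutation(n)]
    folds = np.array_split(perm, k)
    if min(len(f) for f in folds) < 5:
        raise ValueError("each fold must contain at least 5 samples")

    pred = np.full(n, np.nan)
    obs = np.full(n, np.nan)
    fold_of = np.full(n, -1)
    for i, test_idx in enumerate(folds):
        test_idx = np.sort(test_idx)
        train_idx = np.sort(np.setdiff1d(perm, test_idx))
        p_i, y_i, _ = _fold_model(
            prepared, y, C, train_idx, test_idx, combination, feature_counts, family, model
        )
        pred[test_idx] = p_i
        obs[test_idx] = y_i
        fold_of[test_idx] = i
    scores = pd.DataFrame(
        {"predicted": pred, "observed_residual": obs, "fold": fold_of}, index=sample_ids
    )
    pear_r, pear_p = stats.pearsonr(obs, pred)
    spear_rho, spear_p = _spearman(obs, pred)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        adj = adjusted_r2(obs, pred, p_adjust=1)
    summary = {
        "pearson_r": float(pear_r),
        "pearson_p": float(pear_p),
        "spearman_rho": spear_rho,
        "spearman_p": spear_p,
        "cv_r2": float(pear_r**2),
        "adjusted_r2": adj,
    }
    return scores, summary


def _spearman(x, y):
    """Spearman correlation; exact permutation p for tiny n, t approximation
    otherwise."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    rho = float(stats.spearmanr(x, y).statistic)
    if n <= 7:
        rx = stats.rankdata(x)
        ry = stats.rankdata(y)
        observed = abs(np.corrcoef(rx, ry)[0, 1])
        count = 0
        total = 0
        for perm in itertools.permutations(ry):
            total += 1
            if abs(np.corrcoef(rx, np.asarray(perm))[0, 1]) >= observed - 1e-12:
                count += 1
        return rho, count / total
    t = rho * np.sqrt((n - 2) / max(1e-12, 1.0 - rho**2))
    return rho, float(2.0 * stats.t.sf(abs(t), df=n - 2))


def label_association(scores, labels) -> dict:
    """Two-sided Mann-Whitney association of predicted scores with a binary label.

    Mean difference is case minus control (label 1 minus label 0); a
    positive difference means cases score higher.
    """
    s = np.asarray(scores, dtype=float)
    lab = np.asarray(labels)
    if len(np.unique(lab)) < 2:
        raise ValueError("both classes must be present")
    case, ctrl = s[lab == 1], s[lab == 0]
    if s.std() == 0:
        warnings.warn("constant predicted scores; reporting p = 1")
        return {"W": np.nan, "p": 1.0, "mean_difference": 0.0}
    w, p = rank_sum_test(case, ctrl)
    return {"W": w, "p": p, "mean_difference": float(case.mean() - ctrl.mean())}


def apply_external(bundle: KernelModelBundle, external_layer: OmicsLayer, covariates=None):
    """Predict an external methylation-only dataset with a trained bundle.

    External features are intersected with the model's selected features;
    missing features are imputed at the training mean (standardized 0) and
    the achieved coverage is reported. The cross-kernel uses training
    standardization and trace scaling. Covariates, when available for the
    external samples, are removed with the training coefficients;
    otherwise the features enter unadjusted.

    Returns (predicted scores Series, coverage fraction).
    """
    if len(bundle.combination) != 1:
        raise ValueError("external application expects a single-layer (methylation-only) bundle")
    name = bundle.combination[0]
    det = bundle.layer_details[name]
    if external_layer.kind is LayerKind.methylation_beta:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ext_vals = beta_to_m(external_layer.values)
    elif external_layer.kind is LayerKind.methylation_m:
        ext_vals = external_layer.values
    else:
        raise ValueError("external layer must be methylation beta or M values")

    selected = pd.Index(det["selected"])[det["keep"]]
    mean = det["mean"][det["keep"]]
    sd = det["sd"][det["keep"]]
    present = selected.isin(ext_vals.columns)
    coverage = float(present.mean())
    if coverage < 0.10:
        raise ValueError(f"feature overlap {coverage:.1%} below 10%; model not portable")

    n_ext = ext_vals.shape[0]
    Z = np.zeros((n_ext, selected.size))
    Z[:, present] = (
        ext_vals[selected[present]].to_numpy(dtype=float) - mean[present]
    ) / sd[present]
    if covariates is not None:
        C_ext = np.column_stack([np.ones(n_ext), np.asarray(covariates, dtype=float)])
        Z = Z - C_ext @ det["covariate_coef"]
    Zt = det["Z_train"]
    p_sel = Z.shape[1]
    if bundle.family == "linear":
        K_cross = Z @ Zt.T / p_sel
    else:
        bw = det["bandwidth"]
        d2 = np.maximum(
            np.sum(Z**2, 1)[:, None] + np.sum(Zt**2, 1)[None, :] - 2.0 * Z @ Zt.T, 0.0
        )
        K_cross = np.exp(-d2 / bw)
    K_cross = K_cross * det["trace_factor"]
    preds = bundle.estimator.predict(K_cross)
    return pd.Series(preds, index=external_layer.sample_ids, name="predicted"), coverage
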