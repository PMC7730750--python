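"""Genome-wide per-feature association analyses.

Count layers (mRNA, miRNA) are tested with negative-binomial GLMs with a
log link and upper-quartile library offsets; methylation M-values with
Huber robust regression whose variances are moderated by empirical-Bayes
shrinkage; cell-type composition is estimated by reference-based
deconvolution and folded into the count model through an
outcome x proportion interaction. Multiple testing is controlled with
Benjamini-Hochberg throughout.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests

from . import _fastglm
from .datatypes import OmicsLayer, differential_table
from .preprocess import beta_to_m, upper_quartile_normalize


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    NaN entries (e.g. non-converged fits) are excluded from the procedure
    and returned as NaN.
    """
    p = np.asarray(p, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    vals = p[mask]
    if ((vals < 0) | (vals > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if vals.size:
        out[mask] = multipletests(vals, method="fdr_bh")[1]
    return out


def _build_design(n: int, outcome, covariates=None, extra: dict | None = None):
    """Assemble intercept + covariates + extra columns + outcome (last)."""
    y = np.asarray(outcome, dtype=float)
    if y.shape != (n,):
        raise ValueError("outcome length does not match the layer")
    if not np.all(np.isfinite(y)):
        raise ValueError("outcome contains non-finite values")
    if y.std() == 0:
        raise ValueError("outcome is constant (zero-variance predictor)")
    cols = [np.ones(n)]
    names = ["intercept"]
    if covariates is not None:
        cdf = pd.DataFrame(covariates)
        if "intercept" in cdf.columns:
            cdf = cdf.drop(columns="intercept")
        cols.extend(np.asarray(cdf, dtype=float).T)
        names.extend(map(str, cdf.columns))
    for name, arr in (extra or {}).items():
        arr = np.atleast_2d(np.asarray(arr, dtype=float))
        if arr.shape[0] == n:
            arr = arr.T
        for j, row in enumerate(arr):
            cols.append(row)
            names.append(name if arr.shape[0] == 1 else f"{name}{j + 1}")
    cols.append(y)
    names.append("outcome")
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")
    return X, names


def nb_differential(
    layer: OmicsLayer,
    outcome,
    covariates=None,
    ruv_factor=None,
    size_factors=None,
    fast: bool = False,
) -> pd.DataFrame:
    """Negative-binomial Wald test of each count feature against a continuous outcome.

    Per feature: NB GLM with log link, offset = log upper-quartile size
    factor, design = intercept + covariates (+ unwanted-variation factor)
    + outcome. Dispersions are estimated by one-step adjusted profile
    likelihood on a log grid and shrunk toward a log-linear
    mean-dispersion trend with an empirical weight (strong shrinkage only
    when per-feature estimates are noisy relative to their spread around
    the trend); ``fast=True`` skips the profile step and uses moment
    dispersions, for ranking inside cross-validation folds. Effects are
    log2-fold-change per outcome unit.
    """
    if not layer.kind.is_counts:
        raise ValueError("nb_differential requires a count layer")
    Y = layer.values.to_numpy(dtype=float)
    n = Y.shape[0]
    extra = {"ruv": ruv_factor} if ruv_factor is not None else None
    X, _ = _build_design(n, outcome, covariates, extra)
    if size_factors is None:
        _, factors = upper_quartile_normalize(layer)
        size_factors = factors.to_numpy()
    offset = np.log(np.asarray(size_factors, dtype=float))

    pois = _fastglm.nb_irls(X, Y, offset, phi=np.zeros(Y.shape[1]), max_iter=12)
    phi = _fastglm.nb_moment_dispersion(Y, pois["mu"], n_params=X.shape[1])
    if not fast:
        phi = _fastglm.nb_apl_dispersion(X, Y, pois["mu"])
    phi = _fastglm.shrink_dispersion_to_trend(phi, Y.mean(axis=0), n_samples=Y.shape[0])
    fit = _fastglm.nb_irls(X, Y, offset, phi=phi, beta0=pois["beta"], max_iter=10 if fast else 25)

    inv_diag, _ = _fastglm._inv_diag(fit["gram"])
    slope = fit["beta"][:, -1] / np.log(2.0)  # natural-log slope -> log2 scale
    se = np.sqrt(np.maximum(inv_diag[:, -1], 1e-300)) / np.log(2.0)
    z = slope / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    bad = ~fit["converged"] | ~np.isfinite(z)
    if bad.any():
        warnings.warn(f"{int(bad.sum())} features failed NB convergence; excluded from BH")
        p[bad] = np.nan
    return differential_table(layer.feature_ids, slope, se, z, p, bh_adjust(p))


def surrogate_variables(layer, design, k: int = 5) -> np.ndarray:
    """Top-k left singular vectors of the residual matrix after removing the design.

    The two-step surrogate-variable construction used to absorb cell-type
    heterogeneity in the EWAS: regress every feature on the full design
    (including the outcome), then take the leading left singular vectors of
    the residuals. Columns are orthonormal.
    """
    Y = layer.values.to_numpy(dtype=float) if isinstance(layer, OmicsLayer) else np.asarray(layer)
    X = np.asarray(design, dtype=float)
    n = Y.shape[0]
    rank = np.linalg.matrix_rank(X)
    if k >= n - rank:
        raise ValueError("k must be smaller than n_samples - rank(design)")
    if k == 0:
        return np.empty((n, 0))
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    u, s, _ = np.linalg.svd(resid, full_matrices=False)
    return u[:, :k]


def ewas_robust(
    layer: OmicsLayer,
    outcome,
    covariates=None,
    n_surrogates: int = 5,
) -> pd.DataFrame:
    """Epigenome-wide robust regression with empirical-Bayes moderated t-tests.

    Per CpG: Huber M-estimation regression of the M-value on intercept +
    covariates + surrogate variables + outcome; residual variances are
    shrunk toward a scaled inverse-chi-square prior fitted by method of
    moments, and outcome slopes are tested with a moderated t on augmented
    degrees of freedom.
    """
    if layer.kind.value == "methylation_beta":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            Y = beta_to_m(layer.values).to_numpy(dtype=float)
    elif layer.kind.value == "methylation_m":
        Y = layer.values.to_numpy(dtype=float)
    else:
        raise ValueError("ewas_robust requires a methylation layer")
    n = Y.shape[0]
    if n < 10:
        raise ValueError("need at least 10 samples for the EWAS")
    X0, _ = _build_design(n, outcome, covariates)
    sv = surrogate_variables(Y, X0, k=n_surrogates)
    X, _ = _build_design(n, outcome, covariates, extra={"sv": sv} if n_surrogates else None)

    fit = _fastglm.huber_fit(X, Y)
    s2_post, d0, _ = _fastglm.moderate_variances(fit["s2"], fit["df_resid"])
    slope = fit["beta"][:, -1]
    se = np.sqrt(s2_post * fit["inv_gram_diag"][:, -1])
    t = slope / se
    df = fit["df_resid"] if np.isinf(d0) else fit["df_resid"] + d0
    p = 2.0 * stats.t.sf(np.abs(t), df=df)
    return differential_table(layer.feature_ids, slope, se, t, p, bh_adjust(p))


def _check_reference(reference: pd.DataFrame) -> None:
    R = reference.to_numpy(dtype=float)
    if R.shape[1] < 2:
        raise ValueError("reference needs at least two cell types")
    norm = R / np.linalg.norm(R, axis=0)
    gram = norm.T @ norm
    off = gram[~np.eye(R.shape[1], dtype=bool)]
    if np.linalg.matrix_rank(R) < R.shape[1] or off.max() > 0.999:
        raise ValueError("reference profiles are not identifiable")


def deconvolve(bulk, reference: pd.DataFrame) -> pd.DataFrame:
    """Reference-based cell-type deconvolution of bulk expression.

    Solves non-negative least squares of each bulk sample on the reference
    profiles over the reference's feature set, then projects onto the
    simplex by renormalizing to sum one — which also makes the estimate
    invariant to the bulk sample's library scale. Accepts a single sample
    (Series) or samples x features frame / layer; returns samples x
    cell-types proportions.
    """
    _check_reference(reference)
    if isinstance(bulk, OmicsLayer):
        bulk = bulk.values
    single = isinstance(bulk, pd.Series)
    frame = bulk.to_frame().T if single else pd.DataFrame(bulk)
    if not reference.index.isin(frame.columns).all():
        raise ValueError("reference features must be a subset of the bulk features")
    Xb = frame[reference.index].to_numpy(dtype=float)
    R = reference.to_numpy(dtype=float)
    props = np.empty((Xb.shape[0], R.shape[1]))
    for i, x in enumerate(Xb):
        q, _ = optimize.nnls(R, x)
        total = q.sum()
        props[i] = q / total if total > 0 else np.full(R.shape[1], 1.0 / R.shape[1])
    out = pd.DataFrame(props, index=frame.index, columns=reference.columns)
    return out.iloc[0] if single else out


def celltype_interaction_de(
    layer: OmicsLayer,
    outcome,
    covariates=None,
    proportions=None,
    size_factors=None,
    fast: bool = False,
):
    """Cell-type-aware differential expression with an outcome x proportion interaction.

    Per gene: NB GLM with design intercept + covariates + outcome +
    proportion + outcome*proportion. The interaction Wald test detects
    cell-type-specific differential expression; the outcome main effect is
    then interpreted at 0% of the cell type. Returns
    (interaction table, main-effect table), each BH-adjusted within its own
    family.
    """
    prop = np.asarray(proportions, dtype=float)
    if prop.ndim != 1 or prop.shape[0] != layer.n_samples:
        raise ValueError("proportions must be one cell-type column per sample")
    if (prop < 0).any() or (prop > 1).any():
        raise ValueError("proportions must lie in [0, 1]")
    if prop.std() == 0:
        if prop.max() == 0:
            # Degenerate-but-meaningful case: 0% everywhere, the interaction
            # drops out and the model reduces to the main-effect NB fit.
            main = nb_differential(
                layer, outcome, covariates, size_factors=size_factors, fast=fast
            )
            return main.assign(effect=0.0, se=np.nan, statistic=np.nan, p=np.nan, fdr=np.nan), main
        raise ValueError("constant proportion column: interaction unidentifiable")
    if prop.std() < 1e-3:
        warnings.warn("near-constant cell-type proportions: interaction poorly identified")

    if not layer.kind.is_counts:
        raise ValueError("celltype_interaction_de requires a count layer")
    Y = layer.values.to_numpy(dtype=float)
    n = Y.shape[0]
    y = np.asarray(outcome, dtype=float)
    X, _ = _build_design(n, y, covariates, extra={"proportion": prop, "interaction": y * prop})
    # reorder so columns end with [proportion, interaction, outcome] -> place
    # outcome before proportion for clarity of indices below
    if size_factors is None:
        _, factors = upper_quartile_normalize(layer)
        size_factors = factors.to_numpy()
    offset = np.log(np.asarray(size_factors, dtype=float))

    pois = _fastglm.nb_irls(X, Y, offset, phi=np.zeros(Y.shape[1]), max_iter=12)
    phi = _fastglm.nb_moment_dispersion(Y, pois["mu"], n_params=X.shape[1])
    if not fast:
        phi = _fastglm.nb_apl_dispersion(X, Y, pois["mu"])
    phi = _fastglm.shrink_dispersion_to_trend(phi, Y.mean(axis=0), n_samples=Y.shape[0])
    fit = _fastglm.nb_irls(X, Y, offset, phi=phi, beta0=pois["beta"], max_iter=25)
    inv_diag, _ = _fastglm._inv_diag(fit["gram"])

    tables = []
    # design column order: [..., proportion, interaction, outcome]
    for idx in (-2, -1):  # interaction term, then outcome main effect
        slope = fit["beta"][:, idx] / np.log(2.0)
        se = np.sqrt(np.maximum(inv_diag[:, idx], 1e-300)) / np.log(2.0)
        z = slope / se
        p = 2.0 * stats.norm.sf(np.abs(z))
        p[~fit["converged"] | ~np.isfinite(z)] = np.nan
        tables.append(differential_table(layer.feature_ids, slope, se, z, p, bh_adjust(p)))
    interaction_table, main_table = tables
    return interaction_table, main_table


def simulate_power(
    kind: str,
    effect_grid,
    mean: float = 100.0,
    dispersion: float = 0.1,
    m_sd: float = 0.5,
    n: int = 400,
    alpha: float = 0.05,
    n_reps: int = 200,
    seed: int = 0,
) -> pd.DataFrame:
    """Monte Carlo power of the per-feature tests across an effect-size grid.

    ``kind="counts"``: NB counts with the given mean and dispersion and a
    log2-fold-change effect per outcome SD, tested with the NB Wald path.
    ``kind="methylation"``: Gaussian M-values with noise SD ``m_sd`` and an
    M-value slope effect, tested with the robust moderated-t path. Power is
    the fraction of replicates with p < alpha.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be at least 1")
    if kind not in ("counts", "methylation"):
        raise ValueError("kind must be 'counts' or 'methylation'")
    rng = np.random.default_rng(seed)
    rows = []
    for effect in np.asarray(effect_grid, dtype=float):
        x = rng.normal(size=n)
        X = np.column_stack([np.ones(n), x])
        if kind == "counts":
            mu = mean * np.exp2(effect * x)[:, None] * np.ones((1, n_reps))
            Y = rng.negative_binomial(1.0 / dispersion, 1.0 / (1.0 + dispersion * mu)).astype(
                float
            )
            pois = _fastglm.nb_irls(X, Y, np.zeros(n), phi=np.zeros(n_reps), max_iter=12)
            phi = _fastglm.nb_moment_dispersion(Y, pois["mu"], n_params=2)
            fit = _fastglm.nb_irls(X, Y, np.zeros(n), phi=phi, beta0=pois["beta"])
            inv_diag, _ = _fastglm._inv_diag(fit["gram"])
            z = fit["beta"][:, -1] / np.sqrt(np.maximum(inv_diag[:, -1], 1e-300))
            p = 2.0 * stats.norm.sf(np.abs(z))
        else:
            Y = effect * x[:, None] + rng.normal(0.0, m_sd, size=(n, n_reps))
            fit = _fastglm.huber_fit(X, Y)
            s2_post, d0, _ = _fastglm.moderate_variances(fit["s2"], fit["df_resid"])
            t = fit["beta"][:, -1] / np.sqrt(s2_post * fit["inv_gram_diag"][:, -1])
            df = fit["df_resid"] if np.isinf(d0) else fit["df_resid"] + d0
            p = 2.0 * stats.t.sf(np.abs(t), df=df)
        rows.append({"effect": float(effect), "power": float(np.mean(p < alpha)), "n_reps": n_reps})
    return pd.DataFrame(rows)


def covariate_regression(phenotypes, alpha: float = 0.05) -> dict:
    """Multivariable OLS of SRS and of IQ on the eight clinical covariates.

    Returns per-outcome coefficient tables with Wald p-values, BH-adjusted
    p-values across the coefficients, and FDR-adjusted confidence intervals
    (false-coverage-rate correction: level 1 - R*alpha/m given R BH
    rejections), plus each model's adjusted R-squared.
    """
    import statsmodels.api as sm

    design = phenotypes.covariate_design(add_intercept=True)
    X = design.to_numpy(dtype=float)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient covariate design")
    out = {}
    for name in ("SRS", "IQ"):
        fit = sm.OLS(phenotypes.outcome(name).to_numpy(dtype=float), X).fit()
        keep = [i for i, c in enumerate(design.columns) if c != "intercept"]
        est, se = fit.params[keep], fit.bse[keep]
        p = fit.pvalues[keep]
        fdr = bh_adjust(p)
        m = len(keep)
        n_reject = int((fdr <= alpha).sum())
        level_alpha = max(n_reject, 1) * alpha / m
        crit = stats.t.ppf(1.0 - level_alpha / 2.0, df=fit.df_resid)
        out[name] = pd.DataFrame(
            {
                "term": [design.columns[i] for i in keep],
                "estimate": est,
                "se": se,
                "p": p,
                "fdr": fdr,
                "ci_low": est - crit * se,
                "ci_high": est + crit * se,
            }
        ).reset_index(drop=True)
        out[f"{name}_adj_r2"] = float(fit.rsquared_adj)
    return out
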