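"""Normalization and transformation stages applied before modeling.

Methylation is carried through the analysis on the M-value (logit) scale;
expression counts are filtered, upper-quartile normalized, variance
stabilized, and optionally corrected for one dimension of unwanted
variation estimated from empirical negative-control features.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin

from .datatypes import LayerKind, OmicsLayer

_BETA_EPS = 1e-6


def beta_from_intensities(m_intensity, u_intensity):
    """Methylation beta from allele intensities: beta = M / (U + M + 100).

    The +100 stabilizes the ratio at low total intensity. Vectorized over
    arrays of matching shape.
    """
    m = np.asarray(m_intensity, dtype=float)
    u = np.asarray(u_intensity, dtype=float)
    if (m < 0).any() or (u < 0).any():
        raise ValueError("intensities must be non-negative")
    return m / (u + m + 100.0)


def beta_to_m(beta):
    """Logit-transform beta values to M-values: M = log2(beta / (1 - beta)).

    Values outside (eps, 1-eps) are clipped with a warning; the analysis
    scale for array-derived methylation.
    """
    b = np.asarray(beta, dtype=float)
    if (b <= _BETA_EPS).any() or (b >= 1.0 - _BETA_EPS).any():
        warnings.warn("beta values clipped to [1e-6, 1 - 1e-6] before logit", stacklevel=2)
        b = np.clip(b, _BETA_EPS, 1.0 - _BETA_EPS)
    out = np.log2(b / (1.0 - b))
    if isinstance(beta, pd.DataFrame):
        return pd.DataFrame(out, index=beta.index, columns=beta.columns)
    return out


def m_to_beta(m):
    """Inverse of :func:`beta_to_m`."""
    m_arr = np.asarray(m, dtype=float)
    out = 1.0 / (1.0 + np.exp2(-m_arr))
    if isinstance(m, pd.DataFrame):
        return pd.DataFrame(out, index=m.index, columns=m.columns)
    return out


def seq_beta_to_m(beta, offset: float = 1.0):
    """Offset logit transform for sequencing-derived beta values.

    M = log2((beta + offset) / (1 - beta + offset)); finite at beta = 0 and 1,
    so suitable for bisulfite-sequencing fractions that reach the boundary.
    """
    if offset <= 0:
        raise ValueError("offset must be positive")
    b = np.asarray(beta, dtype=float)
    if (b < 0).any() or (b > 1).any():
        raise ValueError("beta values must lie in [0, 1]")
    out = np.log2((b + offset) / (1.0 - b + offset))
    if isinstance(beta, pd.DataFrame):
        return pd.DataFrame(out, index=beta.index, columns=beta.columns)
    return out


def filter_low_counts(layer: OmicsLayer, min_count: float = 5, min_variance: float = 0.5):
    """Drop features with uniformly low counts or near-constant counts.

    A feature is retained iff its maximum count across samples reaches
    ``min_count`` AND its across-sample variance reaches ``min_variance``.
    Returns the filtered layer and a removal report (feature_id, reason).
    """
    if not layer.kind.is_counts:
        raise ValueError("count filtering applies only to count layers")
    vals = layer.values.to_numpy(dtype=float)
    max_ok = vals.max(axis=0) >= min_count
    var_ok = vals.var(axis=0, ddof=1) >= min_variance
    keep = max_ok & var_ok
    reasons = np.where(
        ~max_ok & ~var_ok, "low_count;low_variance", np.where(~max_ok, "low_count", "low_variance")
    )
    report = pd.DataFrame(
        {"feature_id": layer.feature_ids[~keep], "reason": reasons[~keep]}
    ).reset_index(drop=True)
    filtered = OmicsLayer(values=layer.values.loc[:, keep], kind=layer.kind)
    return filtered, report


def upper_quartile_normalize(layer: OmicsLayer, sample_subset=None):
    """Upper-quartile library normalization.

    Each sample's scale factor is its 75th percentile over features with a
    nonzero count in that sample, divided by the geometric mean of those
    percentiles (over ``sample_subset`` if given, so training-fold geometry
    can be reused); scaled value = count / factor. Factors have geometric
    mean 1 (over the subset).
    """
    if not layer.kind.is_counts:
        raise ValueError("upper-quartile normalization applies to count layers")
    vals = layer.values.to_numpy(dtype=float)
    uq = np.empty(vals.shape[0])
    for i, row in enumerate(vals):
        nz = row[row > 0]
        if nz.size == 0:
            raise ValueError(f"sample {layer.sample_ids[i]!r} has all-zero counts")
        uq[i] = np.quantile(nz, 0.75)
    ref = uq if sample_subset is None else uq[np.asarray(sample_subset)]
    factors = uq / np.exp(np.mean(np.log(ref)))
    scaled = pd.DataFrame(
        vals / factors[:, None], index=layer.sample_ids, columns=layer.feature_ids
    )
    out = OmicsLayer.__new__(OmicsLayer)  # scaled values are no longer integers
    out.values, out.kind = scaled, LayerKind.normalized_expression
    return out, pd.Series(factors, index=layer.sample_ids, name="uq_factor")


def variance_stabilize(scaled):
    """Variance-flattening transform for normalized counts: log2(x + 0.5).

    Monotone; maps 0 to -1. Accepts an OmicsLayer or a DataFrame.
    """
    if isinstance(scaled, OmicsLayer):
        df = scaled.values
    else:
        df = scaled
    if (df.to_numpy() < 0).any():
        raise ValueError("variance stabilization expects non-negative values")
    out = np.log2(df + 0.5)
    layer = OmicsLayer.__new__(OmicsLayer)
    layer.values, layer.kind = out, LayerKind.normalized_expression
    return layer


def select_control_features(layer: OmicsLayer, outcomes: pd.DataFrame, n_controls: int):
    """Pick empirical negative-control features.

    Scores each feature by a simple linear association test against every
    outcome column (SRS and IQ) and returns the ``n_controls`` features whose
    *minimum* p-value across outcomes is largest — i.e. the features least
    associated with any outcome of interest. Ties break by feature identifier.
    """
    if n_controls >= layer.n_features:
        raise ValueError("n_controls must be smaller than the feature count")
    x = layer.values.to_numpy(dtype=float)
    n = x.shape[0]
    xc = x - x.mean(axis=0)
    xsd = xc.std(axis=0)
    xsd[xsd == 0] = np.inf  # constant features: r = 0 -> p = 1, ideal controls
    min_p = np.ones(x.shape[1])
    for col in outcomes.columns:
        y = outcomes[col].to_numpy(dtype=float)
        yc = y - y.mean()
        r = (xc * yc[:, None]).sum(axis=0) / (n * xsd * yc.std() + 1e-300)
        r = np.clip(r, -0.999999999, 0.999999999)
        t = r * np.sqrt((n - 2) / (1 - r**2))
        p = 2 * stats.t.sf(np.abs(t), df=n - 2)
        min_p = np.minimum(min_p, p)
    order = pd.DataFrame({"p": -min_p, "fid": layer.feature_ids}).sort_values(
        ["p", "fid"], kind="mergesort"
    )
    return pd.Index(order["fid"].iloc[:n_controls])


class RUVCorrection(BaseEstimator, TransformerMixin):
    """Remove-unwanted-variation correction from negative-control features.

    Fitting takes the top-``k`` left singular vectors of the feature-centered
    control submatrix (samples x controls) as unwanted factors, then records
    per-feature regressions on those factors. Transforming subtracts the
    fitted factor contribution, returning residuals plus feature means.

    Parameters
    ----------
    control_features : sequence of feature identifiers
    k : int, number of unwanted-variation dimensions (k=0 is the identity)
    """

    def __init__(self, control_features=None, k: int = 1):
        self.control_features = control_features
        self.k = k

    def fit(self, X: pd.DataFrame, y=None):
        controls = pd.Index(self.control_features)
        if not controls.isin(X.columns).all():
            raise ValueError("control features must be a subset of the layer features")
        if self.k >= X.shape[0]:
            raise ValueError("k must be smaller than the number of samples")
        if len(controls) < self.k + 1:
            raise ValueError("need at least k+1 control features")
        self.feature_names_in_ = X.columns
        if self.k == 0:
            self.factors_ = np.empty((X.shape[0], 0))
        else:
            c = X[controls].to_numpy(dtype=float)
            c = c - c.mean(axis=0)
            u, s, _ = np.linalg.svd(c, full_matrices=False)
            self.factors_ = u[:, : self.k]
        self.mean_ = X.to_numpy(dtype=float).mean(axis=0)
        if self.k:
            xc = X.to_numpy(dtype=float) - self.mean_
            self.coef_ = self.factors_.T @ xc  # factors are orthonormal
        else:
            self.coef_ = np.empty((0, X.shape[1]))
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not X.columns.equals(self.feature_names_in_):
            raise ValueError("feature mismatch between fit and transform")
        xc = X.to_numpy(dtype=float) - self.mean_
        resid = xc - self.factors_ @ self.coef_
        return pd.DataFrame(resid + self.mean_, index=X.index, columns=X.columns)


def remove_unwanted_variation(layer, control_features, k: int = 1):
    """Functional wrapper over :class:`RUVCorrection`.

    Returns (adjusted layer, factor matrix samples x k).
    """
    df = layer.values if isinstance(layer, OmicsLayer) else layer
    ruv = RUVCorrection(control_features=control_features, k=k).fit(df)
    adjusted = ruv.transform(df)
    out = OmicsLayer.__new__(OmicsLayer)
    out.values, out.kind = adjusted, LayerKind.normalized_expression
    return out, ruv.factors_


@dataclass
class ResidualFit:
    """Stored OLS projection so held-out samples reuse training coefficients."""

    coef: np.ndarray  # design columns x targets
    design_columns: pd.Index
    target_columns: pd.Index | None


class CovariateResidualizer(BaseEstimator):
    """OLS residualization of outcomes or feature matrices on covariates.

    Coefficients estimated at fit time are reused on new samples, so
    held-out data never contributes to the projection (no leakage in CV).
    """

    def fit(self, design: pd.DataFrame, target):
        d = np.asarray(design, dtype=float)
        rank = np.linalg.matrix_rank(d)
        if rank < d.shape[1]:
            _, r, piv = _qr_pivot(d)
            aliased = [design.columns[j] for j in piv[rank:]]
            raise ValueError(f"rank-deficient covariate design; aliased columns: {aliased}")
        t = np.asarray(target, dtype=float)
        t2 = t[:, None] if t.ndim == 1 else t
        coef, *_ = np.linalg.lstsq(d, t2, rcond=None)
        self.fit_ = ResidualFit(
            coef=coef,
            design_columns=pd.Index(design.columns),
            target_columns=getattr(target, "columns", None),
        )
        return self

    def transform(self, design: pd.DataFrame, target):
        if not pd.Index(design.columns).equals(self.fit_.design_columns):
            raise ValueError("design columns differ from the fitted design")
        d = np.asarray(design, dtype=float)
        t = np.asarray(target, dtype=float)
        squeeze = t.ndim == 1
        t2 = t[:, None] if squeeze else t
        resid = t2 - d @ self.fit_.coef
        if squeeze:
            resid = resid[:, 0]
            if isinstance(target, pd.Series):
                return pd.Series(resid, index=target.index, name=target.name)
            return resid
        if isinstance(target, pd.DataFrame):
            return pd.DataFrame(resid, index=target.index, columns=target.columns)
        return resid

    def fit_transform(self, design, target):
        return self.fit(design, target).transform(design, target)


def _qr_pivot(a):
    from scipy.linalg import qr

    q, r, piv = qr(a, pivoting=True, mode="economic")
    return q, r, piv


def residualize(target, covariate_design: pd.DataFrame):
    """Residualize a vector or matrix on a covariate design.

    Returns (residuals, fitted residualizer); apply the residualizer's
    ``transform`` to held-out samples with training coefficients.
    """
    res = CovariateResidualizer()
    out = res.fit_transform(covariate_design, target)
    return out, res
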