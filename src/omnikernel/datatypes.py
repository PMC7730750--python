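"""Shared data containers for the multi-omic kernel pipeline.

The pipeline moves three kinds of objects between stages: per-layer
sample x feature matrices (:class:`OmicsLayer`), the per-sample clinical
table (:class:`PhenotypeTable`), and sample-similarity kernels
(:class:`KernelMatrix`).  All are thin, validated wrappers around pandas /
numpy objects so that downstream code can rely on aligned, uniquely
labelled samples without re-checking.
"""

from __future__ import annotations

import enum
import io
import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd


class LayerKind(str, enum.Enum):
    """What scale a molecular layer is on."""

    methylation_beta = "methylation_beta"
    methylation_m = "methylation_m"
    mrna_counts = "mrna_counts"
    mirna_counts = "mirna_counts"
    normalized_expression = "normalized_expression"

    @property
    def is_counts(self) -> bool:
        return self in (LayerKind.mrna_counts, LayerKind.mirna_counts)


#: Clinical covariates adjusted for throughout: self-reported race, infant sex,
#: maternal age (years), gestational age (days), maternal smoking, insurance
#: (Medicaid vs private), chorion inflammation, and birthweight Z-score.
COVARIATE_COLUMNS = (
    "race",
    "sex",
    "maternal_age",
    "gestational_days",
    "smoking",
    "insurance",
    "chorion_inflammation",
    "birthweight_Z",
)

CATEGORICAL_COVARIATES = {
    "race": ("White", "Black", "Other"),
    "sex": ("Female", "Male"),
    "smoking": ("No", "Yes"),
    "insurance": ("Private", "Medicaid"),
    "chorion_inflammation": ("No", "Yes"),
}

#: Fixed column order for differential-analysis result tables.
DIFFERENTIAL_COLUMNS = ("feature_id", "effect", "se", "statistic", "p", "fdr")


@dataclass
class OmicsLayer:
    """One sample x feature molecular matrix with stable identifiers."""

    values: pd.DataFrame  # samples x features
    kind: LayerKind

    def __post_init__(self) -> None:
        self.kind = LayerKind(self.kind)
        idx, cols = self.values.index, self.values.columns
        if idx.has_duplicates:
            raise ValueError("duplicated sample identifiers in layer")
        if cols.has_duplicates:
            raise ValueError("duplicated feature identifiers in layer")
        vals = self.values.to_numpy()
        if self.kind is LayerKind.methylation_beta:
            if not ((vals > 0.0).all() and (vals < 1.0).all()):
                raise ValueError("beta values must lie strictly in (0, 1)")
        elif self.kind.is_counts:
            if (vals < 0).any() or not np.allclose(vals, np.round(vals)):
                raise ValueError(f"{self.kind.value} layer must contain non-negative integers")

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.index

    @property
    def feature_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def to_tsv_gz(self, path) -> None:
        """Write as gzipped TSV, features x samples with a sample-ID header row."""
        self.values.T.to_csv(path, sep="\t", compression="infer")

    @classmethod
    def from_tsv_gz(cls, path, kind: LayerKind) -> "OmicsLayer":
        df = pd.read_csv(path, sep="\t", index_col=0, compression="infer")
        return cls(values=df.T, kind=kind)


@dataclass
class PhenotypeTable:
    """Per-sample outcomes (SRS, IQ), ASD label and clinical covariates.

    SRS is the Social Responsiveness Scale score (higher = more social
    impairment); IQ is the cognitive ability score; ASD the binary case
    label used only for validation.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"SRS", "IQ", "ASD", *COVARIATE_COLUMNS}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"phenotype table missing columns: {sorted(missing)}")
        if self.data.index.has_duplicates:
            raise ValueError("duplicated sample identifiers in phenotype table")
        if self.data[list(required)].isna().any().any():
            bad = self.data.columns[self.data.isna().any()].tolist()
            raise ValueError(f"missing values in phenotype columns: {bad}")
        for col, levels in CATEGORICAL_COVARIATES.items():
            extra = set(self.data[col].unique()) - set(levels)
            if extra:
                raise ValueError(f"undeclared levels in {col}: {sorted(extra)}")
        if not set(np.unique(self.data["ASD"])) <= {0, 1}:
            raise ValueError("ASD must be binary 0/1")

    @property
    def sample_ids(self) -> pd.Index:
        return self.data.index

    def outcome(self, name: str) -> pd.Series:
        if name.upper() not in ("SRS", "IQ"):
            raise KeyError(f"unknown outcome {name!r}; expected SRS or IQ")
        return self.data[name.upper()]

    def covariate_design(self, add_intercept: bool = True) -> pd.DataFrame:
        """One-hot covariate design with declared reference levels dropped."""
        parts = []
        for col in COVARIATE_COLUMNS:
            if col in CATEGORICAL_COVARIATES:
                levels = CATEGORICAL_COVARIATES[col]
                cat = pd.Categorical(self.data[col], categories=levels)
                dummies = pd.get_dummies(cat, prefix=col, dtype=float).iloc[:, 1:]
                dummies.index = self.data.index
                parts.append(dummies)
            else:
                parts.append(self.data[[col]].astype(float))
        design = pd.concat(parts, axis=1)
        if add_intercept:
            design.insert(0, "intercept", 1.0)
        return design


def check_aligned_samples(*objs) -> pd.Index:
    """Assert identical, identically ordered sample IDs across layers/phenotypes."""
    ids = None
    for obj in objs:
        cur = obj.sample_ids if hasattr(obj, "sample_ids") else pd.Index(obj)
        if ids is None:
            ids = cur
        elif not ids.equals(cur):
            raise ValueError("sample identifiers differ or are ordered differently")
    return ids


@dataclass
class KernelMatrix:
    """Symmetric PSD sample-similarity matrix with provenance."""

    values: np.ndarray
    sample_ids: Sequence
    family: str  # "linear" | "gaussian"
    bandwidth: float | None = None
    source: list = field(default_factory=list)
    standardization: dict | None = None  # {"features": [...], "mean": arr, "sd": arr}

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = self.values.shape[0]
        if self.values.shape != (n, n):
            raise ValueError("kernel matrix must be square")
        if len(self.sample_ids) != n:
            raise ValueError("sample_ids length does not match kernel size")
        if self.family not in ("linear", "gaussian"):
            raise ValueError(f"unknown kernel family {self.family!r}")
        asym = np.abs(self.values - self.values.T).max() if n else 0.0
        if asym > 1e-10 * max(1.0, np.abs(self.values).max()):
            raise ValueError("kernel matrix is not symmetric")
        self.values = 0.5 * (self.values + self.values.T)

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def eigenvalue_floor_ok(self, rel_tol: float = 1e-8) -> bool:
        w = np.linalg.eigvalsh(self.values)
        return w.min() >= -rel_tol * max(w.max(), 1e-300)

    def trace_normalized(self) -> "KernelMatrix":
        """Rescale so the trace equals n (puts kernels on a common scale)."""
        tr = np.trace(self.values)
        if tr <= 0:
            raise ValueError("kernel trace must be positive for normalization")
        return KernelMatrix(
            values=self.values * (self.n / tr),
            sample_ids=self.sample_ids,
            family=self.family,
            bandwidth=self.bandwidth,
            source=list(self.source),
            standardization=self.standardization,
        )


@dataclass
class CVReport:
    """Per-fold adjusted R-squared for one model configuration."""

    model_spec: dict
    fold_r2: list
    fold_seeds: list
    fold_test_indices: list
    failures: list = field(default_factory=list)

    @property
    def mean_r2(self) -> float:
        return float(np.mean(self.fold_r2))

    @property
    def sd_r2(self) -> float:
        return float(np.std(self.fold_r2, ddof=1)) if len(self.fold_r2) > 1 else 0.0

    def to_json(self) -> str:
        return json.dumps(
            {
                "model_spec": self.model_spec,
                "fold_r2": [float(v) for v in self.fold_r2],
                "fold_seeds": [int(s) for s in self.fold_seeds],
                "fold_test_indices": [list(map(int, ix)) for ix in self.fold_test_indices],
                "failures": self.failures,
                "mean_r2": self.mean_r2,
                "sd_r2": self.sd_r2,
            },
            indent=1,
        )


def differential_table(feature_ids, effect, se, statistic, p, fdr) -> pd.DataFrame:
    """Assemble a differential-result table in the fixed column order."""
    df = pd.DataFrame(
        {
            "feature_id": np.asarray(feature_ids),
            "effect": np.asarray(effect, dtype=float),
            "se": np.asarray(se, dtype=float),
            "statistic": np.asarray(statistic, dtype=float),
            "p": np.asarray(p, dtype=float),
            "fdr": np.asarray(fdr, dtype=float),
        }
    )
    return df[list(DIFFERENTIAL_COLUMNS)]
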