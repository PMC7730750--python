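"""Synthetic multi-omic cohort generator.

Emulates the statistical structure of an extremely-preterm birth cohort
with placental molecular data: three sample-aligned layers (CpG
methylation beta values, mRNA counts, miRNA counts), clinical covariates
drawn from the published marginals of such a cohort (52.5% male, 10.3%
maternal smoking, 33.8% Medicaid, ...), continuous SRS and IQ outcomes
driven by correlated latent traits (default Pearson correlation -0.47),
and an ASD label derived from SRS/IQ by a thresholded logistic so that
case status is an *emergent* property the prediction models can be
validated against.

Causal features load linearly on the latent traits: CpGs on the M (logit)
scale, count features on the log2 mean. Everything is deterministic given
the seed, and the full generating truth is recorded for oracle tests.
"""

from __future__ import annotations

import json
import math
import pathlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .datatypes import LayerKind, OmicsLayer, PhenotypeTable, check_aligned_samples
from .preprocess import m_to_beta

#: Sign pattern and magnitudes of the clinical covariate effects on
#: (SRS, IQ), on the design-matrix coding of PhenotypeTable.covariate_design.
#: Medicaid insurance raises SRS and lowers IQ; male sex lowers IQ; etc.
DEFAULT_COVARIATE_EFFECTS = {
    "race_Black": (0.219, -0.369),
    "race_Other": (0.375, -0.113),
    "sex_Male": (0.119, -0.288),
    "maternal_age": (-0.002, -0.003),
    "gestational_days": (-0.017, 0.012),
    "smoking_Yes": (0.215, 0.337),
    "insurance_Medicaid": (0.454, -0.453),
    "chorion_inflammation_Yes": (-0.042, -0.046),
    "birthweight_Z": (-0.060, 0.179),
}

_LAYER_NAMES = ("cpg", "mrna", "mirna")


@dataclass
class SimulationConfig:
    """Generating parameters for a synthetic cohort.

    Defaults are desk-scale: 400 samples with 5,000 CpGs, 2,000 mRNAs and
    800 miRNAs standing in for the full genome-wide panels. Effect sizes
    are in latent-trait SD units (M-value shift for CpGs, log2-fold for
    counts). ``latent_structure`` controls whether all layers reflect one
    shared latent pair ("shared") or each layer carries its own independent
    component of the outcome latent ("per_layer", signal split evenly).
    """

    n_samples: int = 400
    n_cpg: int = 5000
    n_mrna: int = 2000
    n_mirna: int = 800
    n_causal: dict = field(default_factory=lambda: {"cpg": 200, "mrna": 100, "mirna": 50})
    effect_size_sd: dict = field(
        default_factory=lambda: {"cpg": 0.25, "mrna": 0.15, "mirna": 0.15}
    )
    latent_effect: float = 0.6
    outcome_noise_sd: float = 0.9
    srs_iq_latent_correlation: float = -0.47
    asd_prevalence: float = 0.093
    covariate_effects: dict = field(default_factory=lambda: dict(DEFAULT_COVARIATE_EFFECTS))
    nb_dispersion_range: tuple = (0.05, 0.5)
    beta_precision_range: tuple = (20.0, 60.0)
    n_celltypes: int = 4
    latent_structure: str = "shared"  # "shared" | "per_layer"
    seed: int = 0

    def __post_init__(self) -> None:
        for name, n_feat in zip(_LAYER_NAMES, (self.n_cpg, self.n_mrna, self.n_mirna)):
            if self.n_causal.get(name, 0) > n_feat:
                raise ValueError(f"n_causal[{name!r}] exceeds the layer feature count")
        if not (0.0 < self.asd_prevalence < 1.0):
            raise ValueError("asd_prevalence must lie in (0, 1)")
        if not (-1.0 <= self.srs_iq_latent_correlation <= 1.0):
            raise ValueError("srs_iq_latent_correlation must lie in [-1, 1]")
        scalars = [
            self.outcome_noise_sd,
            self.latent_effect,
            *self.effect_size_sd.values(),
            *self.nb_dispersion_range,
            *self.beta_precision_range,
        ]
        if not np.all(np.isfinite(scalars)):
            raise ValueError("non-finite value in simulation config")
        if self.outcome_noise_sd < 0 or any(v < 0 for v in self.effect_size_sd.values()):
            raise ValueError("standard deviations must be non-negative")
        if self.latent_structure not in ("shared", "per_layer"):
            raise ValueError("latent_structure must be 'shared' or 'per_layer'")
        if min(self.nb_dispersion_range) <= 0 or min(self.beta_precision_range) <= 0:
            raise ValueError("dispersion and precision ranges must be positive")


@dataclass
class SyntheticCohort:
    """Sample-aligned layers, phenotypes, cell-type proportions and truth."""

    layers: dict  # {"cpg": OmicsLayer, "mrna": OmicsLayer, "mirna": OmicsLayer}
    phenotypes: PhenotypeTable
    celltype_proportions: pd.DataFrame
    truth: dict

    def __post_init__(self) -> None:
        check_aligned_samples(*self.layers.values(), self.phenotypes)
        props = self.celltype_proportions.to_numpy()
        if (props < 0).any() or np.abs(props.sum(axis=1) - 1.0).max() > 1e-9:
            raise ValueError("cell-type proportion rows must lie on the simplex")

    @property
    def sample_ids(self) -> pd.Index:
        return self.phenotypes.sample_ids


def _draw_loadings(rng: np.random.Generator, k: int, sd: float) -> np.ndarray:
    """Causal loadings: random sign, half-normal magnitude floored at 0.3 sd
    so every designated causal feature carries real signal."""
    mag = 0.3 * sd + np.abs(rng.normal(0.0, sd, k))
    return np.where(rng.random(k) < 0.5, -mag, mag)


def _draw_covariates(rng: np.random.Generator, n: int, index: pd.Index) -> pd.DataFrame:
    race = rng.choice(["White", "Black", "Other"], size=n, p=[0.615, 0.295, 0.090])
    return pd.DataFrame(
        {
            "race": race,
            "sex": np.where(rng.random(n) < 0.525, "Male", "Female"),
            "maternal_age": rng.normal(29.6, 6.61, n),
            "gestational_days": rng.normal(182.5, 9.17, n),
            "smoking": np.where(rng.random(n) < 0.103, "Yes", "No"),
            "insurance": np.where(rng.random(n) < 0.338, "Medicaid", "Private"),
            "chorion_inflammation": np.where(rng.random(n) < 0.336, "Yes", "No"),
            "birthweight_Z": rng.normal(0.0, 1.0, n),
        },
        index=index,
    )


def _assign_asd(rng, srs, iq, prevalence, slope: float = 1.5):
    """Bernoulli(ASD) with logistic probability in standardized SRS - IQ,
    intercept solved so the mean probability hits the target prevalence."""
    score = (srs - srs.mean()) / srs.std() - (iq - iq.mean()) / iq.std()
    lo, hi = -30.0, 30.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if expit(mid + slope * score).mean() < prevalence:
            lo = mid
        else:
            hi = mid
    prob = expit(0.5 * (lo + hi) + slope * score)
    return rng.binomial(1, prob), prob


def generate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Generate a full synthetic cohort; deterministic given ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    n = config.n_samples
    sample_ids = pd.Index([f"S{i:04d}" for i in range(n)], name="sample_id")

    cov = _draw_covariates(rng, n, sample_ids)

    # Latent traits: B blocks; each layer reads one block so signal can be
    # split across layers ("per_layer") or fully shared ("shared").
    rho = config.srs_iq_latent_correlation
    n_blocks = 3 if config.latent_structure == "per_layer" else 1
    U = rng.normal(size=(n, n_blocks))
    V = rng.normal(size=(n, n_blocks))
    W = rho * U + math.sqrt(max(0.0, 1.0 - rho**2)) * V
    g_srs = U.sum(axis=1) / math.sqrt(n_blocks)
    g_iq = W.sum(axis=1) / math.sqrt(n_blocks)

    # Outcomes = covariate effects + latent trait + noise.
    design = PhenotypeTable.__new__(PhenotypeTable)
    design.data = cov.assign(SRS=0.0, IQ=0.0, ASD=0)
    C = design.covariate_design(add_intercept=False)
    beta_srs = np.array([config.covariate_effects.get(c, (0.0, 0.0))[0] for c in C.columns])
    beta_iq = np.array([config.covariate_effects.get(c, (0.0, 0.0))[1] for c in C.columns])
    # Outcome noise shares the configured correlation: SRS and IQ co-vary
    # through non-molecular sources too, so the configured value is the
    # correlation of the whole non-covariate part (and hence close to the
    # observed SRS-IQ correlation when covariate effects are modest).
    e1 = rng.normal(size=n)
    e2 = rho * e1 + math.sqrt(max(0.0, 1.0 - rho**2)) * rng.normal(size=n)
    srs = C.to_numpy() @ beta_srs + config.latent_effect * g_srs
    iq = C.to_numpy() @ beta_iq + config.latent_effect * g_iq
    srs = srs + config.outcome_noise_sd * e1
    iq = iq + config.outcome_noise_sd * e2

    truth = {
        "latents": {"g_srs": g_srs, "g_iq": g_iq, "U": U, "W": W},
        "config": config,
        "layers": {},
    }
    layers = {}

    # --- CpG methylation: Beta-distributed with bimodal means; causal
    # effects applied on the M (logit) scale, then mapped back to beta.
    f_cpg = config.n_cpg
    block = {"cpg": 0, "mrna": min(1, n_blocks - 1), "mirna": min(2, n_blocks - 1)}
    comp = rng.choice(3, size=f_cpg, p=[0.4, 0.4, 0.2])
    a_par = np.choose(comp, [2.0, 8.0, 5.0])
    b_par = np.choose(comp, [8.0, 2.0, 5.0])
    mean_beta = np.clip(rng.beta(a_par, b_par), 0.03, 0.97)
    precision = rng.uniform(*config.beta_precision_range, f_cpg)
    beta_vals = rng.beta(mean_beta * precision, (1.0 - mean_beta) * precision, size=(n, f_cpg))
    beta_vals = np.clip(beta_vals, 1e-5, 1.0 - 1e-5)
    m_vals = np.log2(beta_vals / (1.0 - beta_vals))
    k = config.n_causal["cpg"]
    causal_idx = rng.choice(f_cpg, size=k, replace=False)
    load_s = _draw_loadings(rng, k, config.effect_size_sd["cpg"])
    load_i = _draw_loadings(rng, k, config.effect_size_sd["cpg"])
    b = block["cpg"]
    m_vals[:, causal_idx] += np.outer(U[:, b], load_s) + np.outer(W[:, b], load_i)
    beta_vals = np.clip(m_to_beta(m_vals), 1e-9, 1.0 - 1e-9)
    cpg_ids = pd.Index([f"cg{i:07d}" for i in range(f_cpg)])
    layers["cpg"] = OmicsLayer(
        values=pd.DataFrame(beta_vals, index=sample_ids, columns=cpg_ids),
        kind=LayerKind.methylation_beta,
    )
    truth["layers"]["cpg"] = {
        "causal_ids": cpg_ids[causal_idx].tolist(),
        "loading_srs": load_s,
        "loading_iq": load_i,
        "mean_beta": mean_beta,
        "precision": precision,
        "block": b,
    }

    # --- Count layers: NB with log-normal library sizes; causal effects on
    # the log2 mean.
    for name, f_lay, prefix, kind in (
        ("mrna", config.n_mrna, "gene", LayerKind.mrna_counts),
        ("mirna", config.n_mirna, "mir", LayerKind.mirna_counts),
    ):
        log2_mean = rng.normal(5.0, 2.0, f_lay).clip(0.5, 12.0)
        size_fac = np.exp(rng.normal(0.0, 0.15, n))
        phi = rng.uniform(*config.nb_dispersion_range, f_lay)
        k = config.n_causal[name]
        causal_idx = rng.choice(f_lay, size=k, replace=False)
        load_s = _draw_loadings(rng, k, config.effect_size_sd[name])
        load_i = _draw_loadings(rng, k, config.effect_size_sd[name])
        b = block[name]
        log2mu = np.broadcast_to(log2_mean, (n, f_lay)).copy()
        log2mu[:, causal_idx] += np.outer(U[:, b], load_s) + np.outer(W[:, b], load_i)
        mu = size_fac[:, None] * np.exp2(log2mu)
        counts = rng.negative_binomial(n=1.0 / phi, p=1.0 / (1.0 + phi * mu))
        ids = pd.Index([f"{prefix}{i:05d}" for i in range(f_lay)])
        layers[name] = OmicsLayer(
            values=pd.DataFrame(counts, index=sample_ids, columns=ids), kind=kind
        )
        truth["layers"][name] = {
            "causal_ids": ids[causal_idx].tolist(),
            "loading_srs": load_s,
            "loading_iq": load_i,
            "log2_mean": log2_mean,
            "dispersion": phi,
            "size_factors": size_fac,
            "block": b,
        }

    asd, asd_prob = _assign_asd(rng, srs, iq, config.asd_prevalence)
    truth["asd_probability"] = asd_prob
    pheno = PhenotypeTable(data=cov.assign(SRS=srs, IQ=iq, ASD=asd))

    alpha = 5.0 / (1.0 + np.arange(config.n_celltypes))
    props = rng.dirichlet(alpha, size=n)
    prop_df = pd.DataFrame(
        props,
        index=sample_ids,
        columns=[f"celltype_{j}" for j in range(config.n_celltypes)],
    )
    return SyntheticCohort(
        layers=layers, phenotypes=pheno, celltype_proportions=prop_df, truth=truth
    )


def generate_reference_profiles(
    n_features: int, n_celltypes: int, separation: float, seed: int
) -> pd.DataFrame:
    """Reference expression profiles (features x cell types), non-negative.

    Mimics aggregated single-cell profiles of placental cell types
    (trophoblast subtypes and stromal cells): a shared baseline plus
    disjoint marker blocks per cell type whose magnitude is set by
    ``separation``. Columns are guaranteed identifiable (full column rank,
    pairwise cosine similarity bounded away from 1).
    """
    if n_celltypes < 2:
        raise ValueError("need at least 2 cell types")
    if separation <= 0:
        raise ValueError("separation must be positive (zero is non-identifiable)")
    rng = np.random.default_rng(seed)
    base = rng.gamma(2.0, 3.0, n_features)
    ref = np.tile(base[:, None], (1, n_celltypes)) * rng.uniform(
        0.8, 1.2, (n_features, n_celltypes)
    )
    n_markers = max(3, n_features // (3 * n_celltypes))
    for k in range(n_celltypes):
        rows = slice(k * n_markers, (k + 1) * n_markers)
        ref[rows, k] += separation * rng.gamma(3.0, 3.0, n_markers)
    cols = [f"celltype_{j}" for j in range(n_celltypes)]
    df = pd.DataFrame(ref, index=[f"gene{i:05d}" for i in range(n_features)], columns=cols)
    norm = df.to_numpy() / np.linalg.norm(df.to_numpy(), axis=0)
    gram = norm.T @ norm
    off = gram[~np.eye(n_celltypes, dtype=bool)]
    if np.linalg.matrix_rank(df.to_numpy()) < n_celltypes or off.max() > 0.999:
        raise ValueError("reference profiles are not identifiable at this separation")
    return df


def generate_external_methylation(
    cohort_truth: dict,
    n_samples: int = 47,
    n_cases: int = 24,
    attenuation: float = 1.0,
    seed: int = 0,
    n_features_kept: int | None = None,
):
    """External methylation-only validation set sharing the cohort's causal directions.

    New samples are drawn from the cohort's per-CpG Beta baselines; causal
    CpGs receive the cohort's loadings scaled by ``attenuation`` applied to
    label-shifted latent traits (cases: higher SRS latent, lower IQ
    latent). Returns (OmicsLayer of M-values, binary label Series).
    ``n_features_kept`` subsamples the CpG panel to exercise
    feature-intersection logic downstream.
    """
    if not (0.0 <= attenuation <= 1.0):
        raise ValueError("attenuation must lie in [0, 1]")
    if n_cases > n_samples:
        raise ValueError("n_cases cannot exceed n_samples")
    rng = np.random.default_rng(seed)
    info = cohort_truth["layers"]["cpg"]
    mean_beta = np.asarray(info["mean_beta"])
    precision = np.asarray(info["precision"])
    f = mean_beta.size
    cpg_ids = pd.Index([f"cg{i:07d}" for i in range(f)])

    labels = np.zeros(n_samples, dtype=int)
    labels[rng.choice(n_samples, size=n_cases, replace=False)] = 1
    shift = 1.0
    g_srs = rng.normal(shift * labels, 1.0)
    g_iq = rng.normal(-shift * labels, 1.0)

    beta_vals = rng.beta(mean_beta * precision, (1.0 - mean_beta) * precision, size=(n_samples, f))
    beta_vals = np.clip(beta_vals, 1e-5, 1.0 - 1e-5)
    m_vals = np.log2(beta_vals / (1.0 - beta_vals))
    causal_pos = cpg_ids.get_indexer(info["causal_ids"])
    m_vals[:, causal_pos] += attenuation * (
        np.outer(g_srs, np.asarray(info["loading_srs"]))
        + np.outer(g_iq, np.asarray(info["loading_iq"]))
    )
    sample_index = pd.Index([f"EXT{i:03d}" for i in range(n_samples)], name="sample_id")
    df = pd.DataFrame(m_vals, index=sample_index, columns=cpg_ids)
    if n_features_kept is not None and n_features_kept < f:
        keep = np.sort(rng.choice(f, size=n_features_kept, replace=False))
        df = df.iloc[:, keep]
    layer = OmicsLayer(values=df, kind=LayerKind.methylation_m)
    return layer, pd.Series(labels, index=sample_index, name="ASD")


def save_cohort(cohort: SyntheticCohort, out_dir) -> None:
    """Write layers as gzipped TSV, phenotypes as CSV and causal truth as JSON."""
    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, layer in cohort.layers.items():
        layer.to_tsv_gz(out / f"{name}.tsv.gz")
    cohort.phenotypes.data.to_csv(out / "phenotypes.csv")
    cohort.celltype_proportions.to_csv(out / "celltype_proportions.csv")
    slim = {
        name: {
            "causal_ids": info["causal_ids"],
            "loading_srs": np.asarray(info["loading_srs"]).tolist(),
            "loading_iq": np.asarray(info["loading_iq"]).tolist(),
        }
        for name, info in cohort.truth["layers"].items()
    }
    (out / "truth.json").write_text(json.dumps(slim, indent=1))
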