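# Methods

This note documents the statistical models, numerical choices and known
limitations of `omnikernel`. It describes what the code computes; every
empirical statement here is one the test suite or `scripts/acceptance.py`
computes itself.

## 1. Synthetic cohorts

`simulate.generate_cohort` emulates the structure of an extremely-preterm
birth cohort with placental multi-omics and age-10 neurodevelopmental
outcomes. Nothing downstream depends on real data; the generator is
first-class, tested code whose recorded truth powers the oracle tests.

**Covariates** are drawn from published cohort marginals: race
White/Black/Other at 0.615/0.295/0.090, male sex 0.525, maternal age
N(29.6, 6.61) years, gestational age N(182.5, 9.17) days, smoking 0.103,
Medicaid insurance 0.338, chorion inflammation 0.336, birthweight Z-score
N(0, 1). Their default effects on SRS and IQ copy the sign pattern and
magnitudes reported for such cohorts (e.g. Medicaid +0.45 SRS / -0.45 IQ,
male sex -0.29 IQ, birthweight Z +0.18 IQ).

**Outcomes and latent traits.** Two correlated standard-normal traits drive
SRS and IQ:

    SRS = C b_s + g * G_s + sigma * e_s
    IQ  = C b_i + g * G_i + sigma * e_i

with `corr(G_s, G_i) = corr(e_s, e_i) = rho` (default -0.47). Correlating
the residual pair as well as the latent pair reflects that SRS and IQ share
non-molecular sources of covariance; with the defaults the *observed*
SRS-IQ Pearson correlation lands near -0.47 rather than a noise-diluted
fraction of it. Defaults `g = 0.6`, `sigma = 0.9` put the
molecularly-recoverable share of non-covariate outcome variance at ~0.3, so
that desk-scale kernel models reach cross-validated R-squared in the 0.1-0.3
range — detectable but modest, as in real placenta-neurodevelopment data.
With `latent_structure="per_layer"` the trait decomposes into three
independent components read by one layer each, so the signal is split
evenly across layers; `"shared"` (default) lets all layers reflect the same
trait.

**Molecular layers.** CpG beta values are Beta-distributed around bimodal
feature means (precision uniform on 20-60); causal effects are applied on
the M = log2(beta/(1-beta)) scale, the analysis scale, and mapped back.
Counts are negative binomial with log-normal library sizes (SD 0.15),
log2-mean N(5, 2) and dispersion uniform on 0.05-0.5; causal effects act on
the log2 mean. Causal loadings have random sign and half-normal magnitude
floored at 0.3 of the layer's effect scale — a "causal" feature with a
negligible loading would be causal in name only, and the floor is what makes
the truth-recoverability guarantee (all causal features inside the top
2 x n_causal marginal correlations at large effects) a property of the
generator rather than of luck. Defaults are desk-scale (400 samples,
5,000/2,000/800 features, 200/100/50 causal); full-cohort dimensions are a
config away but not the default.

**ASD label.** Case status is Bernoulli with logistic probability in
standardized (SRS - IQ), the intercept solved by bisection to hit the
configured prevalence (default 9.3%). Deriving ASD *from* the outcomes means
any association between molecularly-predicted scores and ASD is an emergent
property of the pipeline, not an input — which is exactly what the
validation stage is supposed to demonstrate.

**External set.** `generate_external_methylation` reuses the cohort's
per-CpG baselines and causal directions, scales the effects by an
attenuation factor in [0, 1] (platform/portability loss), shifts latents by
label (cases: higher SRS, lower IQ latent), and returns M-values for 47
samples with 24 cases by default, optionally on a feature subset to
exercise intersection logic.

What the generator does *not* emulate: raw intensities or read-level data,
probe-level QC artifacts, batch/plate effects, genomic autocorrelation of
CpGs, and count-count correlation structure beyond the shared latents.
Passing tests therefore certify the statistical machinery, not robustness
to those upstream phenomena.

## 2. Preprocessing

- beta = M_int / (U_int + M_int + 100); the +100 stabilizes low-intensity
  probes.
- Array-scale analysis uses M = log2(beta/(1-beta)) with beta clipped to
  [1e-6, 1-1e-6] (logged warning); sequencing-derived external beta uses the
  offset transform M = log2((beta+1)/(1-beta+1)), finite at 0 and 1.
- Count filtering keeps a feature iff max count >= 5 AND sample variance
  >= 0.5, applied to raw counts before normalization. The "reaches 5 in at
  least one sample" reading was chosen deliberately: requiring 5 in *every*
  sample empties sparse miRNA panels.
- Upper-quartile normalization: per-sample 75th percentile over that
  sample's nonzero counts, divided by the geometric mean of the percentiles
  (restricted to training samples inside CV so held-out data cannot move
  the factors). Variance stabilization is log2(x + 0.5) on the scaled
  counts — a monotone, variance-flattening surrogate chosen because the
  provenance of the original transform is unclear; downstream stages only
  rely on monotonicity and approximate variance flattening.
- Removal of unwanted variation: top-k left singular vectors of the
  feature-centered negative-control submatrix; every feature is then
  regressed on these factors and replaced by residual + mean. Controls are
  the features whose minimum association p-value against SRS and IQ is
  largest (least associated with any outcome). Factors come from the
  centered controls directly — not from residuals of an outcome model — to
  keep the construction leakage-free when used inside CV.

## 3. Genome-wide association

**Counts (NB Wald).** Per feature, an NB GLM with log link, upper-quartile
offsets, and design intercept + covariates (+ optional RUV factor) +
outcome. Fitting is batched IRLS across all features at once (the per-feature
weighted Gram matrices are assembled by one GEMM over the design's pairwise
column products), which is what makes per-fold genome-wide selection
affordable inside 50-fold CV. Dispersion: method-of-moments initialization,
then one-step adjusted profile likelihood on a log grid (NB log-likelihood at
the fitted means plus the Cox-Reid `-0.5 log det(X'WX)` adjustment), then
log-space shrinkage toward a log-linear mean-dispersion trend with an
empirical weight `tau^2 / (tau^2 + 2/n)`, where `tau^2` is the excess spread
of log-dispersions around the trend and `2/n` approximates the sampling
variance of a per-feature estimate. A fixed shrinkage weight was rejected:
at n = 400 the per-feature estimates are precise, and pulling genuinely
dispersed features halfway to the trend inflated the null Wald type-I error
from ~0.051 to ~0.060 in the calibration simulation the acceptance suite
runs. Wald p-values are two-sided normal; non-converged features are flagged
and excluded from BH.

**Methylation (robust EWAS).** Per CpG, Huber M-estimation (tuning constant
1.345, 95% Gaussian efficiency; scale re-estimated each iteration by
normalized MAD) on intercept + covariates + surrogate variables + outcome,
again fully vectorized. Surrogate variables are the top-k left singular
vectors of the residual matrix after regressing all features on the design
including the outcome (k = 5 by default) — a deterministic two-step
construction, preferred over iteratively reweighted alternatives for
testability and replay inside CV. Residual variances are moderated toward a
scaled inverse-chi-square prior fitted by method of moments on the log scale
(trigamma inversion); the moderated t uses df = d0 + (n - p), and identical
residual variances collapse to the common prior variance (d0 -> infinity).

**Deconvolution.** Reference profiles (features x cell types, emulating
trophoblast subtypes and stromal cells) are fit to each bulk sample by
non-negative least squares, then projected to the simplex by renormalizing.
Renormalized NNLS rather than a hard sum-to-one constraint makes the
estimate exactly invariant to the bulk sample's library scale and agrees
with the constrained solution on exact mixtures (recovered to 1e-6).
Non-identifiable references (rank-deficient or near-duplicate columns) are
rejected. The interaction model adds proportion and outcome x proportion to
the NB design; the interaction Wald test captures cell-type-specific
differential expression and the main effect is the association at 0% of the
cell type. An all-zero proportion column legitimately drops both terms
(reducing exactly to the main model); a constant nonzero column is an error,
and near-constant columns trigger a low-identifiability warning.

**Multiple testing** is Benjamini-Hochberg step-up everywhere, NaN-aware.
Significance conventions follow the genome-wide analyses: FDR < 0.01 for the
main scans, FDR < 0.05 for the cell-type analysis. Covariate regressions
report FDR-adjusted confidence intervals by the false-coverage-rate rule
(level 1 - R*alpha/m after R BH rejections).

## 4. Kernel models

Kernels are built from standardized features (training statistics only,
zero-variance features dropped with a warning): linear `XX'/p` or Gaussian
with default bandwidth `sigma^2 = p`. Covariates are removed at the feature
level with training-fold coefficients — algebraically the `PKP` double
projection for the training block, and the only construction that gives
coherent train/test cross-kernels; `residualize_kernel` exposes the `PKP`
form for square kernels. Aggregation is the unweighted mean of
trace-normalized kernels (trace = n), preventing the 5,000-feature
methylation kernel from dominating by scale; weights are a deliberate
non-feature (nothing in the method's definition determines them).

**KRLS** minimizes `||y - b1 - Ka||^2 + lambda a'Ka` jointly over the
unpenalized intercept and dual coefficients. Because the fit is a linear
smoother from a single quadratic objective, leave-one-out residuals have
the exact closed form `e_i / (1 - S_ii)`; `lambda` minimizes the LOO SSE by
bounded search on log10 lambda in [-6, 6], reusing one eigendecomposition.
The joint intercept is the GLS mean `(1'M y)/(1'M 1)`, `M = lambda (K +
lambda I)^-1` — which is exactly the fixed-effect estimate of the kernel
LMM, so BLUP prediction equals KRLS at `lambda = sigma_e^2/sigma_g^2` to
machine precision (an acceptance-tested identity). The **kernel LMM**
profiles the likelihood over the variance ratio on the eigenbasis
(one-dimensional bounded search, log10 delta in [-6, 8]); a ratio pinned at
the upper bound warns and degrades to intercept-only predictions.

**Monte Carlo CV** (default 50 folds, 75/25) derives each fold's seed from
the master seed by a counter scheme recorded in the report, assigns folds by
sample identifier (so row order is irrelevant), and runs the entire training
pipeline inside the fold: outcome residualization with training
coefficients, per-layer feature ranking by raw association p (the batched NB
or robust path with moment dispersions and no surrogate variables — the
cheaper selection-grade variant of the genome-wide tests), training-fold
standardization, feature-level covariate removal, trace normalization,
aggregation, model fit, test prediction, adjusted R-squared with one
predictor charged. Fold failures are recorded; more than 20% failed folds
aborts. The leakage guard in the acceptance suite verifies that on a
pure-noise cohort of the full default size every omic combination's mean
adjusted R-squared stays within +-0.03 of zero.

Feature-count tuning evaluates single-layer models over a per-layer grid
(default {100, 500, 1000, 5000, 10000} intersected with availability) and
returns the argmax of mean adjusted R-squared; validation stages default to
the tuned 5000/1000/1000 configuration.

## 5. Networks

Point-wise effects are average marginal derivatives of the fitted function:
constant `(1/p) X'alpha` for the linear kernel, the analytic Gaussian-kernel
derivative averaged over training points otherwise (checked against central
finite differences to 1e-5). Each layer's effects carry its aggregation
weight (trace factor / number of kernels). The top 50 features per layer by
|effect| (identifier tie-break) form the node set; the network is estimated
on the covariate-residualized, standardized node data the model saw.
`graphical_lasso` maximizes the L1-penalized Gaussian log-likelihood on the
correlation matrix (solver: scikit-learn's coordinate descent; rho = 0
falls back to the dense inverse and requires conditioning below 1e10);
edges are partial correlations `-Theta_ij / sqrt(Theta_ii Theta_jj)`.
Penalty selection minimizes EBIC with gamma = 0.5, where the log-likelihood
is evaluated at the Gaussian MLE *refit on the selected edge support*
(iterative modified-regression sweeps). Scoring the refit rather than the
shrunken lasso estimate is what makes the criterion consistent: scored on
the penalized estimate, the minimizer systematically over-selects (the
acceptance suite's AR(1) chain is then recovered exactly in >= 80% of
seeds, versus never with the shrunken score).

## 6. Validation

`insample_predict` partitions samples into k = 10 identifier-based folds
(each >= 5 samples) and assembles out-of-fold predictions for every sample
from the full in-fold pipeline; predicted and observed are compared on the
covariate-residualized scale (Pearson, Spearman — exact permutation p for
n <= 7, asymptotic t beyond — and cross-validated R-squared).
`label_association` is a two-sided Mann-Whitney of predicted scores across
ASD classes (exact enumeration when both groups have <= 10 samples), with
the case-minus-control mean difference. `apply_external` ports a
methylation-only model bundle to an external M-value set: features are
intersected with the model's selection, missing features are imputed at the
training mean (standardized zero) to preserve kernel geometry, coverage is
reported, and overlap below 10% is refused. Covariates are removed with
training coefficients when the external set has them and skipped otherwise
(the usual case for public external data); with the training set itself as
"external" input, predictions reproduce the in-sample fitted values to
1e-9.

## 7. Problem sizes and defaults

The package's own test and reproduction runs use: the full default cohort
(n = 400; 5,000/2,000/800 features) for the leakage guard, calibration and
the acceptance script; n = 300 with 800/600/400 features, per-layer signal
and 15 folds for the aggregation-benefit study; n = 250 with 600/400/300
features for the end-to-end ASD sign-pattern study; 20 nodes x 500 samples
for network structure recovery. These sizes were chosen so each study has
enough power for its qualitative conclusion while the whole suite runs on a
single CPU in minutes.

## 8. Known limitations

- The NB path does not reimplement independent filtering, outlier
  replacement, or fold-change shrinkage found in dedicated count packages;
  effects are plain Wald estimates.
- Surrogate variables are computed per outcome model; if the same unwanted
  structure should be shared across outcomes, compute them once and pass
  them explicitly.
- The EWAS and NB scans assume post-QC, normalized-scale input matrices;
  probe QC, functional normalization and batch correction are upstream and
  out of scope.
- Kernel aggregation uses fixed equal weights; multi-kernel learning with
  estimated weights is deliberately not implemented.
- External application assumes the external platform's M-values are
  comparable after training-mean imputation; real cross-platform
  harmonization (array vs bisulfite sequencing) is not attempted, and low
  coverage should be read as a portability warning.
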