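# Methods

## Scope and data model

The package operates at the *structure level*: each subject is a row of
numeric features per modality (regional volumes in mm³, regional FA in
[0, 1], regional MD in mm²/s, and Fisher-z connectivity edges), assembled
upstream by segmentation pipelines that are out of scope here.  Derived
features implemented in `data_model`:

- **Fisher z**: z = atanh(r) applied to every off-diagonal seed correlation;
  the S×S matrix yields S(S−1)/2 edge features named `A__B` with A < B
  lexicographically, in row-major upper-triangle order, so edge ordering is
  auditable.
- **Framewise displacement**: FD_t = Σ|Δtranslation| + 50 mm · Σ|Δrotation|
  (rotations in radians, arc length on a 50 mm sphere; degree inputs must
  be converted on read).  QC excludes subjects whose maximum FD exceeds a
  threshold (0.5 mm default).
- **Standardization**: per-feature centering and unit-variance scaling
  before factor analysis.  Mixing mm³, mm²/s and z units without scaling
  would let the largest-variance block dominate the Gaussian likelihood,
  so scaling is the default; `per_feature=False` keeps centering only, and
  the recorded transform supports exact inversion and the scoring of new
  subjects with training-set parameters.
- Missing data are not imputed: a subject with any missing feature fails
  validation (complete-case design).

## The SIFA model and estimation

With K blocks, covariates Y (n×q), joint scores U₀ (r₀ factors) and
per-block individual scores U_k (r_k factors):

U₀ = Y B₀ + F₀, U_k = Y B_k + F_k, X_k = U₀ V₀ₖᵀ + U_k V_kᵀ + E_k,
F ~ N(0, diag(τ)), E_k ~ N(0, σ_k² I).

- **Likelihood**: the marginal covariance of the concatenated feature
  vector is W T Wᵀ + D with W the structured loading matrix (p × R,
  R = r₀ + Σr_k), T diagonal score-noise variances and D block-diagonal
  residual variances.  Both the log-determinant and the quadratic form are
  evaluated through the R×R posterior precision T⁻¹ + WᵀD⁻¹W (Woodbury),
  so cost is O(n p R) and the p×p covariance is never formed.
- **EM**: the E-step computes the exact joint Gaussian posterior of all
  scores (its covariance is subject-independent); the M-step updates B by
  least squares of posterior mean scores on Y, the loadings per block by
  least squares against the posterior second moments, then τ and σ².  All
  updates are exact conditional maximizers, so the observed-data
  log-likelihood is non-decreasing (tests allow −1e−8 numerical slack).
  Convergence: relative log-likelihood change < 1e−7 (default), max 500
  iterations; non-convergence returns a fit flagged `converged=False` with
  a warning, never silently.
- **Initialization**: joint loadings from the SVD of the column-concatenated
  standardized blocks; individual loadings from per-block SVDs of the
  residual; B from least squares of the initial scores on Y; optional
  seed-controlled jitter for basin-sensitivity checks.

## Identifiability convention

Factor models are only identified up to invertible score/loading
transforms.  The canonical gauge used here ("SIFA-B" flavour, robust to
unbalanced block dimensions because every block enters the stacked joint
loading matrix symmetrically):

1. score-noise variances absorbed into the loadings (τ ≡ 1);
2. columns of the *stacked* joint loading matrix [V₀₁; …; V₀K] mutually
   orthogonal; columns of each individual loading matrix orthogonal;
3. factors ordered by decreasing total loading norm;
4. each column's largest-magnitude element positive.

The map (an SVD of the τ-scaled loadings plus compensating transforms of
B and the posterior scores) is exactly likelihood-preserving.  Two further
conditions — per-block orthogonality between joint and individual loadings,
and equal joint-loading norm across blocks — are *structural* constraints,
not gauge freedoms: no likelihood-preserving transform can impose them on
an arbitrary parameter set, because factor mixing acts on all blocks of the
stacked joint loadings at once.  The synthetic generator therefore builds
truths that satisfy them exactly by construction (per-block orthonormal
frames; equal per-block joint norms c_j/√K), and the validator offers a
`strict` level that checks them.  Fits satisfy them asymptotically when the
data were generated that way.

## Rank selection

Likelihood cross-validation: subjects are split into 5 folds (stratified by
group when every group is large enough); each admissible (r₀, r₁..r_K)
candidate is fitted on the training folds and scored by the mean held-out
per-subject log-likelihood.  The all-zero combination is admitted as the
isotropic-noise null model, which is what pure-noise data should select.
Full-grid search up to 200 combinations, otherwise greedy (r₀ first with
individual ranks at their smallest candidate, then each block in turn).
Candidates violating r₀ + r_k < min(n_train, p_k) are skipped and logged.

## Sparse loadings

Holding the posterior scores fixed, each block's loadings are re-estimated
by L1-penalized least squares against the posterior score moments (cyclic
coordinate descent on the score Gram matrix; exact soft-thresholding when
scores are orthogonal; λ=0 is a no-op).  λ is chosen per block by 5-fold
cross-validated held-out reconstruction error with the one-standard-error
rule.  Note a known property of prediction-optimal lasso tuning: the
selected λ retains small spurious loadings, so exact-support recovery
saturates around F1 ≈ 0.8 on sparse truths; the reported loading tables
are therefore read as rankings by magnitude with exact zeros as a
feature-screening device, not as an oracle support estimate.

## Bootstrap inference

Percentile CIs (the simplest defensible reading of "bootstrap confidence
intervals") from resampling subjects with replacement *within* each group,
which preserves group sizes and makes empty-group resamples impossible.
Each resample is refitted by EM warm-started from the point estimate
(tol 1e−6, ≤100 iterations), mapped to canonical gauge, and aligned to the
point estimate by optimal assignment on absolute loading correlations
(joint factors on the stacked loadings, individual factors within block),
with sign flips from the matched correlation's sign.  Ranks are held fixed
at the point estimate's (no re-selection inside resamples).  More than 10%
refit failures aborts.  A factor is reported as group-associated when its
group-dummy coefficient's CI excludes zero; its sparsified loadings are
tabulated by sign and magnitude per modality.

## Classification

Leave-one-out cross-validation of logistic (maximum likelihood; a ridge of
C=1e6 only as a separation fallback) and SVM (linear/polynomial/radial,
Platt-scaled probabilities) classifiers on factor scores, for five feature
sets: all modalities (joint + individual factors of the full fit) and each
single modality (a one-block refit with the same per-block factor budget).
AUC uses the midrank Mann–Whitney statistic; its CI the DeLong variance
estimator (cross-checked against an independent reference implementation).
Threshold metrics are reported at 0.5 with the Youden-J optimum alongside.

Two design points matter:

- **Label leakage through the covariate model.**  Posterior scores are
  conditional means given data *and* covariates; if the group dummies stay
  in the design, the score prior Y·B hands the class label to the
  classifier and LOOCV measures circularity (null data then classify far
  above chance).  Factors used for classification are therefore estimated
  with the group dummies removed from the covariate design (age/sex/race
  retained).  This is the package's own choice where the original workflow
  is ambiguous, and it is what makes the null-data AUC checks honest.
- **Transductive vs strict cross-validation.**  Transductive mode (default)
  estimates factors once on all subjects and cross-validates only the
  classifier — the workflow's behaviour.  Strict mode refits the factor
  model per fold and scores the held-out subject by closed-form posterior
  conditioning; on well-powered synthetic data the two agree to within
  0.05 AUC, and strict mode is the right tool when factor-level leakage is
  a concern.

## The synthetic generator

`synthetic` draws datasets from the model above with a demographics table
matching the cohort's structure: group proportions 62:61:26
(HC : schizophrenia-spectrum FEP : mood-disorder FEP), age ~ N(23, 4) years
truncated to [15, 35], 64% male, five race levels with rare levels
collapsed during encoding.  Loading scale is parametrized by `snr`, the
per-feature variance share of the leading joint factor relative to unit
residual noise (stacked norm² = snr · Σp_k, split equally across blocks);
individual factors carry half that share; factor strengths decay
geometrically (0.8) to keep the canonical ordering strict.  Sparse truths
place loading columns on disjoint random supports, which yields exact
zeros and exact orthogonality simultaneously.  Group effects enter the
joint scores by default (S-FEP strongest on factor 1, M-FEP on the last
factor), nuisance covariates enter all scores weakly (0.2); the null
generator zeroes exactly the group rows.

What the generator does *not* emulate: spatial autocorrelation between
neighbouring regions, heavy-tailed or skewed feature marginals, site or
scanner effects, motion-correlated artefacts, and missingness.  Passing
tests therefore certify the statistical machinery under the model's own
assumptions — not robustness of the original findings to real-data
violations of those assumptions.

## Problem sizes and numerical choices

Test and acceptance runs use reduced dimensions chosen once: the study
shape scaled to p = (40, 20, 20, 60) at n = 150 for recovery; n = 200 with
small blocks for rank-selection recovery (20 seeds); bootstrap coverage at
n = 150 with 100 outer replicates × 200 resamples; null error control over
hundreds of small replicates.  Variance floors: τ ≥ 1e−10, σ² ≥ 1e−12.
Degenerate cases defined explicitly: empty factor sets (R = 0) reduce to
per-block isotropic Gaussian fits; constant probability vectors yield AUC
0.5 with a degeneracy warning; zero-norm loading columns are an error in
canonicalization and are matched last (flagged) in alignment.

One stated recovery figure deserves care: with unit score noise (the
canonical gauge) and this cohort's group split, the best possible estimate
of a group coefficient at n = 150 has standard error ≈ 0.2 — even
regressing the *true* scores on the covariates gives group-row RMSE ≈ 0.25.
The recovery test therefore benchmarks the fit against that in-test oracle
(fit RMSE ≤ 1.6× oracle RMSE; median maximal joint-subspace angle < 8°)
rather than against an absolute constant below the information limit.

## Known limitations

- Gaussian likelihood throughout; no robust or non-Gaussian variants.
- The identifiability gauge is one concrete realization of
  "orthogonal and equal-norm" conditions; other realizations exist and
  would relabel factors without changing fitted means.
- Bootstrap CIs are percentile-based; no BCa or studentized variants.
- LOOCV at these sample sizes has a small pessimistic AUC bias (each
  held-out subject's class is underrepresented in training); comparisons
  across feature sets share the bias and remain meaningful.
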