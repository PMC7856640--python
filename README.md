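# simfa — supervised integrated factor analysis of multimodal brain-imaging features

`simfa` re-implements, as a tested analysis pipeline, a structure-based
multimodal MRI workflow for characterizing first-episode psychosis (FEP):
per-subject feature tables from four modalities — regional volumes (T1),
regional FA and MD means (DTI), and Fisher-z resting-state connectivity
edges — are compared between patients and controls feature by feature, then
integrated with a supervised latent factor model, and finally used to
classify individuals into clinical subgroups.  Because the subject-level
data of such cohorts are typically not deposited, the package ships a
first-class synthetic-data generator that draws datasets from the exact
model the analysis assumes, with known ground truth, so every stage is
testable end to end.

## The model

For K feature blocks X₁..X_K (n subjects × p_k features) and covariates
Y (n × q; group dummies with healthy controls as reference, age, sex, race):

    U₀ = Y B₀ + F₀          common (joint) scores, r₀ factors
    U_k = Y B_k + F_k        block-specific (individual) scores, r_k factors
    X_k = U₀ V₀ₖᵀ + U_k V_kᵀ + E_k,   E_k ~ N(0, σ_k² I)

with independent Gaussian score noise F.  The analysis stages are:

1. **Mass-univariate stats** — per-feature Welch t tests per group contrast
   with Benjamini–Hochberg FDR within each modality (q < .05), plus the
   cohort demographics table (Welch t / Yates χ²).
2. **SIFA-B estimation** — EM on the exact observed-data Gaussian
   likelihood (low-rank Woodbury evaluation), ranks chosen by likelihood
   cross-validation, parameters mapped to a canonical identifiability gauge
   (unit score-noise variance, orthogonal loading columns, decreasing norm,
   sign-fixed), loadings sparsified by cross-validated L1 regression.
3. **Bootstrap inference** — percentile CIs for every coefficient in B from
   group-stratified resampling with warm-started refits and factor
   alignment (optimal assignment on absolute loading correlations); a
   factor is group-associated when its group coefficient's 95% CI excludes 0.
4. **Classification** — leave-one-out cross-validated logistic and SVM
   models on the estimated factor scores, per feature set (all modalities
   and each single one), summarized by ROC AUC with DeLong 95% CIs,
   sensitivity/specificity/F1.

## Worked example

The numbered scripts under `analysis/` run the whole pipeline on a
simulated cohort shaped like the study (n=150; HC / schizophrenia-spectrum
FEP / mood-disorder FEP groups; four blocks, reduced to 40/20/20/60
features so everything re-runs in minutes):

```bash
python analysis/01_simulate.py     # writes feature tables + ground truth
python analysis/02_group_stats.py  # demographics + per-feature Welch/FDR
python analysis/03_fit_sifa.py     # LCV ranks, EM fit, sparse loadings
python analysis/04_bootstrap.py    # 500-resample coefficient CIs
python analysis/05_classify.py     # LOOCV AUC grid per modality set
```

A run with the default seed prints, among other things:

```
LCV-selected ranks: r0=3, r=(1, 1, 2, 0) (generator used r0=2, r=(1,1,1,1))
EM: 41 iterations, converged=True, loglik -22200.3
variance explained (%):
modality  common_pct  individual_pct  all_latent_pct
  volume        35.5            15.0            50.3
      FA        33.8            14.7            48.7
      MD        34.9            21.9            56.6
  rsfmri        51.4             0.0            51.4

joint1:group_M_FEP     0.649  0.112  1.146         True

HC vs S_FEP — LOOCV AUC (95% CI):
feature_set      logistic_ci    svm-linear_ci      svm-poly_ci    svm-radial_ci
        all 0.76 (0.67-0.84) 0.74 (0.65-0.82) 0.79 (0.72-0.87) 0.78 (0.69-0.86)
```

Reading this: likelihood cross-validation slightly over-selects the factor
ranks on one realization (3 joint factors against the generative 2); the
joint factors explain a third to a half of each block's variance; the first
joint factor's group coefficient has a bootstrap CI excluding zero, so the
pipeline flags it as the group-associated multimodal pattern; and factor
scores classify patients vs controls with AUCs around 0.75 at this signal
strength.  Tables land under `results/analysis/`.

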