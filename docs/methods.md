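# Methods

`anrisk` implements a multivariate analysis of regional brain-morphometry
tables: it classifies clinical groups from healthy controls (HC), converts
the classifier's continuous decision value into a per-subject *ML-based risk
score*, and then interrogates that score — its statistical significance, its
dependence on confounds, the anatomical pattern it relies on, the relation
of that pattern to brain-network organization, its transfer across disease
stages, and its value as a predictor of later clinical outcome.  Because the
kind of patient data this design targets is not publicly distributable, the
package ships a first-class synthetic cohort generator whose ground truth
makes every step testable.

## The classification pipeline

Given a subjects-by-features table of 110 regional measures (68
Desikan-Killiany cortical-thickness values plus subcortical gray-matter and
CSF-space volumes) the pipeline is, in order:

1. **Control-anchored confound regression.**  Per feature, an OLS model of
   the confounds is estimated *on the healthy-control training rows only*
   and its prediction subtracted from every row.  Thickness features are
   adjusted for age; volumetric features (including CSF spaces — they are
   volumes) additionally for estimated intracranial volume (eTIV); an
   extended mode adds BMI-SDS to both sets.  Anchoring on controls prevents
   disease effects from being absorbed into the confound model.  Confounds
   are centered at the training-control means, so the adjustment shifts no
   group except through the fitted slopes; whether to center is a
   convention, made explicit here because it is testable.  Near-collinear
   confound designs (condition number above 1e8) fall back to a ridge
   penalty of 1e-8 on the normal equations, with a logged warning.
   Inside cross-validation the model is re-fitted per fold on the controls
   of the training part only, so no test row influences its own adjustment.

2. **Standardization and PCA.**  Features are z-scored with train-fitted
   parameters before PCA.  The standardization step is a design choice made
   here: raw volumes (mm³) would otherwise dominate thickness (mm) in the
   principal components.  It is exposed as a config flag.

3. **Linear L2-regularized SVM.**  Misclassification costs are weighted by
   the inverse of each group's frequency.  The signed decision value is the
   risk score, oriented so that higher = more patient-like.

The number of PCA components and the SVM inverse-penalty C are optimized
jointly by repeated stratified k-fold grid search maximizing mean PR-AUC
(PR-AUC is preferred for selection because the patient groups are minority
classes; ROC-AUC is additionally reported for comparability across tasks
with different class ratios).  Default grids — components {5, 10, 20, 40,
80, min(n, p)} and C in six log-spaced steps from 1e-3 to 1e2 — span under-
to over-parameterized models; the `min(n, p)` grid point makes PCA lossless
at the top end, which matters when signal is spread isotropically across
features.  Ties are broken toward fewer components, then smaller C
(simplicity preference).  Generalization is estimated by nested
cross-validation (default 10-times-repeated stratified 10-fold in both
loops): the *entire* pipeline runs inside each outer training set and is
evaluated on the untouched outer fold.  Out-of-fold risk scores are
collected once per scan per repeat and averaged over repeats for downstream
use — training-set scores would make the later correlation analyses
circular.

All fold shuffling derives from a single user seed through named CRC-32
substreams (`anrisk._seeds`), so any stage can be re-run in isolation with
identical results.

## Inference

**Permutation tests.**  Group labels are permuted before everything and the
full nested-CV pipeline re-run per permutation, including deconfounding on
the permuted "control" set, so the null distribution reflects every
data-dependent step.  P-values use the add-one convention
`(1 + #{null >= observed}) / (1 + B)`, which is exact under exchangeability
and never zero.  A frozen-hyperparameter mode (singleton grids, inner search
skipped) is provided for compute-bound settings; when the frozen values are
fixed a priori the test remains exact, and the type-I error of exactly this
mode is verified in the acceptance suite.

**Deviance partitioning.**  For each task, a logistic model of group
membership quantifies deviance explained, `1 − D(model)/D(intercept)`, for
the risk score alone, the confounds alone, and both together; the shared
component is `D(risk) + D(conf) − D(joint)` and the exclusives are joint
minus the other set.  The three components reconstruct the joint deviance by
construction, and the shared part may be negative (suppression).  Logistic
fits use IRLS (statsmodels); singular or separated designs — which IRLS can
"converge" through silently — are detected by a deviance sanity check and
re-fitted with a damped Newton iteration under a small L2 penalty (1e-6),
logged.  Note that logistic deviance is not perfectly collapsible:
independent informative predictors yield a shared component near, but not
exactly, zero.  Component p-values come from permuting the risk vector
(preserving the confound-label relation) and, for the confound-exclusive
component, the confound rows; this null construction is our own, made
explicit here.

**Outcome model.**  A Gaussian identity-link GLM (OLS) of the outcome score
on the risk score, optionally with one covariate (BMI-SDS, BMI-SDS change,
or a comorbidity flag).  Slope inference is the usual two-sided t-test; the
no-covariate R² is the squared multiple correlation.

## Explainability

Per-feature importance is the *activation pattern* of the linear decoder:
the Pearson correlation of each (deconfounded) feature with the out-of-fold
risk score, with two-sided p-values and Bonferroni correction across the
110 features.  Zero-variance features get NaN importance, flagged rather
than raised.  *Reliability* is the fraction of stratified 90% subsamples
(default 100, without replacement) in which a feature's importance is
Bonferroni-significant after refitting the full pipeline on the subsample;
the subsample pattern is computed against the refit model's own scores,
accepting a small optimism that cancels in the fraction.  *Permutation
importance* is the mean PR-AUC drop when a feature's raw column is shuffled
across held-out rows (default 25 repeats); because the risk score is affine
in the inputs, only the shuffled column's contribution changes, which the
implementation exploits.

**Connectome contextualization.**  Weighted degree centrality — the row sum
of a region-by-region connectivity matrix — marks network hubs.  The
cortical importance profile is correlated (Pearson) against centrality,
aligned by an explicit feature-name-to-region-label mapping (a shipped CSV
for the Desikan-Killiany set; positional alignment for generated cohorts);
fuzzy string matching is deliberately not attempted.  Connectivity matrices
are symmetrized as `(W + Wᵀ)/2`, negatives clipped to zero with a logged
count (functional connectomes contain negative edges, but the centrality
definition assumes nonnegative ties), and the diagonal zeroed.

**Transfer classification.**  A model fitted on one task is applied
unchanged to another; rows of subjects seen in training are excluded.
Because controls are identical across tasks, the orchestrated workflow
trains the source model on half the controls and evaluates transfer on the
other half — otherwise subject-level exclusion would leave no controls in
the test set.

## The synthetic cohort generator

The generator emulates the statistical structure the analysis assumes, on a
standardized latent scale mapped affinely to physical units (mm, mm³), so
all effect sizes are in residual-SD units:

* **Confounds:** age ~ Uniform(12, 30) years, eTIV ~ Normal(1.5e6, 1.5e5)
  mm³, per-feature linear slopes (age for all features, eTIV for volumetric
  ones); BMI-SDS group means 0 / −2.5 / −1.0 / −0.2 (HC / acute / partially
  restored / recovered), SD 0.6.
* **Group effect:** per-feature signed effect `γ_g (1 + s_i) δ_j`, negative
  for thickness and gray-matter volumes, positive for CSF spaces, with a
  per-subject latent severity `s_i ~ N(0, 0.3²)` shared between a subject's
  two acute timepoints.  Cortical magnitudes are weighted by `1 + λc_j`
  with log-normal latent hub centrality `c` from the synthetic connectome
  (λ = 1 by default), normalized so λ does not change the overall effect
  scale; non-cortical magnitudes carry Uniform(0.5, 1.5) jitter, cortical
  ones none, so |δ| is exactly monotone in centrality.
* **Noise:** rank-5 low-rank loadings (scale 0.7) plus unit diagonal — the
  multivariate, network-like covariation that univariate tests miss.
* **State scales:** γ = 0 for controls by definition; defaults γ = 1.20 /
  0.33 / 0.12 for the three patient stages were calibrated once against the
  generator's own oracle (below) to population-optimal ROC-AUC ≈ 0.90 /
  0.65 / 0.55 — a strong acute-stage separation, a weak one after partial
  restoration, near chance after recovery.  These mirror the intended
  regime; they are conditions of the simulation, not targets.
* **BMI routing:** an optional fraction of the group effect is routed
  through BMI-SDS, so BMI deconfounding attenuates but does not abolish the
  signal (default 0; the deviance-partition example uses it).
* **Second acute timepoint:** reuses the subject's age/eTIV draws and
  severity with updated BMI-SDS and a smaller γ (partial normalization),
  and carries an outcome score `9 − 1.5(1 + s_i) + N(0, 2²)` on a
  Morgan-Russell-like 0-12 scale — stronger residual alteration, worse
  outcome.
* **Default sizes** mirror the reference design: 289 / 165 / 115 / 89
  (HC / acute / partially restored / recovered).

`oracle_bayes_auc` draws large Monte-Carlo samples from the generative
model (confound terms omitted, as they are removable in principle), fits
the linear discriminant analytically from the pooled covariance, and
evaluates ROC-AUC on an independent draw: the ceiling a linear pipeline can
approach.  `calibrate_gamma` bisects the state scale against this oracle.

What the generator does **not** emulate: realistic anatomy or inter-feature
correlation structure beyond low-rank-plus-diagonal, scanner/site effects,
non-linear confound relations, longitudinal drift beyond the single paired
timepoint, and non-Gaussian tails.  Tests passing on these cohorts
therefore certify the *statistical machinery* — absence of leakage,
calibration of inference, recovery of planted structure — not performance
on real morphometry.

## Verification strategy and problem sizes

The acceptance suite checks, at desk-scale problem sizes chosen for
estimator convergence and runtime: chance-level nested-CV AUC on 20
effect-free cohorts (n = 200 each); exact type-I error of the frozen-mode
permutation test (100 null runs × 99 permutations, binomial band around
α = 0.05); nested-CV AUC within ±0.05 of the Monte-Carlo oracle on cohorts
calibrated to oracle 0.90 (n = 600, p = 30) and 0.65 (n = 900, p = 30 — the
weaker signal needs more subjects for the learner to approach its ceiling);
exact deconfounding on noiseless linear confounds and bitwise invariance of
the confound fit to arbitrary corruption of patient rows; the deviance
additivity identity to 1e-10; ROC-AUC against a brute-force concordance
oracle to 1e-12; recovery of the planted effect direction by the activation
pattern (r ≥ 0.8 at n = 400); negative importance-centrality correlation in
≥ 18/20 hub-weighted replicates; 95% CI coverage and 5% null rejection of
the outcome GLM at n = 74 over 500 simulations; and above-chance transfer
in ≥ 18/20 replicates.  The recovery, hub and transfer cohorts use stronger
planted effects than the defaults (γ = 3, λ = 2) so the checked property,
not estimator noise, dominates the result.

## Numerical conventions and edge cases

* Ties in metrics: ROC-AUC counts tied score pairs one half; PR-AUC is the
  average-precision step sum without interpolation.
* Undefined metrics (single-class labels, no positives) raise a dedicated
  error rather than returning a default.
* Zero-variance features: standardization scale is clamped to 1 (the
  centered column is zero, contributing nothing); importance is NaN and
  flagged.
* Infeasible PCA component counts are pruned from the grid with a warning;
  an empty feasible grid is an error.
* CSV round-trips write 17 significant digits and read with exact
  round-trip float parsing.
* Missing feature values are rejected at load time, not imputed — quality
  control is assumed upstream.

## Known limitations

The permutation test in full mode is expensive (it re-runs the entire
nested CV per permutation); the frozen mode trades away the grid search's
contribution to the null.  The inner CV re-uses the outer training set's
deconfounding fit rather than re-fitting per inner split — a deliberate
economy; the outer loop still sees a fully honest pipeline, which is what
the performance estimate relies on.  Reliability refits use training-score
activation patterns (see above).  The importance-centrality analysis
assumes hub status in controls carries over to patients, and tests no
spatial-autocorrelation null.
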