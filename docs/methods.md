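# Methods

`ibdmark` implements a whole-blood prognostic-biomarker development and
validation procedure for inflammatory bowel disease (IBD), together with a
synthetic-cohort simulator that provides data with the statistical
structure the procedure assumes. This note documents the models, the
defaults and their rationale, the numerical choices, and what the synthetic
data can and cannot show.

## The procedure

1. **Subgroup discovery.** Two patient subgroups (IBD1 = poor prognosis,
   IBD2 = good prognosis) are derived from CD8 T cell expression by
   Monti-style consensus clustering: repeated subsampling without
   replacement, k-means base clustering, and a consensus matrix whose
   entry (i, j) is the fraction of co-samplings in which i and j
   co-clustered. The number of clusters minimises the PAC score (the
   proportion of off-diagonal consensus entries inside an ambiguous band,
   default (0.1, 0.9)); final labels come from average-linkage hierarchical
   clustering of 1 − consensus. The cluster with higher mean expression of
   a designated marker set is named IBD1; an exact tie goes to the cluster
   containing the first sample.

2. **Whole-blood classifier.** Logistic regression of subgroup membership
   on standardised whole-blood expression with an adaptive elastic-net
   penalty. The objective is

       (1/n) Σᵢ [log(1 + exp(ηᵢ)) − yᵢ ηᵢ]
         + λ₁ Σⱼ wⱼ |βⱼ| + (λ₂/2) Σⱼ βⱼ²,

   intercept unpenalised. Stage 1 fits with unit weights (classic elastic
   net); stage 2 re-fits with wⱼ = (|β̂ⱼ| + 1/n)^(−γ), which relaxes the
   penalty on strong coefficients and sharpens selection under
   multicollinearity while keeping all weights finite. The default grid is
   70 λ₁ values (log-spaced from the smallest all-zero penalty down to
   10⁻³ of it) × 10 λ₂ values (10⁻³…10, log-spaced) × γ ∈ {0.5, 1, 2} =
   2100 candidate models. The BIC-optimal model is selected; ties break to
   smaller k, then larger λ₁.

3. **Generalisation.** Nested leave-one-out cross-validation: for every
   held-out sample the *entire* procedure — standardisation, grid fit,
   BIC selection — is re-run on the remaining n − 1 samples. Accuracy gets
   an exact Clopper–Pearson 95% interval, and the comparison against a
   dummy classifier is a one-sided exact binomial tail at p₀ = 0.5
   (class-prevalence p₀ available).

4. **qPCR translation and lock-down.** A candidate panel is assembled from
   the optimal model's genes, genes correlated with them (default
   |r| ≥ 0.8), and recurrent genes of lower-ranked models (default quotas
   12/6/21). Measurements are ΔΔCt relative expression from triplicate Ct
   values; the microarray–qPCR correlation filter removes genes with
   r < 0.5 between log2 microarray values and −ΔCt. The adaptive
   elastic-net + BIC machinery is re-run on standardised ΔCt features;
   finally, a cross-validated lasso-dominated path on *unscaled* ΔCt
   (a prerequisite for clinical use, where per-cohort standardisation is
   unavailable) picks the most-penalised model within one standard error
   of the minimum mean CV misclassification error (stratified 10-fold).
   That model is locked: genes, coefficients, intercept and the 0.5
   threshold are frozen under a SHA-256 checksum, so any later mutation is
   detected on load. A boundary probability of exactly 0.5 is called
   IBDhi — the conservative side, flagging the patient for closer
   monitoring.

5. **Prognostic validation.** Kaplan–Meier curves, the one-degree-of-
   freedom log-rank test, and a single-binary-covariate Cox model (Efron
   tie handling, Wald 95% CI on the log scale) quantify separation of
   time-to-first-treatment-escalation; a confusion matrix at the 18-month
   horizon (condition: ≥ 2 escalations) yields sensitivity/specificity/
   PPV/NPV; relative risks use the log-normal interval; Fisher's exact
   test and Mann–Whitney (exact when n₁·n₂ ≤ 400 and tie-free) cover the
   categorical and count comparisons. KM *display* is administratively
   censored at 18 months; tests always use full follow-up.

## The BIC convention

The selection criterion is standard BIC = −2·loglik + k·ln(n), minimised,
with k the number of genes with nonzero coefficients. A "paper-literal"
variant (−loglik − k·ln(n), maximised) is kept behind a flag for
auditability: read literally it subtracts the complexity penalty twice and
rewards sparser models regardless of fit, so it is not the default.

## The synthetic cohort

The generator emulates the study conditions a real training cohort would
present:

- **Cohort**: n = 69 samples, IBD1 fraction 35/69 (realised split 35/34),
  500 genes of which 50 are informative.
- **Expression**: Gaussian on the log2 scale. Informative genes are
  organised in 10 equicorrelated blocks (shared latent factor, ρ = 0.7) to
  reproduce the multicollinearity among co-regulated signature genes that
  motivates the elastic-net penalty; background genes are independent.
  Gene baselines (4–12 log2 units) are fixed properties of the genes,
  shared across independently simulated cohorts, so a classifier locked on
  one cohort transfers to another.
- **Effect sizes**: informative genes shift by 1.0 log2 units between
  subgroups in CD8 T cells and by 0.5 in whole blood
  (`wholeblood_attenuation = 0.5`): the subgroups are cleanly separable in
  CD8 data but only weakly visible in unseparated blood, which keeps the
  supervised whole-blood problem solvable yet non-trivial. The residual SD
  is 0.5 log2 units, chosen so the planted CD8 separation is essentially
  noiseless at the cohort level (Bayes error ~10⁻⁴) — matching a setting
  in which every patient can be confidently assigned by unsupervised
  clustering — while the attenuated whole-blood problem retains a
  misclassification floor of a few percent, the scale of the reported
  whole-blood LOOCV accuracy.
- **qPCR**: Ct = 40 − slope·log2(expression) + N(0, 0.2) per replicate,
  three replicates, slope 1 cycle per doubling (ideal amplification
  efficiency); three reference genes with near-constant expression
  (SD 0.05).
- **Clinical course**: time to first escalation is exponential with rate
  0.25/year for IBD2 and 2.65 × that for IBD1 (the planted hazard ratio),
  administratively censored at 3 years; 18-month escalation counts are
  Poisson (0.6 expected for IBD2, rate ratio 3). Therapy tier is the count
  truncated into the tier ladder; colectomy occurs only in
  multiply-escalating IBD1 patients.

**What the simulator does not model**: microarray batch effects, RNA
degradation, multi-centre effects, amplification-efficiency deviations,
overdispersed escalation counts (the Poisson choice keeps the count oracle
closed-form; a negative-binomial hook would be the natural extension), and
any association between expression noise and clinical outcome beyond the
subgroup label. Passing tests therefore demonstrate that the *procedure*
recovers planted structure under its stated assumptions, not that the
original gene panel or its coefficients are reproduced — those are
proprietary and undisclosed, and all panels here are synthetic.

## Numerical choices

- **Solver**: coordinate descent on the penalised logistic objective with
  the global curvature bound 1/4 of the logistic loss as a per-coordinate
  quadratic majoriser. Every update minimises an upper bound of the
  objective, so the objective is monotonically non-increasing — a property
  the test suite asserts — and with λ₂ > 0 the optimum is unique.
  Convergence: relative objective change < 10⁻⁸ (10⁻⁶ inside CV error
  curves, where only the misclassification decision matters), cap 10⁵
  sweeps. Warm starts descend the λ₁ path. Verified against a generic
  convex-optimisation oracle (split-variable L-BFGS-B) to ~10⁻¹³ on random
  instances.
- **Standardisation** uses the sample SD (n − 1); zero-variance genes are
  a hard error naming the gene.
- **ΔΔCt**: reference aggregation is the arithmetic mean of the reference
  genes' mean Cts (equivalently the geometric mean of their linear
  quantities); the calibrator defaults to 0 (pure ΔCt) since any fixed
  per-gene calibrator is absorbed by the classifier's coefficients and
  intercept. Replicate QC default: SD ≤ 0.5 cycles flags a record.
- **Consensus clustering** defaults: 250 resamples (100 in the fast
  in-package pipeline), subsample fraction 0.8, k ∈ 2…6, k-means with 3
  restarts on the top 5000 most-variable genes. A sample pair never
  co-sampled is an error instructing more resamples.
- **Degenerate inputs**: single-class labels, empty grids, empty samples,
  all-censored arms and missing classifier genes raise errors naming the
  offending object; classification never silently defaults.

## Null calibration of nested LOOCV

Two statistical subtleties shape the no-signal test. First, with *exactly
balanced, permuted* labels, LOOCV is structurally anti-correlated: leaving
out a sample tilts the training majority against its class, so
intercept-only folds are always wrong and mean accuracy sits far below
0.5 — a known pathology of LOOCV with majority-type predictions, not an
implementation defect. The null check therefore draws iid Bernoulli(0.5)
labels, under which the held-out label is provably independent of its
prediction and expected accuracy is exactly 0.5. Second, fold outcomes
within one dataset are correlated, so the spread of mean LOOCV accuracy is
about twice the nominal binomial value; the test keeps the 0.5 centre and
95% level but takes the band width from the null simulation's own
per-seed dispersion.

## Problem sizes in the test suite

The suite and the acceptance script re-run every statistical claim at
sizes chosen for quick iteration: consensus recovery at the default
69 × 500 cohort over 20 seeds with 100 resamples; the solver oracle on 50
random (20, 5) instances; nested-LOOCV nulls at n = 30, p = 50 with a
24-model grid; hazard-ratio recovery at 1000 patients per arm; type-I
error over 1000 null replicates; and the full simulate → discover → train
→ translate → lock → classify → validate pipeline over 20 seeds with a
reduced 210-model grid (14 × 5 × 3). The full 2100-model grid is the
library default for `default_grid` and is exercised directly by the grid
tests.

## Known limitations

- The locked classifier's gene count is whatever the 1-SE rule returns on
  the synthetic panel (typically 7–11 informative genes at default
  settings); the 17-gene size of the original assay is a property of its
  undeposited data and is not a target.
- The Cox wrapper handles the single binary covariate the validation
  needs; multivariable models with clinical covariates are out of scope.
- `consensus_cluster` stores one consensus matrix per candidate k
  (O(k·n²) memory), which is fine for cohort-scale n but not for
  thousands of samples.
- The paper-literal BIC variant is provided for auditability only.
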