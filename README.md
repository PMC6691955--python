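# ibdmark

A whole-blood prognostic biomarker pipeline for inflammatory bowel disease
(IBD), for computational biologists and biomarker developers who want a
tested, reusable implementation of the full development-and-validation
procedure:

1. derive two patient subgroups — **IBD1** (poor prognosis) and **IBD2**
   (good prognosis) — from CD8 T cell expression by resampling-based
   **consensus clustering**;
2. learn a sparse classifier of subgroup membership from whole-blood
   expression by **logistic regression with an adaptive elastic-net
   penalty**, selecting among a 2100-model hyperparameter grid by **BIC**
   and estimating generalisation error by **nested leave-one-out
   cross-validation**;
3. translate the signature to the qPCR scale (**ΔΔCt** relative
   expression, microarray–qPCR correlation filtering, re-regularisation on
   unscaled ΔCt with the **1-SE rule**) and **lock** the resulting
   classifier (genes, coefficients, 0.5 threshold, tamper-evident
   checksum), whose calls are **IBDhi**/**IBDlo**;
4. validate prognostic separation on time-to-treatment-escalation
   endpoints: Kaplan–Meier / log-rank, a Cox hazard ratio, confusion
   matrices at the 18-month horizon, relative risks, Fisher's exact and
   Mann–Whitney tests.

Because no patient-level data are public, a first-class synthetic-cohort
module generates expression, qPCR and clinical follow-up data with the
statistical structure the analysis assumes (correlated informative gene
blocks, attenuated whole-blood signal, subgroup-dependent escalation
hazards), so every stage is testable end to end.

## The model at the core

For labels y ∈ {0,1} and standardised features X, the classifier minimises

    (1/n) Σᵢ [log(1 + exp(ηᵢ)) − yᵢηᵢ] + λ₁ Σⱼ wⱼ|βⱼ| + (λ₂/2) Σⱼ βⱼ²,

η = β₀ + Xβ, intercept unpenalised. A classic elastic-net fit (wⱼ = 1)
provides initial coefficients; adaptive weights wⱼ = (|β̂ⱼ| + 1/n)^(−γ)
drive a second, weighted fit. Each fitted model is scored by
BIC = −2·loglik + k·ln(n) with k the number of nonzero gene coefficients,
and the grid optimum is selected. The solver is a monotone coordinate
descent (logistic curvature bound 1/4 as majoriser), verified against a
generic convex-programming oracle to ~10⁻¹³.

## Worked example

```python
from ibdmark import run_pipeline

result = run_pipeline(seed=1)   # simulate -> discover -> train -> lock -> validate
print(result.summary())
```

prints

```
End-to-end synthetic pipeline
==============================================
Discovery ARI vs planted subgroups: 1.000
Microarray optimal model: k=7, BIC=43.8
Candidate panel: 39 informative + 3 reference (39 retained after correlation filter)
qPCR optimal model: k=7
Locked classifier: 7 informative + 3 reference genes
Validation: IBD1 vs IBD2: HR=1.96 (95% CI 1.04 to 3.72; p=0.0384); log-rank chi2=4.45, p=0.035
Validation confusion: Horizon 1.5 y, >= 2 escalations: sensitivity 72.7% (n=22), specificity 55.3% (n=47), PPV 43.2% (n=37), NPV 81.2% (n=32); 0 excluded
Validation call/planted-label agreement: 0.855
```

Reading this: consensus clustering recovered the planted subgroups
perfectly (adjusted Rand index 1.0); BIC selected a 7-gene whole-blood
model; the qPCR candidate panel (39 informative + 3 reference genes) all
survived the correlation filter; the locked classifier kept 7 informative
genes. On an independently simulated validation cohort, IBDhi patients
escalated treatment about twice as fast (hazard ratio 1.96, log-rank
p = 0.035), the classifier caught 72.7% of patients needing multiple
escalations within 18 months, and its calls agreed with the planted
subgroup labels for 85.5% of patients.

Per-stage functions (`consensus_cluster`, `nested_loocv`,
`regularize_unscaled`, `compare_survival`, …) and a statsmodels-style
model class (`PenalizedLogit(...).fit(...)` → results with `.summary()`)
are available for piecemeal use, as is a CLI:

```bash
ibdmark simulate --out cohort/ --seed 1
ibdmark discover --expr cohort/cd8.tsv --out disc --seed 1
ibdmark lock --qpcr cohort/ct.csv --labels disc_labels.csv \
        --reference-genes REF1,REF2,REF3 --out classifier.json
ibdmark classify --classifier classifier.json --ct cohort/ct.csv --out calls.csv
ibdmark validate --calls calls.csv --clinical cohort/clinical.csv --out report.json
```

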